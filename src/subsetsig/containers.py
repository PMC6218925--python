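"""Validated in-memory containers for every table the pipeline touches.

Matrices are stored as pandas DataFrames with feature IDs (genes or probes)
as the index and sample IDs as columns, the layout produced by
featureCounts-style count tables and series-matrix-style array exports.
Validation is total: any invariant violation raises, nothing is silently
repaired.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "IntensityMatrix",
    "GeneIntensityMatrix",
    "OrthologMap",
    "RankedSignature",
    "SimilarityResult",
    "MarkerReport",
    "PCAResult",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class CountMatrix:
    """Integer gene x sample read counts from sorted cell subsets.

    ``subset_of`` maps every sample to its cell-subset label (e.g. pDC,
    cDC1, cM); ``batch_of`` optionally records a sorting batch.
    """

    counts: pd.DataFrame
    subset_of: dict[str, str]
    batch_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "gene")
        _check_unique(list(self.counts.columns), "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            # pinpoint the first offending cell for the error message
            frac = vals != np.floor(vals)
            if np.any(frac):
                g, s = np.argwhere(frac)[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.subset_of]
        if missing:
            raise ValueError(f"samples without subset label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subsets(self) -> list[str]:
        out: list[str] = []
        for s in self.sample_ids:
            lbl = self.subset_of[s]
            if lbl not in out:
                out.append(lbl)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and {s: self.subset_of[s] for s in self.sample_ids}
            == {s: other.subset_of[s] for s in other.sample_ids}
            and (self.batch_of or {}) == (other.batch_of or {})
        )


@dataclasses.dataclass
class NormalizedMatrix:
    """Counts divided by per-sample size factors ("normalized reads")."""

    values: pd.DataFrame
    subset_of: dict[str, str]
    size_factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if np.any(self.values.to_numpy() < 0):
            raise ValueError("normalized values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.subset_of]
        if missing:
            raise ValueError(f"samples without subset label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_subset(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.subset_of[s] == label]

    def subsets(self) -> list[str]:
        out: list[str] = []
        for s in self.sample_ids:
            lbl = self.subset_of[s]
            if lbl not in out:
                out.append(lbl)
        return out


@dataclasses.dataclass
class IntensityMatrix:
    """Probe x sample log2 intensities with probe -> gene annotation.

    ``genes_of`` maps every probe to the (possibly empty) set of gene
    symbols it measures; multi-gene probes carry more than one symbol and
    unannotated probes an empty set.  Both are retained at read time so the
    probe-collapsing step can audit its exclusions.
    """

    log2_intensity: pd.DataFrame
    genes_of: dict[str, frozenset[str]]
    subset_of: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(list(self.log2_intensity.index), "probe")
        _check_unique(list(self.log2_intensity.columns), "sample")
        if not np.all(np.isfinite(self.log2_intensity.to_numpy())):
            raise ValueError("non-finite intensity value")
        for p in self.log2_intensity.index:
            if p not in self.genes_of:
                raise ValueError(f"probe {p!r} missing from annotation")
        missing = [s for s in self.log2_intensity.columns if s not in self.subset_of]
        if missing:
            raise ValueError(f"samples without subset label: {missing}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.log2_intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2_intensity.columns)

    def unannotated_probes(self) -> list[str]:
        return [p for p in self.probe_ids if not self.genes_of[p]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return (
            self.log2_intensity.equals(other.log2_intensity)
            and {p: self.genes_of[p] for p in self.probe_ids}
            == {p: other.genes_of[p] for p in other.probe_ids}
            and {s: self.subset_of[s] for s in self.sample_ids}
            == {s: other.subset_of[s] for s in other.sample_ids}
        )


@dataclasses.dataclass
class GeneIntensityMatrix:
    """Gene-level log2 intensities after probe collapsing (bovine ID space)."""

    log2_intensity: pd.DataFrame
    subset_of: dict[str, str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2_intensity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2_intensity.columns)

    def samples_in_subset(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.subset_of[s] == label]


@dataclasses.dataclass
class OrthologMap:
    """Finite relation between foreign-species gene IDs and bovine gene IDs.

    A foreign gene is *ambiguous* iff it maps to anything other than exactly
    one bovine gene; ambiguous genes are dropped during probe collapsing
    because their cattle ortholog cannot be determined.
    """

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)

    def bovine_targets(self, foreign_gene: str) -> frozenset[str]:
        return frozenset(b for f, b in self.pairs if f == foreign_gene)

    def as_dict(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for f, b in self.pairs:
            out.setdefault(f, set()).add(b)
        return {f: frozenset(v) for f, v in out.items()}

    def is_ambiguous(self, foreign_gene: str) -> bool:
        return len(self.bovine_targets(foreign_gene)) != 1

    def foreign_genes(self) -> frozenset[str]:
        return frozenset(f for f, _ in self.pairs)


@dataclasses.dataclass
class RankedSignature:
    """Total order over a gene universe for one subset.

    Position 1 holds the most significantly upregulated gene of the subset
    (versus the pool of all remaining subsets), the final position the most
    significantly downregulated one.
    """

    subset_label: str
    species_label: str
    ordered_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.ordered_genes = tuple(self.ordered_genes)
        if len(set(self.ordered_genes)) != len(self.ordered_genes):
            raise ValueError("ranked signature contains duplicate genes")

    def __len__(self) -> int:
        return len(self.ordered_genes)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.ordered_genes)

    def restricted_to(self, keep: Mapping[str, bool] | set[str] | frozenset[str]) -> "RankedSignature":
        """Drop genes outside ``keep``, preserving the relative order."""
        return RankedSignature(
            self.subset_label,
            self.species_label,
            tuple(g for g in self.ordered_genes if g in keep),
        )


@dataclasses.dataclass
class SimilarityResult:
    """Observed tail-overlap similarity plus its permutation null."""

    score_observed: float
    n_tail: int
    alpha_decay: float
    informative_universe_size: int
    null_scores: np.ndarray
    empirical_p: float

    def __post_init__(self) -> None:
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        n_perm = len(self.null_scores)
        expect = (1 + int(np.sum(self.null_scores >= self.score_observed))) / (1 + n_perm)
        if not np.isclose(self.empirical_p, expect):
            raise ValueError("empirical_p inconsistent with null_scores")

    @property
    def n_perm(self) -> int:
        return len(self.null_scores)


@dataclasses.dataclass
class MarkerReport:
    """Subset-specific marker genes per grouped subset.

    ``up`` / ``down`` map each group to a DataFrame indexed by gene with
    columns ``min_abs_log2fc`` (the weakest fold change across all pairwise
    comparisons) and ``max_adj_p`` (the least significant adjusted p).
    """

    grouping: dict[str, str]
    up: dict[str, pd.DataFrame]
    down: dict[str, pd.DataFrame]
    tested_pairs: list[tuple[str, str]]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for direction, table in (("up", self.up), ("down", self.down)):
            for group in sorted(table):
                df = table[group]
                for gene in df.index:
                    rows.append(
                        {
                            "group": group,
                            "direction": direction,
                            "gene": gene,
                            "min_abs_log2fc": df.loc[gene, "min_abs_log2fc"],
                            "max_adj_p": df.loc[gene, "max_adj_p"],
                        }
                    )
        return pd.DataFrame(
            rows, columns=["group", "direction", "gene", "min_abs_log2fc", "max_adj_p"]
        )


@dataclasses.dataclass
class PCAResult:
    """First two principal components over the most variable genes."""

    selected_genes: tuple[str, ...]
    sample_coordinates: pd.DataFrame  # samples x (PC1, PC2)
    variance_explained: np.ndarray  # per retained component, non-increasing

    def __post_init__(self) -> None:
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        ve = self.variance_explained
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ValueError("variance_explained entries must lie in [0, 1]")
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")
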