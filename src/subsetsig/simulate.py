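"""Synthetic two-species expression data with planted subset signatures.

The generator emulates the study design the pipeline targets: bulk RNA-seq
of six sorted blood mononuclear phagocyte subsets (pDC, cDC1, two cDC2
sorting batches, classical monocytes, and merged intermediate/non-classical
monocytes) from a small number of animals, plus a second "species" measured
on a microarray-style platform whose genes map back to the bovine ID space
through an ortholog table with realistic defects (multi-probe genes,
multi-gene probes, ambiguous orthologs).

Every planted marker, effect and size factor is recorded in a
:class:`SimTruth` so downstream stages can be scored against ground truth;
nothing of the truth leaks into the generated data files themselves.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, IntensityMatrix, OrthologMap, RankedSignature

# default design mirrors the sorted-subset study: 6 subsets x 3 animals;
# the two cDC2 sorting batches share their marker genes and differ only by
# a batch offset on a fraction of background genes
DEFAULT_SUBSETS: tuple[tuple[str, int], ...] = (
    ("pDC", 3),
    ("cDC1", 3),
    ("cDC2a", 3),
    ("cDC2b", 3),
    ("cM", 3),
    ("intncM", 3),
)
DEFAULT_MARKER_GROUPS: tuple[tuple[str, ...], ...] = (
    ("pDC",),
    ("cDC1",),
    ("cDC2a", "cDC2b"),
    ("cM",),
    ("intncM",),
)
DEFAULT_GROUPING: dict[str, str] = {
    "pDC": "pDC",
    "cDC1": "cDC1",
    "cDC2a": "cDC2",
    "cDC2b": "cDC2",
    "cM": "cM",
    "intncM": "intncM",
}


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``marker_of`` maps each subset label to its planted (up, down) marker
    gene sets; subsets sharing a marker group reference the same sets.
    ``conserved_of`` (populated by :func:`simulate_second_species`) records
    which markers kept their effect in the second species.
    """

    marker_of: dict[str, tuple[frozenset[str], frozenset[str]]]
    effect_log2: float
    baseline_log2_mean: dict[str, float]
    size_factor_of: dict[str, float]
    dispersion: float
    batch_genes: frozenset[str] = frozenset()
    batch_offset_log2: float = 0.0
    conserved_frac: float | None = None
    conserved_of: dict[str, tuple[frozenset[str], frozenset[str]]] | None = None

    def all_marker_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for up, down in self.marker_of.values():
            out |= up | down
        return frozenset(out)

    def to_json(self, path: str | Path) -> None:
        def _pair(d):
            return {k: [sorted(u), sorted(v)] for k, (u, v) in d.items()}

        payload = {
            "marker_of": _pair(self.marker_of),
            "effect_log2": self.effect_log2,
            "baseline_log2_mean": self.baseline_log2_mean,
            "size_factor_of": self.size_factor_of,
            "dispersion": self.dispersion,
            "batch_genes": sorted(self.batch_genes),
            "batch_offset_log2": self.batch_offset_log2,
            "conserved_frac": self.conserved_frac,
            "conserved_of": _pair(self.conserved_of) if self.conserved_of else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)

        def _pair(d):
            return {k: (frozenset(u), frozenset(v)) for k, (u, v) in d.items()}

        return cls(
            marker_of=_pair(raw["marker_of"]),
            effect_log2=raw["effect_log2"],
            baseline_log2_mean=raw["baseline_log2_mean"],
            size_factor_of=raw["size_factor_of"],
            dispersion=raw["dispersion"],
            batch_genes=frozenset(raw["batch_genes"]),
            batch_offset_log2=raw["batch_offset_log2"],
            conserved_frac=raw["conserved_frac"],
            conserved_of=_pair(raw["conserved_of"]) if raw["conserved_of"] else None,
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    dispersion = 0 degenerates to Poisson.
    """
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(
    n_genes: int = 12000,
    subsets: tuple[tuple[str, int], ...] = DEFAULT_SUBSETS,
    n_markers_per_subset: int = 150,
    effect_log2: float = 3.0,
    dispersion: float = 0.1,
    seed: int = 0,
    marker_groups: tuple[tuple[str, ...], ...] | None = None,
    baseline_log2_mean: float = 5.0,
    baseline_log2_sd: float = 2.0,
    size_factor_log_sd: float = 0.3,
    batch_offset_log2: float = 1.0,
    batch_frac: float = 0.1,
) -> tuple[CountMatrix, SimTruth]:
    """Simulate a sorted-subset count matrix with planted markers.

    Baseline per-gene means are drawn log-normally (log2 mean 5, sd 2,
    spanning the tens-to-tens-of-thousands normalized-read range typical of
    these data).  Each marker group receives ``n_markers_per_subset``
    marker genes, half shifted up and half down by ``effect_log2`` in that
    group's samples.  Counts are negative-binomial with per-sample
    log-normal size factors.  When ``marker_groups`` is None the default
    design is used: each subset has its own markers except the two cDC2
    sorting batches, which share theirs and instead differ by a batch
    offset applied to a random ``batch_frac`` of background genes —
    emulating the consistent handling-induced difference between the two
    cDC2 sortings.
    """
    labels = [lbl for lbl, _ in subsets]
    if marker_groups is None:
        if set(labels) == {lbl for lbl, _ in DEFAULT_SUBSETS}:
            marker_groups = DEFAULT_MARKER_GROUPS
        else:
            marker_groups = tuple((lbl,) for lbl in labels)
    group_members = {g: members for g, members in enumerate(marker_groups)}
    covered = [m for ms in marker_groups for m in ms]
    if sorted(covered) != sorted(set(covered)) or set(covered) != set(labels):
        raise ValueError("marker_groups must partition the subset labels")
    n_groups = len(marker_groups)
    if n_genes < n_groups * n_markers_per_subset:
        raise ValueError(
            f"cannot allocate {n_groups} x {n_markers_per_subset} markers "
            f"from {n_genes} genes"
        )

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids: list[str] = []
    sample_subset: dict[str, str] = {}
    for lbl, n_rep in subsets:
        for r in range(1, n_rep + 1):
            sid = f"{lbl}_{r}"
            sample_ids.append(sid)
            sample_subset[sid] = lbl

    log2_mu = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    mu = np.power(2.0, log2_mu)
    size_factor = np.exp(rng.normal(0.0, size_factor_log_sd, size=len(sample_ids)))

    # disjoint marker allocation across groups, half up / half down each
    marker_pool = rng.permutation(n_genes)[: n_groups * n_markers_per_subset]
    marker_of: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    effect = np.zeros((n_genes, len(sample_ids)))
    half = n_markers_per_subset // 2
    for gi, members in group_members.items():
        block = marker_pool[gi * n_markers_per_subset : (gi + 1) * n_markers_per_subset]
        up_idx, down_idx = block[:half], block[half:]
        up_set = frozenset(gene_ids[i] for i in up_idx)
        down_set = frozenset(gene_ids[i] for i in down_idx)
        cols = [j for j, s in enumerate(sample_ids) if sample_subset[s] in members]
        effect[np.ix_(up_idx, cols)] = effect_log2
        effect[np.ix_(down_idx, cols)] = -effect_log2
        for m in members:
            marker_of[m] = (up_set, down_set)

    # batch offset between marker-sharing subsets, on background genes only
    batch_genes: frozenset[str] = frozenset()
    shared = [ms for ms in marker_groups if len(ms) > 1]
    if shared and batch_offset_log2 != 0 and batch_frac > 0:
        background = np.setdiff1d(np.arange(n_genes), marker_pool)
        n_batch = int(round(batch_frac * n_genes))
        batch_idx = rng.choice(background, size=min(n_batch, len(background)), replace=False)
        batch_genes = frozenset(gene_ids[i] for i in batch_idx)
        for ms in shared:
            # the second member of each shared pair carries the offset
            off_cols = [j for j, s in enumerate(sample_ids) if sample_subset[s] == ms[-1]]
            effect[np.ix_(batch_idx, off_cols)] += batch_offset_log2

    mean_matrix = size_factor[None, :] * mu[:, None] * np.power(2.0, effect)
    counts = _nb_draw(rng, mean_matrix, dispersion)
    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids),
        subset_of=sample_subset,
        batch_of=None,
    )
    truth = SimTruth(
        marker_of=marker_of,
        effect_log2=effect_log2,
        baseline_log2_mean=dict(zip(gene_ids, log2_mu.astype(float))),
        size_factor_of=dict(zip(sample_ids, size_factor.astype(float))),
        dispersion=dispersion,
        batch_genes=batch_genes,
        batch_offset_log2=batch_offset_log2 if batch_genes else 0.0,
    )
    return cm, truth


def simulate_second_species(
    truth: SimTruth,
    conserved_frac: float = 0.8,
    probes_per_gene_range: tuple[int, int] = (1, 3),
    multi_gene_probe_rate: float = 0.05,
    ambiguous_ortholog_rate: float = 0.05,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_replicates: int = 3,
    species_label: str = "sp2",
) -> tuple[IntensityMatrix, OrthologMap, SimTruth]:
    """Simulate a microarray-style dataset for a second species.

    Species-2 genes are renamed bovine genes (prefix ``species_label``).
    A ``conserved_frac`` fraction of each subset's planted markers keeps its
    effect; the rest revert to baseline.  Each gene is measured by 1-k
    probes (log2 intensity = gene log2 mean + subset effect + probe offset
    + Gaussian noise); a ``multi_gene_probe_rate`` fraction of probes is
    additionally annotated to a second random gene, and an
    ``ambiguous_ortholog_rate`` fraction of foreign genes maps to two
    bovine genes in the ortholog table.  The returned SimTruth records
    which markers were conserved.
    """
    for name, rate in (
        ("conserved_frac", conserved_frac),
        ("multi_gene_probe_rate", multi_gene_probe_rate),
        ("ambiguous_ortholog_rate", ambiguous_ortholog_rate),
    ):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    bovine_genes = sorted(truth.baseline_log2_mean)
    foreign_of = {g: f"{species_label.upper()}_{g}" for g in bovine_genes}

    subset_labels = sorted(truth.marker_of)
    # decide conservation per marker group (shared sets decided once)
    conserved_of: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    decided: dict[frozenset[str], frozenset[str]] = {}

    def _conserve(genes: frozenset[str]) -> frozenset[str]:
        if genes not in decided:
            arr = np.array(sorted(genes))
            keep = rng.random(len(arr)) < conserved_frac
            decided[genes] = frozenset(arr[keep])
        return decided[genes]

    for lbl in subset_labels:
        up, down = truth.marker_of[lbl]
        conserved_of[lbl] = (_conserve(up), _conserve(down))

    sample_ids: list[str] = []
    sample_subset: dict[str, str] = {}
    for lbl in subset_labels:
        for r in range(1, n_replicates + 1):
            sid = f"{species_label}_{lbl}_{r}"
            sample_ids.append(sid)
            sample_subset[sid] = lbl

    n_genes = len(bovine_genes)
    base = np.array([truth.baseline_log2_mean[g] for g in bovine_genes])
    effect = np.zeros((n_genes, len(sample_ids)))
    gene_index = {g: i for i, g in enumerate(bovine_genes)}
    for lbl in subset_labels:
        cols = [j for j, s in enumerate(sample_ids) if sample_subset[s] == lbl]
        up_c, down_c = conserved_of[lbl]
        for g in up_c:
            effect[gene_index[g], cols] = truth.effect_log2
        for g in down_c:
            effect[gene_index[g], cols] = -truth.effect_log2

    lo, hi = probes_per_gene_range
    if not (1 <= lo <= hi):
        raise ValueError("probes_per_gene_range must satisfy 1 <= lo <= hi")
    n_probes_of = rng.integers(lo, hi + 1, size=n_genes)

    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    genes_of: dict[str, frozenset[str]] = {}
    for i, g in enumerate(bovine_genes):
        for k in range(n_probes_of[i]):
            pid = f"P_{foreign_of[g]}_{k}"
            probe_offset = rng.normal(0.0, 0.25)
            noise = rng.normal(0.0, noise_sd, size=len(sample_ids))
            rows.append(base[i] + effect[i] + probe_offset + noise)
            ann = {foreign_of[g]}
            if rng.random() < multi_gene_probe_rate:
                other = bovine_genes[int(rng.integers(n_genes))]
                if other != g:
                    ann.add(foreign_of[other])
            probe_ids.append(pid)
            genes_of[pid] = frozenset(ann)

    pairs: set[tuple[str, str]] = set()
    ambiguous = rng.random(n_genes) < ambiguous_ortholog_rate
    for i, g in enumerate(bovine_genes):
        pairs.add((foreign_of[g], g))
        if ambiguous[i]:
            other = bovine_genes[int(rng.integers(n_genes))]
            if other != g:
                pairs.add((foreign_of[g], other))

    im = IntensityMatrix(
        log2_intensity=pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids),
        genes_of=genes_of,
        subset_of=sample_subset,
    )
    om = OrthologMap(pairs=frozenset(pairs))
    truth2 = dataclasses.replace(
        truth, conserved_frac=conserved_frac, conserved_of=conserved_of
    )
    return im, om, truth2


def make_toy_list_pair(
    universe_size: int,
    tail_depth: int,
    planted_top_overlap: int,
    planted_bottom_overlap: int,
    seed: int = 0,
) -> tuple[RankedSignature, RankedSignature]:
    """Two rankings of one universe with exact planted tail overlaps.

    At depth ``tail_depth`` the top tails of the two lists share exactly
    ``planted_top_overlap`` genes and the bottom tails exactly
    ``planted_bottom_overlap``; fixture generator for the similarity
    statistic.
    """
    d = tail_depth
    if not (
        0 <= planted_top_overlap <= d
        and 0 <= planted_bottom_overlap <= d
        and 2 * d <= universe_size
    ):
        raise ValueError("overlaps must be <= tail depth and 2*depth <= universe")
    middle_needed = (d - planted_top_overlap) + (d - planted_bottom_overlap)
    if universe_size - 2 * d < middle_needed:
        raise ValueError(
            "not enough middle genes to realise the requested (dis)overlap"
        )
    rng = np.random.default_rng(seed)
    genes = [f"T{i:04d}" for i in range(universe_size)]
    list_a = list(rng.permutation(genes))
    top_a, bottom_a = list_a[:d], list_a[-d:]
    middle_a = list_a[d:-d]

    shared_top = list(rng.choice(top_a, size=planted_top_overlap, replace=False))
    shared_bottom = list(rng.choice(bottom_a, size=planted_bottom_overlap, replace=False))
    middle_pool = list(rng.permutation(middle_a))
    fill_top = [middle_pool.pop() for _ in range(d - planted_top_overlap)]
    fill_bottom = [middle_pool.pop() for _ in range(d - planted_bottom_overlap)]
    used = set(shared_top + shared_bottom + fill_top + fill_bottom)
    remainder = [g for g in genes if g not in used]
    remainder = list(rng.permutation(remainder))
    # full overlap keeps the original tail order so the score is maximal
    if planted_top_overlap == d:
        top_b = list(top_a)
    else:
        top_b = list(rng.permutation(shared_top + fill_top))
    if planted_bottom_overlap == d:
        bottom_b = list(bottom_a)
    else:
        bottom_b = list(rng.permutation(shared_bottom + fill_bottom))
    list_b = top_b + remainder + bottom_b
    return (
        RankedSignature("toyA", "toy", tuple(list_a)),
        RankedSignature("toyB", "toy", tuple(list_b)),
    )
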