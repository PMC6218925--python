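"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import math

import yaml


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the comparison pipeline.

    Attributes
    ----------
    n_tail:
        Number of genes taken from each end of a ranked signature when
        computing the tail-overlap similarity score.
    alpha_decay:
        Exponential decay constant of the per-depth weights ``exp(-alpha * j)``.
        ``None`` resolves to ``ln(20) / n_tail``, i.e. the weight at the
        deepest tail position is 5% of the weight at rank 1, so the score is
        dominated by the most extreme genes while every tail rank still
        contributes.
    middle_frac:
        Fraction of list positions regarded as uninformative "middle" genes;
        genes in the middle of *both* lists are excluded before the
        permutation test because they cannot contribute to tail overlap.
    n_perm:
        Number of reshuffles used to build the null score distribution.
    fold_threshold:
        Minimal fold change (not log2) a subset-specific marker must reach
        against every other group.
    sig_level:
        BH-adjusted p-value threshold for the marker filter.
    min_reads:
        Genes whose mean normalized read count stays below this floor in
        every group are omitted from marker discovery.
    n_top_var:
        Number of most-variable genes entering the PCA.
    rng_seed:
        Master seed; per-pair permutation seeds are derived from it.
    score_on_restricted:
        If True (default) the observed similarity score is computed on the
        middle-excluded lists, the same universe the null scores use.  If
        False the observed score is computed on the full harmonized lists
        while the null remains restricted.
    """

    n_tail: int = 1000
    alpha_decay: float | None = None
    middle_frac: float = 0.6
    n_perm: int = 1000
    fold_threshold: float = 5.0
    sig_level: float = 0.05
    min_reads: float = 200.0
    n_top_var: int = 500
    rng_seed: int = 0
    score_on_restricted: bool = True

    def __post_init__(self) -> None:
        if self.n_tail < 1:
            raise ValueError(f"n_tail must be >= 1, got {self.n_tail}")
        if self.alpha_decay is not None and self.alpha_decay < 0:
            raise ValueError("alpha_decay must be non-negative")
        if not 0 <= self.middle_frac < 1:
            raise ValueError("middle_frac must lie in [0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be strictly positive")
        if not 0 < self.sig_level < 1:
            raise ValueError("sig_level must lie in (0, 1)")
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")
        if self.n_top_var < 1:
            raise ValueError("n_top_var must be positive")

    @property
    def alpha(self) -> float:
        """Resolved decay constant (default ln(20)/n_tail)."""
        if self.alpha_decay is None:
            return math.log(20.0) / self.n_tail
        return self.alpha_decay

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
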