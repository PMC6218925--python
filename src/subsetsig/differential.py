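"""Normalization and one-vs-rest differential-transcription tests.

Counts are scaled by median-of-ratios size factors, then each subset is
contrasted against the pool of all remaining subsets.  For RNA-seq counts a
delta-method Wald test under a negative-binomial mean-variance relation
(var = mu + disp * mu^2) produces per-gene fold changes and p-values; for
probe-collapsed log2 microarray intensities a Welch two-sample t-test is
used.  Both test families feed Benjamini-Hochberg FDR adjustment and the
downstream ranking; neither claims to replicate a full GLM fit with
dispersion shrinkage — the consumers here use only the induced rankings
and threshold filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, GeneIntensityMatrix, NormalizedMatrix

DE_COLUMNS = ["mean_target", "mean_rest", "log2fc", "p_value", "adj_p"]


def size_factors(cm: CountMatrix) -> dict[str, float]:
    """Median-of-ratios size factor per sample.

    For each gene with strictly positive counts in every sample, the ratio
    of each sample's count to the gene's geometric mean is formed; a
    sample's factor is the median of its ratios.  Factors are not rescaled
    further, so multiplying one sample's column by c multiplies its factor
    by exactly c.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — consider adding a pseudo-reference or filtering samples"
        )
    ref = counts[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return dict(zip(cm.sample_ids, factors.astype(float)))


def normalize(cm: CountMatrix, factors: dict[str, float] | None = None) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(cm)
    missing = [s for s in cm.sample_ids if s not in factors]
    if missing:
        raise ValueError(f"missing size factor for samples: {missing}")
    for s in cm.sample_ids:
        if factors[s] <= 0:
            raise ValueError(f"size factor for sample {s!r} must be positive")
    fac = np.array([factors[s] for s in cm.sample_ids])
    values = cm.counts.to_numpy(dtype=float) / fac[None, :]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns),
        subset_of=cm.subset_of,
        size_factors={s: float(factors[s]) for s in cm.sample_ids},
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over k >= i of p_(k) * m / k, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def _nb_wald_core(
    vals_a: np.ndarray,
    vals_b: np.ndarray,
    pseudo: float,
    min_dispersion: float,
) -> pd.DataFrame:
    """Delta-method NB Wald test between two groups of normalized columns.

    Per gene: group means mu_A, mu_B; a method-of-moments dispersion from
    the pooled within-group residual variance, floored at ``min_dispersion``;
    W = (ln(mu_A + pseudo) - ln(mu_B + pseudo)) / SE with
    SE^2 = (1/n_A)(1/(mu_A + pseudo) + disp) + (1/n_B)(1/(mu_B + pseudo) + disp);
    two-sided normal p-value.  A gene that is zero everywhere collapses to
    log2fc = 0, W = 0, p = 1 via the pseudo-count.
    """
    n_a, n_b = vals_a.shape[1], vals_b.shape[1]
    mu_a = vals_a.mean(axis=1)
    mu_b = vals_b.mean(axis=1)
    s2_a = vals_a.var(axis=1, ddof=1) if n_a > 1 else np.zeros_like(mu_a)
    s2_b = vals_b.var(axis=1, ddof=1) if n_b > 1 else np.zeros_like(mu_b)
    df_a, df_b = max(n_a - 1, 0), max(n_b - 1, 0)
    pooled_var = (df_a * s2_a + df_b * s2_b) / max(df_a + df_b, 1)
    mu_bar = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - mu_bar) / mu_bar**2
    disp = np.where(mu_bar > 0, disp, min_dispersion)
    disp = np.maximum(disp, min_dispersion)
    la = np.log(mu_a + pseudo)
    lb = np.log(mu_b + pseudo)
    se2 = (1.0 / n_a) * (1.0 / (mu_a + pseudo) + disp) + (1.0 / n_b) * (
        1.0 / (mu_b + pseudo) + disp
    )
    w = (la - lb) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(w))
    log2fc = np.log2((mu_a + pseudo) / (mu_b + pseudo))
    return pd.DataFrame(
        {
            "mean_target": mu_a,
            "mean_rest": mu_b,
            "log2fc": log2fc,
            "p_value": p,
            "W": w,
        }
    )


def nb_wald_two_groups(
    nm: NormalizedMatrix,
    samples_a: list[str],
    samples_b: list[str],
    pseudo: float = 0.5,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """NB Wald test between two explicit sample groups; BH across all genes."""
    if len(samples_a) < 2:
        raise ValueError("target group must contain at least 2 samples")
    if len(samples_b) == 0:
        raise ValueError("comparison group is empty")
    res = _nb_wald_core(
        nm.values[samples_a].to_numpy(dtype=float),
        nm.values[samples_b].to_numpy(dtype=float),
        pseudo,
        min_dispersion,
    )
    res.index = nm.values.index
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    return res[DE_COLUMNS + ["W"]]


def nb_wald_one_vs_rest(
    nm: NormalizedMatrix,
    target_subset: str,
    pseudo: float = 0.5,
    min_dispersion: float = 1e-8,
) -> pd.DataFrame:
    """One-vs-rest NB Wald DE table for one subset against the pooled rest.

    Returns a DataFrame indexed by gene (input order) with columns
    mean_target, mean_rest, log2fc, p_value, adj_p and the Wald statistic W.
    """
    target = nm.samples_in_subset(target_subset)
    rest = [s for s in nm.sample_ids if nm.subset_of[s] != target_subset]
    if len(target) < 2:
        raise ValueError(
            f"target subset {target_subset!r} has {len(target)} sample(s); need >= 2"
        )
    if not rest:
        raise ValueError("rest pool is empty")
    return nb_wald_two_groups(nm, target, rest, pseudo=pseudo, min_dispersion=min_dispersion)


def welch_t_one_vs_rest(gm: GeneIntensityMatrix, target_subset: str) -> pd.DataFrame:
    """Welch two-sample t-test of one subset vs the pooled rest on log2 intensities.

    log2fc is the difference of group means.  When both group variances are
    zero the statistic is degenerate: p is reported as 1 if the means are
    equal and 0 otherwise, so constant genes never produce NaNs.
    """
    target = gm.samples_in_subset(target_subset)
    rest = [s for s in gm.sample_ids if gm.subset_of[s] != target_subset]
    if len(target) < 2 or len(rest) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (target {len(target)}, rest {len(rest)})"
        )
    a = gm.log2_intensity[target].to_numpy(dtype=float)
    b = gm.log2_intensity[rest].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p[degenerate] = np.where(mean_a[degenerate] == mean_b[degenerate], 1.0, 0.0)
    p = np.nan_to_num(p, nan=1.0)
    res = pd.DataFrame(
        {
            "mean_target": mean_a,
            "mean_rest": mean_b,
            "log2fc": mean_a - mean_b,
            "p_value": p,
        },
        index=gm.log2_intensity.index,
    )
    res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
    return res[DE_COLUMNS]
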