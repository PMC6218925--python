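"""Subset-specific marker discovery and descriptive PCA.

A gene is a subset-specific marker when it is at least ``fold_threshold``-
fold up- (or down-) regulated against *every* other grouped subset with a
BH-adjusted p below ``sig_level`` in each pairwise comparison, after
dropping genes whose mean normalized reads stay below ``min_reads`` in all
groups.  Intermediate and non-classical monocytes are conventionally merged
into one group, as are the two cDC2 sorting batches.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import CountMatrix, MarkerReport, NormalizedMatrix, PCAResult
from .differential import nb_wald_two_groups


def subset_specific_genes(
    nm: NormalizedMatrix,
    grouping: dict[str, str],
    config: AnalysisConfig,
    raw_counts: CountMatrix | None = None,
) -> MarkerReport:
    """Find genes specifically up- or downregulated in one grouped subset.

    Procedure: (1) drop genes whose mean normalized reads fall below
    ``config.min_reads`` in every group (pass ``raw_counts`` to apply the
    floor to raw per-group mean counts instead); (2) run the NB Wald test
    between every ordered pair of groups, BH-adjusting within each pairwise
    comparison; (3) a gene is UP-specific for a group iff against every
    other group its log2 fold change is at least ``log2(fold_threshold)``
    with adjusted p below ``sig_level`` — DOWN-specific analogously.

    Merged subsets (same group label) are never tested against each other;
    the tested pairs are recorded on the report for audit.
    """
    unknown = [s for s in nm.subsets() if s not in grouping]
    if unknown:
        raise ValueError(f"subsets without group assignment: {unknown}")
    group_samples: dict[str, list[str]] = {}
    for s in nm.sample_ids:
        group_samples.setdefault(grouping[nm.subset_of[s]], []).append(s)
    too_small = {g: len(ss) for g, ss in group_samples.items() if len(ss) < 2}
    if too_small:
        raise ValueError(f"groups with fewer than 2 samples: {too_small}")
    groups = sorted(group_samples)

    floor_source = nm.values if raw_counts is None else raw_counts.counts.astype(float)
    group_means = pd.DataFrame(
        {g: floor_source[group_samples[g]].mean(axis=1) for g in groups}
    )
    keep = group_means.max(axis=1) >= config.min_reads
    tested_genes = nm.values.index[keep.to_numpy()]

    kept_nm = NormalizedMatrix(
        values=nm.values.loc[tested_genes],
        subset_of=nm.subset_of,
        size_factors=nm.size_factors,
    )
    pair_de: dict[tuple[str, str], pd.DataFrame] = {}
    tested_pairs: list[tuple[str, str]] = []
    for t in groups:
        for o in groups:
            if t == o:
                continue
            pair_de[(t, o)] = nb_wald_two_groups(
                kept_nm, group_samples[t], group_samples[o]
            )
            tested_pairs.append((t, o))

    lfc_min = np.log2(config.fold_threshold)
    up: dict[str, pd.DataFrame] = {}
    down: dict[str, pd.DataFrame] = {}
    for t in groups:
        others = [o for o in groups if o != t]
        lfc = pd.DataFrame({o: pair_de[(t, o)]["log2fc"] for o in others})
        adj = pd.DataFrame({o: pair_de[(t, o)]["adj_p"] for o in others})
        sig = (adj < config.sig_level).all(axis=1)
        is_up = (lfc >= lfc_min).all(axis=1) & sig
        is_down = (lfc <= -lfc_min).all(axis=1) & sig
        up[t] = pd.DataFrame(
            {
                "min_abs_log2fc": lfc[is_up].abs().min(axis=1),
                "max_adj_p": adj[is_up].max(axis=1),
            }
        )
        down[t] = pd.DataFrame(
            {
                "min_abs_log2fc": lfc[is_down].abs().min(axis=1),
                "max_adj_p": adj[is_down].max(axis=1),
            }
        )
    return MarkerReport(grouping=dict(grouping), up=up, down=down, tested_pairs=tested_pairs)


def pca_top_variable(nm: NormalizedMatrix, config: AnalysisConfig) -> PCAResult:
    """PCA of samples on the most variable genes.

    Normalized values are log2(x+1)-transformed; genes are ranked by
    variance across all samples and the top ``config.n_top_var`` kept (ties
    broken by gene ID); each gene is centered and the sample coordinates on
    the first two principal components are returned, with each component's
    sign fixed so its largest-magnitude gene loading is positive.
    """
    if len(nm.sample_ids) < 2:
        raise ValueError("PCA needs at least 2 samples")
    if len(nm.gene_ids) < 2:
        raise ValueError("PCA needs at least 2 genes")
    x = np.log2(nm.values.to_numpy(dtype=float) + 1.0)
    var = x.var(axis=1, ddof=1)
    order = sorted(range(len(var)), key=lambda i: (-var[i], nm.gene_ids[i]))
    n_keep = min(config.n_top_var, len(order))
    sel = order[:n_keep]
    selected_genes = tuple(nm.gene_ids[i] for i in sel)
    xs = x[sel]
    xs = xs - xs.mean(axis=1, keepdims=True)
    # SVD of the samples x genes matrix
    u, s, vt = np.linalg.svd(xs.T, full_matrices=False)
    total = float(np.sum(s**2))
    n_comp = min(2, len(s))
    coords = u[:, :n_comp] * s[:n_comp]
    for c in range(n_comp):
        loading = vt[c]
        peak = loading[np.argmax(np.abs(loading))]
        if peak < 0:
            coords[:, c] *= -1
    if n_comp < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - n_comp))])
    variance_explained = (
        (s**2) / total if total > 0 else np.zeros_like(s)
    )
    return PCAResult(
        selected_genes=selected_genes,
        sample_coordinates=pd.DataFrame(
            coords, index=pd.Index(nm.sample_ids, name="sample_id"), columns=["PC1", "PC2"]
        ),
        variance_explained=variance_explained,
    )


def heatmap_matrix(
    nm: NormalizedMatrix,
    gene_list: list[str],
    report: MarkerReport,
) -> pd.DataFrame:
    """Mean normalized reads per grouped subset for selected genes.

    Rows follow ``gene_list`` order; unknown genes are skipped with a
    warning.  The ``flag`` column marks genes reported subset-specific
    ("up:GROUP*" / "down:GROUP*"), the asterisk convention of
    marker heat maps.
    """
    grouping = report.grouping
    group_samples: dict[str, list[str]] = {}
    for s in nm.sample_ids:
        group_samples.setdefault(grouping.get(nm.subset_of[s], nm.subset_of[s]), []).append(s)
    groups = sorted(group_samples)
    rows = []
    kept_genes = []
    for g in gene_list:
        if g not in nm.values.index:
            warnings.warn(f"gene {g!r} not in matrix; skipped", stacklevel=2)
            continue
        kept_genes.append(g)
        rows.append([nm.values.loc[g, group_samples[grp]].mean() for grp in groups])
    out = pd.DataFrame(rows, index=pd.Index(kept_genes, name="gene_id"), columns=groups)
    flags = []
    for g in kept_genes:
        tag = ""
        for grp in groups:
            if grp in report.up and g in report.up[grp].index:
                tag = f"up:{grp}*"
            elif grp in report.down and g in report.down[grp].index:
                tag = f"down:{grp}*"
        flags.append(tag)
    out["flag"] = flags
    return out
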