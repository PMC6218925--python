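"""Tab-delimited readers and writers for the pipeline's external tables.

The dialect is deliberately plain: UTF-8, header row, gene/probe IDs in the
first column — the shape featureCounts summaries and series-matrix exports
take once stripped of their comment blocks.  Readers validate on entry and
raise on any malformed cell rather than coercing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    GeneIntensityMatrix,
    IntensityMatrix,
    NormalizedMatrix,
    OrthologMap,
    RankedSignature,
)

MULTI_GENE_DELIMITER = "///"


def _read_sample_metadata(path: str | Path) -> tuple[dict[str, str], dict[str, str] | None]:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subset"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata {path} must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID in metadata: {dup!r}")
    subset_of = dict(zip(meta["sample_id"], meta["subset"]))
    batch_of = None
    if "batch" in meta.columns and meta["batch"].notna().any():
        batch_of = dict(zip(meta["sample_id"], meta["batch"].fillna("")))
    return subset_of, batch_of


def read_count_matrix(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count table plus its sample annotation.

    The count table's first column holds gene IDs; every remaining column is
    one sample.  The metadata table maps every sample to a cell-subset label
    (columns ``sample_id``, ``subset`` and optionally ``batch``).
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene ID: {dup[0]!r}")
    for col in table.columns:
        series = table[col]
        if not np.issubdtype(series.dtype, np.number):
            bad = series[pd.to_numeric(series, errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count at gene {bad.index[0]!r}, sample {col!r}"
            )
    subset_of, batch_of = _read_sample_metadata(metadata_path)
    unlabeled = [s for s in table.columns if s not in subset_of]
    if unlabeled:
        raise ValueError(f"samples without subset label: {unlabeled}")
    return CountMatrix(counts=table, subset_of=subset_of, batch_of=batch_of)


def write_count_matrix(cm: CountMatrix, path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    rows = {"sample_id": cm.sample_ids, "subset": [cm.subset_of[s] for s in cm.sample_ids]}
    if cm.batch_of:
        rows["batch"] = [cm.batch_of.get(s, "") for s in cm.sample_ids]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def read_intensity_matrix(
    path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    delimiter: str = MULTI_GENE_DELIMITER,
) -> IntensityMatrix:
    """Read a probe x sample log2-intensity table with probe annotation.

    The annotation table has columns ``probe_id`` and ``genes``; the latter
    holds zero or more gene symbols joined by ``delimiter`` ("///" by
    convention).  Probes with an empty annotation are retained, flagged as
    unannotated, and only removed later by probe collapsing.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            bad = table[col][pd.to_numeric(table[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric intensity at probe {bad.index[0]!r}, sample {col!r}"
            )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    if not {"probe_id", "genes"}.issubset(ann.columns):
        raise ValueError("probe annotation must have columns ['probe_id', 'genes']")
    genes_of_raw = dict(zip(ann["probe_id"], ann["genes"]))
    genes_of: dict[str, frozenset[str]] = {}
    for probe in table.index:
        if probe not in genes_of_raw:
            raise ValueError(f"probe {probe!r} missing from annotation")
        raw = genes_of_raw[probe].strip()
        genes_of[probe] = frozenset(g for g in raw.split(delimiter) if g) if raw else frozenset()
    subset_of, _ = _read_sample_metadata(metadata_path)
    unlabeled = [s for s in table.columns if s not in subset_of]
    if unlabeled:
        raise ValueError(f"samples without subset label: {unlabeled}")
    return IntensityMatrix(
        log2_intensity=table.astype(float), genes_of=genes_of, subset_of=subset_of
    )


def write_intensity_matrix(
    im: IntensityMatrix,
    path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
    delimiter: str = MULTI_GENE_DELIMITER,
) -> None:
    im.log2_intensity.rename_axis("probe_id").to_csv(path, sep="\t")
    pd.DataFrame(
        {
            "probe_id": im.probe_ids,
            "genes": [delimiter.join(sorted(im.genes_of[p])) for p in im.probe_ids],
        }
    ).to_csv(annotation_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": im.sample_ids,
            "subset": [im.subset_of[s] for s in im.sample_ids],
        }
    ).to_csv(metadata_path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column foreign-gene -> bovine-gene table.

    Duplicate pairs are deduplicated; ambiguity (a foreign gene mapping to
    more than one bovine gene) stays encoded in the relation itself.
    """
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header and len(header.rstrip("\n").split("\t")) != 2:
            raise ValueError(f"{path}: line 1: expected two tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: line {lineno}: malformed row {line!r}")
            pairs.add((parts[0], parts[1]))
    return OrthologMap(pairs=frozenset(pairs))


def write_ortholog_map(om: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("foreign_gene\tbovine_gene\n")
        for f, b in sorted(om.pairs):
            fh.write(f"{f}\t{b}\n")


def write_table(result, path: str | Path) -> None:
    """Write any tabular pipeline output as a deterministic TSV.

    Accepts a DataFrame (row/column order preserved as given), a
    NormalizedMatrix, a GeneIntensityMatrix, or a RankedSignature (written
    as a two-column rank/gene table).
    """
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, sep="\t", index=result.index.name is not None)
    elif isinstance(result, NormalizedMatrix):
        result.values.rename_axis("gene_id").to_csv(path, sep="\t")
    elif isinstance(result, GeneIntensityMatrix):
        result.log2_intensity.rename_axis("gene_id").to_csv(path, sep="\t")
    elif isinstance(result, RankedSignature):
        pd.DataFrame(
            {"rank": range(1, len(result) + 1), "gene": list(result.ordered_genes)}
        ).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot serialise {type(result).__name__} as a table")


def read_ranked_signature(path: str | Path, subset_label: str, species_label: str) -> RankedSignature:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return RankedSignature(subset_label, species_label, tuple(df["gene"]))
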