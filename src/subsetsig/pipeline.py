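"""End-to-end orchestration: differential tests -> signatures -> similarity
matrix -> markers -> PCA, with a reproducibility manifest.

The pipeline is deterministic given the configuration seed: permutation
seeds are derived per signature pair by stable hashing, so re-running with
the same inputs and seed reproduces every output table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import build_ranked_signature, collapse_probes, similarity_matrix
from .config import AnalysisConfig
from .containers import CountMatrix, IntensityMatrix, OrthologMap
from .differential import nb_wald_one_vs_rest, normalize, size_factors, welch_t_one_vs_rest
from .io import write_table
from .markers import pca_top_variable, subset_specific_genes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def default_grouping(cm: CountMatrix) -> dict[str, str]:
    """Identity grouping over the subsets present in the matrix."""
    return {s: s for s in cm.subsets()}


def run_pipeline(
    cm: CountMatrix,
    config: AnalysisConfig,
    out_dir: str | Path,
    foreign: list[tuple[str, IntensityMatrix, OrthologMap]] | None = None,
    grouping: dict[str, str] | None = None,
    input_paths: list[str | Path] | None = None,
) -> dict:
    """Run every analysis stage and write result tables plus a manifest.

    ``foreign`` lists (species_label, intensity matrix, ortholog map)
    triples; when given, one-vs-rest signatures are built for both species
    and the full similarity matrix with permutation p-values is emitted.
    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    outputs: list[Path] = []

    t0 = time.perf_counter()
    nm = normalize(cm, size_factors(cm))
    bovine_sigs = []
    for subset in cm.subsets():
        de = nb_wald_one_vs_rest(nm, subset)
        path = out / f"de_bovine_{subset}.tsv"
        write_table(de.rename_axis("gene_id"), path)
        outputs.append(path)
        sig = build_ranked_signature(de, subset, "bovine")
        bovine_sigs.append(sig)
        sig_path = out / f"signature_bovine_{subset}.tsv"
        write_table(sig, sig_path)
        outputs.append(sig_path)
    stages["differential_and_signatures"] = time.perf_counter() - t0

    if foreign:
        t0 = time.perf_counter()
        foreign_sigs = []
        for species, im, om in foreign:
            gm, audit = collapse_probes(im, om)
            audit_path = out / f"probe_audit_{species}.tsv"
            write_table(audit, audit_path)
            outputs.append(audit_path)
            for subset in sorted(set(gm.subset_of.values())):
                de = welch_t_one_vs_rest(gm, subset)
                path = out / f"de_{species}_{subset}.tsv"
                write_table(de.rename_axis("gene_id"), path)
                outputs.append(path)
                foreign_sigs.append(build_ranked_signature(de, subset, species))
        cells, results = similarity_matrix(bovine_sigs, foreign_sigs, config)
        sim_path = out / "similarity_matrix.tsv"
        write_table(cells, sim_path)
        outputs.append(sim_path)
        null_summary = {
            f"{b}|{f}": {
                "score": res.score_observed,
                "empirical_p": res.empirical_p,
                "informative_universe": res.informative_universe_size,
                "null_mean": float(res.null_scores.mean()),
                "null_max": float(res.null_scores.max()),
            }
            for (b, f), res in sorted(results.items())
        }
        json_path = out / "similarity_matrix.json"
        json_path.write_text(json.dumps(null_summary, indent=1, sort_keys=True))
        outputs.append(json_path)
        stages["similarity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = subset_specific_genes(nm, grouping or default_grouping(cm), config)
    marker_path = out / "markers.tsv"
    write_table(report.as_frame(), marker_path)
    outputs.append(marker_path)
    stages["markers"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pca = pca_top_variable(nm, config)
    coords = pca.sample_coordinates.copy()
    coords["subset"] = [cm.subset_of[s] for s in coords.index]
    pca_path = out / "pca_coordinates.tsv"
    write_table(coords, pca_path)
    outputs.append(pca_path)
    ve_path = out / "pca_variance_explained.tsv"
    write_table(
        pd.DataFrame(
            {
                "component": range(1, len(pca.variance_explained) + 1),
                "variance_explained": pca.variance_explained,
            }
        ),
        ve_path,
    )
    outputs.append(ve_path)
    stages["pca"] = time.perf_counter() - t0

    manifest = {
        "tool": "subsetsig",
        "version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in (input_paths or [])},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "stage_seconds": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
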