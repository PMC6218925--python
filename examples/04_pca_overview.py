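"""PCA of samples on the 500 most variable genes.

log2(x+1)-transformed normalized counts; genes ranked by variance across
all samples; sample coordinates on the first two principal components.
"""

from subsetsig import AnalysisConfig, normalize, pca_top_variable, simulate_counts, size_factors

cm, _ = simulate_counts(n_genes=3000, n_markers_per_subset=60, seed=1)
nm = normalize(cm, size_factors(cm))
res = pca_top_variable(nm, AnalysisConfig(n_top_var=500))

coords = res.sample_coordinates.copy()
coords["subset"] = [cm.subset_of[s] for s in coords.index]
print(coords.round(2).to_string())
print(
    "variance explained: "
    f"PC1 {res.variance_explained[0]:.1%}, PC2 {res.variance_explained[1]:.1%}"
)
# Samples of one subset cluster together; the planted marker blocks drive
# the separation, just as subset-restricted transcription separates sorted
# cell populations in real data.
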