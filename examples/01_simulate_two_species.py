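"""Simulate a two-species sorted-subset expression study with known truth.

Generates bovine-style RNA-seq counts for 6 blood mononuclear phagocyte
subsets (3 animals each) with planted subset-restricted markers, then a
microarray-style second species in which 80% of those markers are
conserved, connected through an ortholog table with realistic defects.
"""

from subsetsig import simulate_counts, simulate_second_species

cm, truth = simulate_counts(n_genes=3000, n_markers_per_subset=60, seed=1)
im, om, truth = simulate_second_species(truth, conserved_frac=0.8, seed=2)

print(f"count matrix: {len(cm.gene_ids)} genes x {len(cm.sample_ids)} samples")
print(f"subsets: {cm.subsets()}")
up, down = truth.marker_of["pDC"]
print(f"pDC planted markers: {len(up)} up, {len(down)} down")
up_c, down_c = truth.conserved_of["pDC"]
print(f"  conserved in second species: {len(up_c)} up, {len(down_c)} down")
n_amb = sum(om.is_ambiguous(f) for f in om.foreign_genes())
print(f"array: {len(im.probe_ids)} probes; {n_amb} foreign genes with ambiguous orthologs")
# Each subset carries its own marker block (the two cDC2 sorting batches
# share theirs); the conserved subsets are what the cross-species
# comparison should rediscover.
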