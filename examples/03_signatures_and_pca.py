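"""Disease-signature specificity and PCA projection of an external cohort.

Three diseases get disjoint sets of true DMRs on a shared genome; one
comparison per disease yields three signature sets whose genomic overlap
is tallied (Venn cells).  A testis-style comparison is then used to fit a
PCA on DMR-window RPKM, and an external cohort simulated with a
*different* DMR set is projected into that space without refitting.
"""

import numpy as np

from epimark import SimConfig, generate_genome, generate_truth, simulate_counts
from epimark.coverage import rpkm
from epimark.pca import project_external
from epimark.pipeline import disease_comparison
from epimark.signature import SignatureSet, overlap_sets

cfg = SimConfig(seed=6)
genome = generate_genome(cfg)
master = generate_truth(cfg, genome, diseases=("testis", "prostate", "kidney"))

sigs = []
for k, disease in enumerate(("testis", "prostate", "kidney")):
    sub = type(master)(
        true_dmrs=[t for t in master.true_dmrs if t.disease == disease],
        disease_labels={s: {disease: l[disease]} for s, l in master.disease_labels.items()},
        library_sizes=master.library_sizes,
        null_loci=master.null_loci
        + [(t.chrom, t.start, t.end) for t in master.true_dmrs if t.disease != disease],
    )
    m = simulate_counts(SimConfig(seed=60 + k), sub, genome)
    labels = {s: master.disease_labels[s][disease] for s in m.sample_ids}
    out = disease_comparison(m, labels, disease, genome=genome.sequences, run_pca=False)
    sigs.append(SignatureSet(disease, out.dmrs))
    print(f"{disease}: {len(out.dmrs)} DMRs")

cells = overlap_sets(sigs)
print("\nVenn cells (disease combination -> overlap groups):")
for key in sorted(cells, key=lambda k: (len(k), sorted(k))):
    print(f"  {'+'.join(sorted(key)):<24}{cells[key]}")
shared = sum(v for k, v in cells.items() if len(k) > 1)
print(f"cross-disease overlap: {shared} of {sum(cells.values())} groups")

# PCA + external projection
cfg_t = SimConfig(seed=1)
genome_t = generate_genome(cfg_t)
truth_t = generate_truth(cfg_t, genome_t)
m_t = simulate_counts(cfg_t, truth_t, genome_t)
labels_t = {s: truth_t.disease_labels[s]["disease"] for s in m_t.sample_ids}
res = disease_comparison(m_t, labels_t, genome=genome_t.sequences)
model = res.pca_model
print(f"\nPCA silhouette, disease vs non-disease: {res.silhouette:.2f}")

ext_truth = generate_truth(SimConfig(seed=71), genome_t)  # different DMR set
m_ext = simulate_counts(SimConfig(seed=71), ext_truth, genome_t)
wids = [f"{c}:{s}" for c, s in zip(m_ext.grid.chroms, m_ext.grid.starts)]
proj = project_external(model, rpkm(m_ext).values.T, m_ext.sample_ids, wids)
train = model.scores_matrix(m_t.sample_ids)[:, :2]
lab = np.array([labels_t[s] for s in m_t.sample_ids])
ext = np.vstack([p[:2] for p in proj.values()]).mean(axis=0)
for name, mask in (("disease", lab), ("non-disease", ~lab)):
    c = train[mask].mean(axis=0)
    r = np.linalg.norm(train[mask] - c, axis=1).max()
    d = np.linalg.norm(ext - c)
    print(f"external centroid vs {name} cluster: distance {d:.0f} (cluster radius {r:.0f})")
print("The external cohort carries its own epimutation set, so its samples")
print("fall outside both training clusters -- exposure-specific signatures.")
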