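"""Supervised projection with a permutation control, and isoform reclustering.

First: a neighbourhood-component-analysis (NCA) projection of separable
cell groups, with the overfitting control — permute the labels, refit, and
check that neighbour label purity collapses to the chance rate sum(f^2).

Second: a gene-derived cluster hiding a planted isoform-only split (gene
totals constant) is re-partitioned in isoform space; the split is accepted
because isoforms — not genes — separate the halves.
"""

import numpy as np
import pandas as pd

import isoshift as iso

# --- NCA + permutation control --------------------------------------------
rng = np.random.default_rng(0)
n_per, n_feat = 150, 12
x = rng.normal(size=(3 * n_per, n_feat))
labels = np.repeat(["Pvalb", "Sst", "Vip"], n_per)
for i in range(3):
    x[labels == ["Pvalb", "Sst", "Vip"][i], 2 * i:2 * i + 2] += 6
m = iso.ExpressionMatrix(x, pd.Index([f"c{i}" for i in range(3 * n_per)]),
                         pd.Index([f"f{j}" for j in range(n_feat)]), state="scaled")
lab = pd.Series(labels, index=m.cell_ids)

embedding = iso.supervised_projection(m, lab, k=10, seed=0)
purity = iso.neighbour_label_purity(embedding, lab)
chance = iso.chance_purity(lab)
perm = iso.permutation_control(m, lab, k=10, seed=1)
print(f"neighbour label purity: true labels {purity:.3f}, "
      f"permuted {perm:.3f}, chance rate {chance:.3f}")
print("True labels far exceed chance; permuted labels sit at chance, so the")
print("projection is not overfitting labels onto noise.\n")

# --- isoform-driven cluster refinement -------------------------------------
effects = [iso.PlantedEffect("cluster_split", f"g{i:03d}", "c1", 0.8,
                             {"gene_mean": 20.0}) for i in range(1, 6)]
config = iso.SimulationConfig(seed=5, ontology={"glut": {"L": {"c1": 200}}},
                              n_genes=40, planted_effects=effects)
annotation = iso.simulate_annotation(config)
counts, cells, truth = iso.simulate_counts(config, annotation)
result = iso.recluster_by_isoform(counts, cells, "c1", annotation["gene_id"], seed=0)
print(f"cluster c1 split: {result.split}")
print(f"  significant isoforms between subclusters: {result.n_significant_isoforms}")
print(f"  mean effect size — isoforms {result.isoform_effect_size:.2f} "
      f"vs genes {result.gene_effect_size:.2f}")
print("A higher isoform effect with a negligible gene effect is the signature")
print("of substructure visible only at isoform resolution.")
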