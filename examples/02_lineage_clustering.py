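"""Cluster the mesenchymal lineages and find their marker genes.

PCA on the scaled residuals, shared-nearest-neighbor modularity clustering,
and cluster-vs-rest ROC-AUC marker detection (log fold change >= 0.25,
detected in >= 25% of cluster cells).
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import zonate

cfg = zonate.SimConfig(n_cells_per_condition=1500, seed=11)
adata, truth = zonate.simulate_dataset(cfg)
adata = zonate.filter_cells_genes(adata, zonate.compute_qc_metrics(adata))
zonate.normalize_log(adata)
zonate.regress_and_scale(adata)
hvg = zonate.select_hvg(adata)

hm = adata.var["highly_variable"].values
emb = zonate.run_pca(np.asarray(adata.layers["scaled"])[:, hm], 10, gene_names=hvg)
print("variance explained by the first 3 PCs:",
      np.round(emb.variance_ratio[:3], 3))

labels = zonate.cluster_snn(emb, seed=0)
sizes = np.bincount(labels)
print(f"{sizes.size} clusters of sizes {sizes.tolist()}")

lineage = truth.set_index("barcode").loc[adata.obs_names, "lineage"].values
print(f"agreement with simulated lineages (ARI): "
      f"{adjusted_rand_score(lineage, labels):.3f}")

for c in range(sizes.size):
    tab = zonate.find_markers_auc(adata.layers["lognorm"], adata.var_names,
                                  labels, c)
    top = ", ".join(tab.head(4)["gene"])
    print(f"cluster {c}: {len(tab)} markers; top by AUC: {top}")
# With the default simulation the three clusters are the FB/HSC/VSMC
# lineages and each cluster's top markers are its implanted marker genes.
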