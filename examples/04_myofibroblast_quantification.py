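"""Quantify which lobule zone supplies collagen-producing myofibroblasts.

Simulates an uninjured plus a chronically injured condition (activation
probability 0.44 in the central half of the lobule, 0.06 in the portal
half), discovers the zonation signature on the uninjured cells, classifies
every HSC as PaHSC or CaHSC, thresholds the fibrillar collagen score
(Col1a1/Col1a2/Col3a1 geometric mean, 1-D 2-means), and crosses the calls.
"""

import numpy as np

import zonate
import zonate.qc as zqc

cfg = zonate.SimConfig(
    conditions=("uninjured", "chronic"),
    n_cells_per_condition=4000,
    lineage_proportions={"HSC": 1.0, "FB": 0.0, "VSMC": 0.0},
    seed=0,
)
adata, truth = zonate.simulate_dataset(cfg)
adata = zonate.filter_cells_genes(adata, zonate.compute_qc_metrics(adata))
zonate.normalize_log(adata)
zonate.regress_and_scale(adata)
cond = adata.obs["condition"].astype(str).values

# signature discovery on the homeostatic reference only
ref = adata[cond == "uninjured"].copy()
zqc.regress_and_scale(ref)
hvg = zonate.select_hvg(ref)
hm = ref.var["highly_variable"].values
ica = zonate.run_ica(np.asarray(ref.layers["scaled"])[:, hm], hvg, 10, seed=1)
comp, orient = zonate.select_anchor_component(
    ica, ref.layers["lognorm"], list(ref.var_names), anchor_gene="Ngfr")
sig = zonate.extract_zonation_signature(ica, comp, orient)
print(f"signature: {len(sig.portal_genes)} portal + {len(sig.central_genes)} central genes")

scaled = np.asarray(adata.layers["scaled"])
lognorm = adata.layers["lognorm"]
labels = np.empty(adata.n_obs, dtype=object)
for c in ("uninjured", "chronic"):
    m = cond == c
    labels[m] = zonate.classify_zonation(scaled[m], lognorm[m],
                                         adata.var_names, sig, seed=2).labels

col = zonate.score_signature(lognorm, adata.var_names,
                             zonate.COLLAGEN_GENES, "collagen")
call = zonate.binarize_kmeans(col)
print(f"collagen threshold {call.threshold:.3f} "
      f"(cluster centroids {call.centroids[0]:.3f} / {call.centroids[1]:.3f}); "
      f"{int(call.positive.sum())} collagen-high cells")

myo = zonate.quantify_myofibroblast_zonation(call, labels)
print(myo["counts"].to_string())
print(f"CaHSC share among myofibroblasts: "
      f"{100 * myo['fraction_CaHSC_among_positive']:.1f}%")
# The designed condition concentrates activation pericentrally (44% vs 6%
# over equal zones, i.e. 88% of activated cells are central); the recovered
# share is slightly below the design because classification blurs the exact
# lobule midline.
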