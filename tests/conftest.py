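"""Shared fixtures: preprocessed simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import zonate
import zonate.qc as zqc


def preprocess(adata):
    """QC-filter, normalize, depth-regress and flag HVGs (in place on a copy)."""
    qc = zonate.compute_qc_metrics(adata)
    out = zonate.filter_cells_genes(adata, qc)
    zonate.normalize_log(out)
    zonate.regress_and_scale(out)
    zonate.select_hvg(out)
    return out


@pytest.fixture(scope="session")
def uninjured_hsc():
    """Default uninjured HSC-only simulation (3,000 cells), preprocessed.

    The reference dataset for zonation-signature discovery: 52 portal and
    29 central genes implanted among 2,000 background genes, zonation
    effect 4.
    """
    cfg = zonate.SimConfig(
        n_cells_per_condition=3000,
        lineage_proportions={"HSC": 1.0, "FB": 0.0, "VSMC": 0.0},
        seed=0,
    )
    adata, truth = zonate.simulate_dataset(cfg)
    adata = preprocess(adata)
    truth = truth.set_index("barcode").loc[adata.obs_names]
    return {"cfg": cfg, "adata": adata, "truth": truth}


@pytest.fixture(scope="session")
def discovered_signature(uninjured_hsc):
    """Anchored-ICA zonation signature discovered on the uninjured fixture."""
    a = uninjured_hsc["adata"]
    hvg = list(a.var_names[a.var["highly_variable"]])
    hm = a.var["highly_variable"].values
    ica = zonate.run_ica(np.asarray(a.layers["scaled"])[:, hm], hvg,
                         n_components=10, seed=0)
    comp, orient = zonate.select_anchor_component(
        ica, a.layers["lognorm"][:, hm], hvg, anchor_gene="Ngfr")
    sig = zonate.extract_zonation_signature(ica, comp, orient)
    return {"ica": ica, "component": comp, "orientation": orient, "signature": sig}


@pytest.fixture(scope="session")
def lineage_sim():
    """Three-lineage (FB/HSC/VSMC) simulation for clustering tests."""
    cfg = zonate.SimConfig(n_cells_per_condition=1500, seed=11)
    adata, truth = zonate.simulate_dataset(cfg)
    adata = preprocess(adata)
    truth = truth.set_index("barcode").loc[adata.obs_names]
    return {"cfg": cfg, "adata": adata, "truth": truth}


def run_injury_chain(seed: int):
    """Full uninjured+chronic myofibroblast-quantification chain.

    Simulates ~2,000 HSCs per lobule half in the chronic condition with
    activation probabilities 0.44 (central) / 0.06 (portal), discovers the
    zonation signature on the uninjured condition (with its own HVG and
    scaling), classifies each condition's HSCs, binarizes the fibrillar
    collagen score and returns the CaHSC share among collagen-positive
    cells plus intermediate objects.
    """
    cfg = zonate.SimConfig(
        conditions=("uninjured", "chronic"),
        n_cells_per_condition=4000,
        lineage_proportions={"HSC": 1.0, "FB": 0.0, "VSMC": 0.0},
        seed=seed,
    )
    adata, truth = zonate.simulate_dataset(cfg)
    adata = preprocess(adata)
    truth = truth.set_index("barcode").loc[adata.obs_names]
    cond = adata.obs["condition"].astype(str).values

    ref = adata[cond == "uninjured"].copy()
    zqc.regress_and_scale(ref)
    hvg = zonate.select_hvg(ref)
    hm = ref.var["highly_variable"].values
    ica = zonate.run_ica(np.asarray(ref.layers["scaled"])[:, hm], hvg,
                         n_components=10, seed=seed + 1)
    comp, orient = zonate.select_anchor_component(
        ica, ref.layers["lognorm"][:, hm], hvg, anchor_gene="Ngfr")
    sig = zonate.extract_zonation_signature(ica, comp, orient)

    scaled = np.asarray(adata.layers["scaled"])
    lognorm = adata.layers["lognorm"]
    labels = np.empty(adata.n_obs, dtype=object)
    for c in ("uninjured", "chronic"):
        m = cond == c
        labels[m] = zonate.classify_zonation(
            scaled[m], lognorm[m], adata.var_names, sig, seed=seed + 2).labels

    col = zonate.score_signature(lognorm, adata.var_names, zonate.COLLAGEN_GENES,
                                 "collagen")
    call = zonate.binarize_kmeans(col)
    myo = zonate.quantify_myofibroblast_zonation(call, labels)
    return {
        "cfg": cfg, "adata": adata, "truth": truth, "signature": sig,
        "labels": labels, "collagen_call": call, "myo": myo,
    }


@pytest.fixture(scope="session")
def injury_chain():
    """One seeded run of the injury quantification chain."""
    return run_injury_chain(0)
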