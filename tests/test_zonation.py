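"""Anchored ICA signature discovery, PaHSC/CaHSC classification, conservation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import zonate
from zonate.zonation import (
    ICAResult,
    ZonationSignature,
    classify_zonation,
    extract_zonation_signature,
    profile_consistency,
    run_ica,
    select_anchor_component,
)


def mixed_sources(seed=0, n_cells=400, n_genes=50):
    """Two independent non-Gaussian gradients mixed into genes."""
    rng = np.random.default_rng(seed)
    s1 = rng.uniform(-1, 1, n_cells)
    s2 = rng.uniform(-1, 1, n_cells) ** 3
    A = rng.standard_normal((2, n_genes))
    X = np.outer(s1, A[0]) + np.outer(s2, A[1]) + 0.05 * rng.standard_normal((n_cells, n_genes))
    X = (X - X.mean(0)) / X.std(0)
    return X, s1, s2


# ---------------------------------------------------------------- ICA


def test_ica_blind_source_separation():
    X, s1, s2 = mixed_sources()
    res = run_ica(X, [f"g{i}" for i in range(X.shape[1])], n_components=2, seed=0)
    cors = np.abs(np.corrcoef(np.column_stack([s1, s2, res.scores]).T)[:2, 2:])
    # each source matched by exactly one component
    assert cors.max(axis=1).min() > 0.95


def test_ica_determinism_and_unit_norm():
    X, *_ = mixed_sources(seed=1)
    genes = [f"g{i}" for i in range(X.shape[1])]
    r1 = run_ica(X, genes, n_components=3, seed=42)
    r2 = run_ica(X, genes, n_components=3, seed=42)
    np.testing.assert_array_equal(r1.scores, r2.scores)
    np.testing.assert_array_equal(r1.loadings, r2.loadings)
    np.testing.assert_allclose(np.linalg.norm(r1.loadings, axis=0), 1.0, atol=1e-8)


# ---------------------------------------------------------------- anchor


def test_anchor_selects_correct_planted_factor():
    """Anchor loaded on gradient B only -> B's component is selected."""
    rng = np.random.default_rng(2)
    n = 500
    sA = rng.uniform(-1, 1, n)
    sB = rng.uniform(-1, 1, n)
    genes = [f"g{i}" for i in range(40)] + ["Anchor"]
    X = np.zeros((n, 41))
    X[:, :20] += np.outer(sA, rng.standard_normal(20))
    X[:, 20:40] += np.outer(sB, rng.standard_normal(20))
    X[:, 40] = 2 * sB
    X += 0.05 * rng.standard_normal(X.shape)
    Xs = (X - X.mean(0)) / X.std(0)
    res = run_ica(Xs, genes, n_components=2, seed=0)
    anchor_expr = (2 * sB - (2 * sB).min())[:, None]   # nonnegative "expression"
    comp, orient = select_anchor_component(res, anchor_expr.repeat(41, 1), genes,
                                           anchor_gene="Anchor")
    assert abs(spearmanr(res.scores[:, comp], sB).statistic) > 0.9
    # orientation contract: anchor loading positive, score correlation >= 0
    w = orient * res.loadings[:, comp]
    assert w[genes.index("Anchor")] > 0
    assert spearmanr(orient * res.scores[:, comp], 2 * sB).statistic > 0


def test_anchor_error_cases():
    res = ICAResult(scores=np.zeros((5, 1)), loadings=np.ones((2, 1)),
                    gene_names=["a", "b"], n_components=1, seed=0)
    with pytest.raises(ValueError, match="absent"):
        select_anchor_component(res, np.zeros((5, 2)), ["a", "b"], anchor_gene="zz")
    with pytest.raises(ValueError, match="all-zero"):
        select_anchor_component(res, np.zeros((5, 2)), ["a", "b"], anchor_gene="a")


# ---------------------------------------------------------------- extraction


def hand_ica(loadings):
    loadings = np.asarray(loadings, dtype=float)[:, None]
    loadings = loadings / np.linalg.norm(loadings)
    return ICAResult(scores=np.zeros((10, 1)), loadings=loadings,
                     gene_names=[f"g{i}" for i in range(loadings.shape[0])],
                     n_components=1, seed=0)


def test_extraction_on_hand_built_loadings():
    """Two extreme genes against a tight null background are extracted."""
    w = [3.0, -3.0] + [0.01 * ((-1) ** i) for i in range(40)]
    sig = extract_zonation_signature(hand_ica(w), 0, 1, anchor_gene="g0")
    assert sig.portal_genes == ["g0"]
    assert sig.central_genes == ["g1"]


def test_extraction_orders_by_loading_magnitude():
    rng = np.random.default_rng(0)
    w = [3.0, 2.0, -2.5, -3.5] + list(0.01 * rng.standard_normal(30))
    sig = extract_zonation_signature(hand_ica(w), 0, 1, anchor_gene="g0")
    assert sig.portal_genes == ["g0", "g1"]
    assert sig.central_genes == ["g3", "g2"]


def test_extraction_empty_side_raises():
    w = [3.0, 2.5] + [0.01] * 30                   # nothing on the negative side
    with pytest.raises(ValueError, match="empty"):
        extract_zonation_signature(hand_ica(w), 0, 1)


def test_signature_recovery_on_default_simulation(uninjured_hsc, discovered_signature):
    """The anchored component yields the two opposed implanted programs."""
    cfg = uninjured_hsc["cfg"]
    sig = discovered_signature["signature"]
    P, C = set(sig.portal_genes), set(sig.central_genes)
    pt, ct = set(cfg.portal_genes), set(cfg.central_genes)
    assert len(P & pt) / len(P) >= 0.9 and len(P & pt) / len(pt) >= 0.9
    assert len(C & ct) / len(C) >= 0.9 and len(C & ct) / len(ct) >= 0.9
    assert "Ngfr" in sig.portal_genes              # anchor on the portal side
    assert set(sig.genes) == P | C and not P & C


# ---------------------------------------------------------------- classification


def test_classification_of_duplicated_prototypes():
    rng = np.random.default_rng(3)
    genes = [f"p{i}" for i in range(5)] + [f"c{i}" for i in range(5)]
    proto_portal = np.array([3.0] * 5 + [0.0] * 5)
    proto_central = np.array([0.0] * 5 + [3.0] * 5)
    lognorm = np.vstack([proto_portal] * 30 + [proto_central] * 30)
    scaled = (lognorm - lognorm.mean(0)) / lognorm.std(0)
    sig = ZonationSignature("p0", 0, genes[:5], [1.0] * 5, genes[5:], [-1.0] * 5, 3.5)
    call = classify_zonation(scaled + 1e-6 * rng.standard_normal(scaled.shape),
                             lognorm, genes, sig, seed=0)
    assert list(call.labels[:30]) == ["PaHSC"] * 30
    assert list(call.labels[30:]) == ["CaHSC"] * 30
    assert call.portal_score[call.labels == "PaHSC"].mean() > \
        call.portal_score[call.labels == "CaHSC"].mean()


def test_classification_accuracy_against_z_truth(uninjured_hsc, discovered_signature):
    a = uninjured_hsc["adata"]
    call = classify_zonation(np.asarray(a.layers["scaled"]), a.layers["lognorm"],
                             a.var_names, discovered_signature["signature"], seed=0)
    z = uninjured_hsc["truth"]["z"].values
    acc = (np.where(z < 0.5, "PaHSC", "CaHSC") == call.labels).mean()
    assert acc >= 0.95


def test_classification_invariant_to_gene_order_and_padding(uninjured_hsc,
                                                            discovered_signature):
    a = uninjured_hsc["adata"]
    sig = discovered_signature["signature"]
    scaled = np.asarray(a.layers["scaled"])
    lognorm = np.asarray(a.layers["lognorm"].todense())
    base = classify_zonation(scaled, lognorm, a.var_names, sig, seed=0)
    rng = np.random.default_rng(4)
    perm = rng.permutation(a.n_vars)
    permuted = classify_zonation(scaled[:, perm], lognorm[:, perm],
                                 list(np.array(a.var_names)[perm]), sig, seed=0)
    np.testing.assert_array_equal(base.labels, permuted.labels)
    # adding non-signature genes changes nothing
    padded = classify_zonation(
        np.hstack([scaled, rng.standard_normal((a.n_obs, 3))]),
        np.hstack([lognorm, np.abs(rng.standard_normal((a.n_obs, 3)))]),
        list(a.var_names) + ["padA", "padB", "padC"], sig, seed=0)
    np.testing.assert_array_equal(base.labels, padded.labels)


def test_truth_signature_classifies_at_least_as_well(uninjured_hsc,
                                                     discovered_signature):
    """Swapping the recovered gene lists for the implanted truth does not
    improve accuracy (extraction sanity)."""
    a = uninjured_hsc["adata"]
    cfg = uninjured_hsc["cfg"]
    z = uninjured_hsc["truth"]["z"].values
    truth_lab = np.where(z < 0.5, "PaHSC", "CaHSC")
    scaled = np.asarray(a.layers["scaled"])
    rec = classify_zonation(scaled, a.layers["lognorm"], a.var_names,
                            discovered_signature["signature"], seed=0)
    sig_true = ZonationSignature(
        "Ngfr", 0, list(cfg.portal_genes), [1.0] * 52,
        list(cfg.central_genes), [-1.0] * 29, 3.5)
    tru = classify_zonation(scaled, a.layers["lognorm"], a.var_names,
                            sig_true, seed=0)
    acc_rec = (rec.labels == truth_lab).mean()
    acc_tru = (tru.labels == truth_lab).mean()
    assert acc_tru >= acc_rec - 0.01


def test_classification_error_cases(discovered_signature):
    sig = discovered_signature["signature"]
    with pytest.raises(ValueError, match="at least 10"):
        classify_zonation(np.ones((5, 3)), np.ones((5, 3)), ["a", "b", "c"], sig)
    with pytest.raises(ValueError, match="no signature gene"):
        classify_zonation(np.ones((20, 2)), np.ones((20, 2)), ["x", "y"], sig)


# ---------------------------------------------------------------- conservation


def test_profile_consistency_on_conserved_and_perturbed_genes(injury_chain):
    """Conserved implanted genes test consistent along the portal-score
    ordering of chronic cells; killing a gene's zonal effect flags it."""
    a = injury_chain["adata"]
    sig = injury_chain["signature"]
    cond = a.obs["condition"].astype(str).values
    m = cond == "chronic"
    lognorm = np.asarray(a.layers["lognorm"].todense())[m]
    portal = zonate.score_signature(lognorm, a.var_names, sig.portal_genes,
                                    barcodes=list(a.obs_names[m]))
    ordering = zonate.order_cells(portal, descending=True)
    tab = profile_consistency(lognorm, a.var_names, ordering.positions, sig)
    assert tab["consistent"].mean() >= 0.95

    # permuted ordering: consistency collapses to noise
    rng = np.random.default_rng(5)
    tab0 = profile_consistency(lognorm, a.var_names,
                               rng.permutation(ordering.positions), sig)
    assert tab0["consistent"].mean() <= 0.10

    # flatten one implanted portal gene -> flagged inconsistent
    flat = lognorm.copy()
    j = list(a.var_names).index(sig.portal_genes[1])
    flat[:, j] = rng.permutation(flat[:, j])
    tab1 = profile_consistency(flat, a.var_names, ordering.positions, sig)
    assert not tab1.set_index("gene").loc[sig.portal_genes[1], "consistent"]
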