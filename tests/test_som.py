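"""SOM metagene training, per-cell signature selection, spot retention."""

import numpy as np
import pandas as pd
import pytest

import zonate
from zonate.som import (
    MetageneMatrix,
    filter_population_signatures,
    metagene_expression,
    select_cell_signatures,
    train_som,
)


@pytest.fixture(scope="module")
def planted_blocks():
    """Two 50-gene blocks with opposite cell patterns + 40 background genes,
    per-gene standardized (three cluster labels for retention tests)."""
    rng = np.random.default_rng(0)
    n_cells = 150
    pat_a = np.repeat([1.0, -1.0, 0.0], 50)
    pat_b = np.repeat([-1.0, 1.0, 0.0], 50)
    X = np.zeros((n_cells, 140))
    for j in range(50):
        X[:, j] = pat_a + 0.3 * rng.standard_normal(n_cells)
    for j in range(50, 100):
        X[:, j] = pat_b + 0.3 * rng.standard_normal(n_cells)
    for j in range(100, 140):
        X[:, j] = 0.3 * rng.standard_normal(n_cells)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    genes = [f"g{j}" for j in range(140)]
    labels = np.array(["A"] * 50 + ["B"] * 50 + ["C"] * 50)
    model = zonate.train_som(X, genes, grid=(8, 8), epochs=50, seed=1)
    return {"X": X, "genes": genes, "labels": labels, "model": model}


# ---------------------------------------------------------------- training


def test_blocks_map_to_separated_regions(planted_blocks):
    model = planted_blocks["model"]
    coords = model.unit_coords()
    ca = coords[model.gene_assignment[:50]].mean(axis=0)
    cb = coords[model.gene_assignment[50:100]].mean(axis=0)
    assert np.linalg.norm(ca - cb) >= 4.0      # >= half the 8x8 grid


def test_training_deterministic(planted_blocks):
    m2 = zonate.train_som(planted_blocks["X"], planted_blocks["genes"],
                          grid=(8, 8), epochs=50, seed=1)
    np.testing.assert_array_equal(planted_blocks["model"].gene_assignment,
                                  m2.gene_assignment)
    np.testing.assert_array_equal(planted_blocks["model"].codebook, m2.codebook)


def test_quantization_error_non_increasing(planted_blocks):
    qe = planted_blocks["model"].quantization_errors
    assert np.all(np.diff(qe) <= 1e-6)


def test_degenerate_input_warns_single_unit():
    X = np.ones((20, 30))
    with pytest.warns(UserWarning):
        model = train_som(X, [f"g{i}" for i in range(30)], grid=(4, 4), epochs=5, seed=0)
    assert np.unique(model.gene_assignment).size == 1


def test_small_gene_count_warns():
    rng = np.random.default_rng(1)
    with pytest.warns(UserWarning, match="grid is larger"):
        train_som(rng.standard_normal((10, 5)), list("abcde"), grid=(4, 4),
                  epochs=5, seed=0)


# ---------------------------------------------------------------- metagenes


def test_single_gene_unit_equals_gene_row(planted_blocks):
    model = planted_blocks["model"]
    X = planted_blocks["X"]
    mm = metagene_expression(model, X)
    counts = np.bincount(model.gene_assignment,
                         minlength=model.grid_shape[0] * model.grid_shape[1])
    singles = np.where(counts == 1)[0]
    if singles.size:
        u = singles[0]
        g = int(np.where(model.gene_assignment == u)[0][0])
        np.testing.assert_allclose(mm.e[u], X[:, g])


def test_metagene_hand_arithmetic():
    # two genes on one unit with values 0.2 and 0.8 in a cell -> e = 0.5
    model = zonate.SOMModel(
        grid_shape=(1, 2), codebook=np.zeros((2, 1)),
        gene_assignment=np.array([0, 0, 1]), gene_names=["a", "b", "c"],
        quantization_errors=np.zeros(1), epochs=0, seed=0)
    X = np.array([[0.2, 0.8, 0.4]])
    mm = metagene_expression(model, X)
    assert mm.e[0, 0] == pytest.approx(0.5)
    assert mm.e[1, 0] == pytest.approx(0.4)
    assert mm.e_max[0] == pytest.approx(0.5)


def test_duplicate_gene_mean_invariance():
    model = zonate.SOMModel(
        grid_shape=(1, 2), codebook=np.zeros((2, 1)),
        gene_assignment=np.array([0, 0, 1]), gene_names=["a", "a2", "c"],
        quantization_errors=np.zeros(1), epochs=0, seed=0)
    X = np.array([[0.7, 0.7, 0.1]])
    mm = metagene_expression(model, X)
    assert mm.e[0, 0] == pytest.approx(0.7)


def test_empty_units_excluded_from_e_max():
    model = zonate.SOMModel(
        grid_shape=(2, 2), codebook=np.zeros((4, 1)),
        gene_assignment=np.array([0, 0]), gene_names=["a", "b"],
        quantization_errors=np.zeros(1), epochs=0, seed=0)
    mm = metagene_expression(model, np.array([[0.3, 0.5]]))
    assert np.isnan(mm.e[1, 0]) and np.isnan(mm.e[3, 0])
    assert mm.e_max[0] == pytest.approx(0.4)


# ---------------------------------------------------------------- selection


def grid_mm(e, grid_shape, barcodes=None):
    e = np.asarray(e, dtype=float)
    return MetageneMatrix(e=e, e_max=np.nanmax(e, axis=0),
                          grid_shape=grid_shape, barcodes=barcodes)


def test_selection_threshold_arithmetic():
    # metagene values (1.0, 0.96, 0.90) -> first two units selected
    mm = grid_mm(np.array([[1.0], [0.96], [0.90]]), (1, 3))
    sel = select_cell_signatures(mm)
    assert sel.loc[0, "selected_units"] == (0, 1)


def test_argmax_always_selected_and_ratio_contract():
    rng = np.random.default_rng(2)
    e = np.abs(rng.standard_normal((16, 25)))
    mm = grid_mm(e, (4, 4))
    sel = select_cell_signatures(mm, ratio=0.95)
    for c, row in sel.iterrows():
        units = row["selected_units"]
        assert int(np.argmax(e[:, c])) in units
        assert min(e[u, c] / e[:, c].max() for u in units) >= 0.95


def test_nonpositive_emax_selects_nothing():
    mm = grid_mm(np.array([[-1.0], [-0.5]]), (1, 2))
    sel = select_cell_signatures(mm)
    assert sel.loc[0, "selected_units"] == ()


def test_selection_scale_invariant_per_cell():
    rng = np.random.default_rng(3)
    e = np.abs(rng.standard_normal((9, 10)))
    s1 = select_cell_signatures(grid_mm(e, (3, 3)))
    s2 = select_cell_signatures(grid_mm(e * 7.3, (3, 3)))
    assert list(s1["selected_units"]) == list(s2["selected_units"])


# ---------------------------------------------------------------- retention


def hand_selection(frac_a, n_a=10, n_b=10):
    """Cluster A selects spot 0 in round(frac_a * n_a) cells; B never does."""
    k = round(frac_a * n_a)
    rows = [((0,), (0,))] * k + [((5,), (5,))] * (n_a - k) + [((5,), (5,))] * n_b
    sel = pd.DataFrame(rows, columns=["selected_units", "spots"])
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    return sel, labels


def test_retention_rule_exact_on_hand_fixtures():
    sel, labels = hand_selection(0.40)
    retained, prev = filter_population_signatures(sel, labels)
    assert 0 in retained                       # 40% of cluster A -> kept
    assert prev.loc[0, "A"] == pytest.approx(0.40)
    sel, labels = hand_selection(0.29, n_a=100, n_b=100)
    retained, _ = filter_population_signatures(sel, labels)
    assert 0 not in retained                   # 29% max anywhere -> dropped


def test_retention_monotone_in_threshold():
    sel, labels = hand_selection(0.40)
    kept_30, _ = filter_population_signatures(sel, labels, min_fraction=0.30)
    kept_10, _ = filter_population_signatures(sel, labels, min_fraction=0.10)
    assert set(kept_30) <= set(kept_10)


def test_planted_blocks_recovered_as_spots(planted_blocks):
    """Each cluster retains a spot whose gene content overlaps its
    implanted block with Jaccard >= 0.5."""
    model = planted_blocks["model"]
    X = planted_blocks["X"]
    mm = metagene_expression(model, X)
    sel = select_cell_signatures(mm)
    retained, prev = filter_population_signatures(sel, planted_blocks["labels"])
    spot_units = sel.attrs["spot_units"]
    blocks = {"A": set(planted_blocks["genes"][:50]),
              "B": set(planted_blocks["genes"][50:100])}
    for cl in ("A", "B"):
        best = 0.0
        for s in retained:
            units = set(spot_units[s])
            gset = {planted_blocks["genes"][i] for i in range(140)
                    if model.gene_assignment[i] in units}
            j = len(gset & blocks[cl]) / len(gset | blocks[cl])
            best = max(best, j if prev.loc[s, cl] >= 0.30 else 0.0)
        assert best >= 0.5
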