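"""Self-organizing-map metagenes and per-cell signature spots.

Genes are the mapped items and cells the feature space: a rectangular
Kohonen grid is batch-trained on the gene vectors of the scaled expression
matrix, each grid unit's metagene expression in a cell is the mean scaled
expression of the genes assigned to it, and a cell's expressed signatures
are the units within 95% of its maximal metagene (e >= 0.95 * e_max),
grouped into contiguous map "spots".  A spot is retained for population
analysis when at least 30% of the cells of some cluster select it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SOMModel",
    "MetageneMatrix",
    "train_som",
    "metagene_expression",
    "select_cell_signatures",
    "filter_population_signatures",
]


@dataclass
class SOMModel:
    grid_shape: tuple[int, int]
    codebook: np.ndarray                  # units x features(cells)
    gene_assignment: np.ndarray           # gene -> unit index (row-major)
    gene_names: list[str]
    quantization_errors: np.ndarray       # per epoch
    epochs: int
    seed: int

    def unit_coords(self) -> np.ndarray:
        r, c = self.grid_shape
        return np.array([(i // c, i % c) for i in range(r * c)])


@dataclass
class MetageneMatrix:
    e: np.ndarray                         # units x cells, NaN for empty units
    e_max: np.ndarray                     # per cell, over non-empty units
    grid_shape: tuple[int, int]
    barcodes: list[str] | None = None


def train_som(
    scaled, gene_names, grid: tuple[int, int] = (20, 20), epochs: int = 100,
    seed: int = 0,
) -> SOMModel:
    """Batch Kohonen training of unit codebooks over gene vectors.

    ``scaled`` is cells x genes; internally genes are the training items
    (feature dimension = cells).  Gaussian neighborhood with radius decaying
    linearly from max(grid)/2 to 1 over the epochs; codebooks start at the
    data centroid plus small seeded noise (so the annealed batch updates
    refine monotonically); assignment is nearest codebook by Euclidean
    distance.
    """
    X = np.asarray(scaled, dtype=np.float64).T  # genes x cells
    n_genes, n_feat = X.shape
    rows, cols = grid
    n_units = rows * cols
    if n_genes < n_units:
        warnings.warn(
            f"{n_genes} genes for {n_units} SOM units; grid is larger than the data"
        )
    if np.allclose(X, X[0]):
        warnings.warn("degenerate input: all genes identical; mapped to one unit")
    rng = np.random.default_rng(seed)
    # mean-centered initialization: starting at the data centroid keeps the
    # annealed batch updates strictly refining (monotone quantization error)
    data_sd = X.std() if X.std() > 0 else 1.0
    W = X.mean(axis=0)[None, :] + 0.01 * data_sd * rng.standard_normal((n_units, n_feat))
    coords = np.array([(i // cols, i % cols) for i in range(n_units)], dtype=np.float64)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)  # units x units

    x_sq = (X**2).sum(axis=1)
    r_max, r_min = max(grid) / 2.0, 1.0
    qes = []
    bmu = np.zeros(n_genes, dtype=int)
    for epoch in range(epochs):
        radius = r_max + (r_min - r_max) * (epoch / max(epochs - 1, 1))
        d2 = x_sq[:, None] + (W**2).sum(axis=1)[None, :] - 2.0 * X @ W.T
        bmu = np.argmin(d2, axis=1)
        qes.append(float(np.sqrt(np.maximum(d2[np.arange(n_genes), bmu], 0.0)).mean()))
        H = np.exp(-grid_d2[:, bmu] / (2.0 * radius**2))  # units x genes
        denom = H.sum(axis=1)
        num = H @ X
        nonzero = denom > 1e-12
        W[nonzero] = num[nonzero] / denom[nonzero, None]
    d2 = x_sq[:, None] + (W**2).sum(axis=1)[None, :] - 2.0 * X @ W.T
    bmu = np.argmin(d2, axis=1)
    qes.append(float(np.sqrt(np.maximum(d2[np.arange(n_genes), bmu], 0.0)).mean()))
    return SOMModel(
        grid_shape=grid, codebook=W, gene_assignment=bmu, gene_names=list(gene_names),
        quantization_errors=np.asarray(qes), epochs=epochs, seed=seed,
    )


def metagene_expression(model: SOMModel, scaled, barcodes=None) -> MetageneMatrix:
    """Per-unit metagene expression: mean scaled expression of its genes.

    Units with no assigned gene carry NaN and are excluded from ``e_max``.
    """
    X = np.asarray(scaled, dtype=np.float64).T  # genes x cells
    if X.shape[0] != len(model.gene_names):
        raise ValueError("scaled matrix does not match the trained gene set")
    n_units = model.grid_shape[0] * model.grid_shape[1]
    e = np.full((n_units, X.shape[1]), np.nan)
    counts = np.bincount(model.gene_assignment, minlength=n_units)
    if counts.sum() == 0:
        raise ValueError("no gene assigned to any unit")
    sums = np.zeros((n_units, X.shape[1]))
    np.add.at(sums, model.gene_assignment, X)
    occ = counts > 0
    e[occ] = sums[occ] / counts[occ, None]
    e_max = np.nanmax(e, axis=0)
    return MetageneMatrix(e=e, e_max=e_max, grid_shape=model.grid_shape,
                         barcodes=list(barcodes) if barcodes is not None else None)


def _connected_spots(units: np.ndarray, grid_shape: tuple[int, int]) -> list[list[int]]:
    """Group selected unit indices into 8-connected components on the grid."""
    rows, cols = grid_shape
    unit_set = set(int(u) for u in units)
    seen: set[int] = set()
    comps = []
    for u in sorted(unit_set):
        if u in seen:
            continue
        stack, comp = [u], []
        seen.add(u)
        while stack:
            v = stack.pop()
            comp.append(v)
            r, c = divmod(v, cols)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    w = rr * cols + cc
                    if 0 <= rr < rows and 0 <= cc < cols and w in unit_set and w not in seen:
                        seen.add(w)
                        stack.append(w)
        comps.append(sorted(comp))
    return comps


def select_cell_signatures(mm: MetageneMatrix, ratio: float = 0.95) -> pd.DataFrame:
    """Per-cell selected metagene units and their grouping into map spots.

    Unit u is selected for cell c iff ``e(u,c) >= ratio * e_max(c)`` (cells
    with ``e_max <= 0`` select nothing, logged).  Spots are global map
    regions: the 8-connected components of the union of selected units over
    all cells; a spot's id is its lexicographically smallest member unit.
    A cell expresses every spot its selected units touch.  Returns one row
    per cell with columns ``selected_units`` (tuple) and ``spots`` (tuple of
    spot ids); the spot -> unit-set map is attached as ``result.attrs["spot_units"]``.
    """
    n_cells = mm.e.shape[1]
    per_cell = []
    union: set[int] = set()
    for c in range(n_cells):
        emax = mm.e_max[c]
        if not np.isfinite(emax) or emax <= 0:
            logger.info("cell %d has e_max <= 0; no signature selected", c)
            per_cell.append(())
            continue
        sel = np.where(np.nan_to_num(mm.e[:, c], nan=-np.inf) >= ratio * emax)[0]
        per_cell.append(tuple(int(u) for u in sel))
        union.update(int(u) for u in sel)
    comps = _connected_spots(np.array(sorted(union), dtype=int), mm.grid_shape)
    spot_of_unit = {u: comp[0] for comp in comps for u in comp}
    rows = [
        (sel, tuple(sorted({spot_of_unit[u] for u in sel})))
        for sel in per_cell
    ]
    out = pd.DataFrame(rows, columns=["selected_units", "spots"])
    if mm.barcodes is not None:
        out.index = pd.Index(mm.barcodes, name="barcode")
    out.attrs["spot_units"] = {comp[0]: tuple(comp) for comp in comps}
    return out


def filter_population_signatures(
    selections: pd.DataFrame, labels, min_fraction: float = 0.30
) -> tuple[list[int], pd.DataFrame]:
    """Retain spots selected by >= min_fraction of the cells of some cluster.

    Returns ``(retained_spot_ids, prevalence)`` where prevalence is a
    spot x cluster table of selection fractions.  Empty clusters are
    excluded from the quantifier (logged).
    """
    labels = np.asarray(labels)
    if len(labels) != len(selections):
        raise ValueError("labels are not aligned to the selection table")
    clusters = [c for c in pd.unique(labels)]
    all_spots = sorted({s for spots in selections["spots"] for s in spots})
    prev = pd.DataFrame(0.0, index=pd.Index(all_spots, name="spot"), columns=clusters)
    for cl in clusters:
        mask = labels == cl
        size = int(mask.sum())
        if size == 0:
            logger.info("cluster %r is empty; excluded from retention", cl)
            continue
        counts = {}
        for spots in selections.loc[mask, "spots"]:
            for s in spots:
                counts[s] = counts.get(s, 0) + 1
        for s, n in counts.items():
            prev.loc[s, cl] = n / size
    retained = [int(s) for s in all_spots if (prev.loc[s] >= min_fraction).any()]
    return retained, prev
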