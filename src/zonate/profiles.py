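"""Expression profiles along a 0-1 cell ordering and gene-module clustering.

Cells are ordered by a signature score (or an externally supplied position),
ranks are scaled to [0, 1], cubic smoothing splines (smoothing chosen by
generalized cross-validation) summarize each gene's profile on a uniform
grid, a spline-basis F-test flags genes whose expression changes along the
ordering, and hierarchical clustering of the smoothed profiles yields gene
modules with correlated dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import make_smoothing_spline
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .scoring import SignatureScore

logger = logging.getLogger(__name__)

__all__ = [
    "CellOrdering",
    "GeneProfiles",
    "order_cells",
    "fit_gene_profiles",
    "test_profile_de",
    "cluster_gene_modules",
    "exclude_mito_ribo",
]


@dataclass
class CellOrdering:
    positions: np.ndarray          # per cell, in [0, 1]
    barcodes: list[str] | None
    source: str = "signature_score"


@dataclass
class GeneProfiles:
    profiles: np.ndarray           # genes x grid, each row min-max scaled
    grid: np.ndarray
    genes: list[str]
    smoothing: str = "gcv"


def exclude_mito_ribo(genes) -> list[str]:
    """Drop mitochondrial (mt-) and ribosomal (Rps/Rpl) genes by name prefix."""
    out = []
    for g in genes:
        gl = g.lower()
        if gl.startswith("mt-") or gl.startswith("rps") or gl.startswith("rpl"):
            continue
        out.append(g)
    return out


def order_cells(score: SignatureScore, descending: bool = True) -> CellOrdering:
    """Rank cells by signature score and scale the ranks linearly to [0, 1].

    With ``descending=True`` (the default used for zonation profiles) the
    highest-scoring cell sits at position 0.  Ties are broken
    deterministically by barcode (or by input order when barcodes are
    absent).  All-equal scores are an error: there is no ordering.
    """
    s = np.asarray(score.scaled, dtype=np.float64)
    if s.size < 2:
        raise ValueError("need at least 2 cells to order")
    if np.all(s == s[0]):
        raise ValueError("all scores identical: no ordering defined")
    keys = score.barcodes if score.barcodes is not None else [f"{i:09d}" for i in range(s.size)]
    sort_idx = sorted(range(s.size), key=lambda i: (-s[i] if descending else s[i], keys[i]))
    positions = np.empty(s.size)
    positions[np.asarray(sort_idx)] = np.linspace(0.0, 1.0, s.size)
    return CellOrdering(positions=positions, barcodes=score.barcodes)


def fit_gene_profiles(
    lognorm, gene_names, ordering: CellOrdering, genes, grid_size: int = 100
) -> GeneProfiles:
    """Cubic smoothing splines (GCV) of expression along the ordering.

    One spline per gene, evaluated on a uniform grid over [0, 1] and
    min-max scaled per gene.  Constant genes give a flat profile at 0
    (logged).  The caller excludes mitochondrial/ribosomal genes
    (see :func:`exclude_mito_ribo`) when emulating trajectory heatmaps.
    """
    x = np.asarray(ordering.positions, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 cells to fit profiles")
    order = np.argsort(x)
    xs = x[order]
    X = lognorm
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    gene_names = list(gene_names)
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    kept = []
    for g in genes:
        if g not in gene_names:
            logger.warning("fit_gene_profiles: %s absent from matrix, skipped", g)
            continue
        y = X[:, gene_names.index(g)].ravel()[order]
        if np.all(y == y[0]):
            logger.info("fit_gene_profiles: %s constant, flat profile", g)
            rows.append(np.zeros(grid_size))
            kept.append(g)
            continue
        spl = make_smoothing_spline(xs, y)
        prof = spl(grid)
        lo, hi = prof.min(), prof.max()
        rows.append((prof - lo) / (hi - lo) if hi - lo > 1e-15 else np.zeros(grid_size))
        kept.append(g)
    if not rows:
        raise ValueError("no requested gene present in the matrix")
    return GeneProfiles(profiles=np.vstack(rows), grid=grid, genes=kept)


def _natural_cubic_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic regression-spline basis (df columns, no intercept)."""
    # boundary knots at min/max, df-1 interior knots at quantiles
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, probs)
    knots = np.unique(knots)
    if knots.size < 3:  # degenerate spread: fall back to polynomial basis
        return np.vstack([x, x**2, x**3]).T[:, :df]
    bk_lo, bk_hi = knots[0], knots[-1]
    inner = knots[1:-1]
    all_knots = np.concatenate([[bk_lo], inner, [bk_hi]])

    def d(k_idx: int) -> np.ndarray:
        num = np.maximum(x - all_knots[k_idx], 0) ** 3 - np.maximum(x - bk_hi, 0) ** 3
        return num / (bk_hi - all_knots[k_idx])

    cols = [x]
    K = all_knots.size
    for j in range(K - 2):
        cols.append(d(j) - d(K - 2))
    B = np.vstack(cols).T
    return B[:, :df]


def test_profile_de(
    lognorm, gene_names, ordering: CellOrdering, genes=None, q_threshold: float = 1e-20
) -> pd.DataFrame:
    """F-test of a natural-cubic-spline trend (3 df) per gene along the ordering.

    Compares the spline-basis regression of expression on position against
    the intercept-only model; Benjamini-Hochberg adjustment over the tested
    genes; ``significant = q <= q_threshold`` (the stringent trajectory
    cut).  Constant genes get q = 1.
    """
    x = np.asarray(ordering.positions, dtype=np.float64)
    n = x.size
    if n < 30:
        raise ValueError("need at least 30 cells for the profile DE test")
    X = lognorm
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    gene_names = list(gene_names)
    if genes is None:
        genes = gene_names
    idx = [gene_names.index(g) for g in genes if g in gene_names]
    kept = [g for g in genes if g in gene_names]
    Y = X[:, idx]

    B = _natural_cubic_basis(x, df=3)
    D = np.column_stack([np.ones(n), B])
    p_model = D.shape[1]
    if n <= p_model:
        raise ValueError("fewer cells than model degrees of freedom")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df1 = p_model - 1
    df2 = n - p_model
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    pvals = np.where(rss0 < 1e-30, 1.0, f_dist.sf(np.where(np.isfinite(F), F, 0.0), df1, df2))
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": kept, "F": F, "p": pvals, "q": qvals,
        "significant": qvals <= q_threshold,
    })


def cluster_gene_modules(p: GeneProfiles, k: int = 3) -> np.ndarray:
    """Hierarchical gene modules from smoothed profiles.

    Complete-linkage clustering on Euclidean distances between profile rows,
    tree cut at ``k``; module ids 0..k-1 are ordered by the grid position of
    the module-mean profile's maximum (early-peaking modules first).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(p.genes) < k:
        raise ValueError(f"need at least {k} genes for {k} modules")
    Z = linkage(p.profiles, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust") - 1
    peak = {}
    for c in np.unique(raw):
        peak[c] = p.grid[np.argmax(p.profiles[raw == c].mean(axis=0))]
    order = sorted(peak, key=lambda c: (peak[c], c))
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)
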