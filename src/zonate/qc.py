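"""Quality control, normalization, depth regression and HVG selection.

The preprocessing chain for droplet UMI counts:

1. per-cell QC metrics (detected genes, total UMI, mitochondrial fraction);
2. cell filter (>= 300 detected genes, <= 30% mitochondrial UMI) followed by
   a gene filter (expressed, i.e. count > 0, in >= 3 retained cells);
3. depth normalization ``ln(1e4 * count / total_UMI + 1)``;
4. per-gene negative-binomial regression of raw counts on log total UMI,
   Pearson residuals centered/standardized per gene and clipped;
5. highly variable genes by the binned mean/dispersion criterion.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "compute_qc_metrics",
    "filter_cells_genes",
    "normalize_log",
    "regress_and_scale",
    "select_hvg",
]


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    return sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell QC table: ``n_genes``, ``n_umi``, ``pct_mito`` (fraction in [0,1]).

    ``pct_mito`` of a zero-count cell is defined as 0.  A prefix matching no
    gene logs a warning and yields an all-zero ``pct_mito`` column.
    """
    X = _counts(adata)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    is_mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in adata.var_names])
    if not is_mito.any():
        logger.warning("no gene name matches mito prefix %r; pct_mito set to 0", mito_prefix)
        mito_umi = np.zeros_like(n_umi)
    else:
        mito_umi = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    qc = pd.DataFrame(
        {"n_genes": n_genes.astype(int), "n_umi": n_umi.astype(int), "pct_mito": pct_mito},
        index=adata.obs_names,
    )
    adata.obs[["n_genes", "n_umi", "pct_mito"]] = qc
    return qc


def filter_cells_genes(
    adata: ad.AnnData,
    qc: pd.DataFrame | None = None,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 300,
    max_pct_mito: float = 0.30,
) -> ad.AnnData:
    """Apply the cell filter, then the gene filter; returns a copy.

    Cells kept: ``n_genes >= min_genes_per_cell`` and ``pct_mito <= max_pct_mito``.
    Genes kept: count > 0 in at least ``min_cells_per_gene`` retained cells.
    """
    if qc is None:
        qc = compute_qc_metrics(adata)
    qc = qc.loc[adata.obs_names]
    keep_cells = (qc["n_genes"].values >= min_genes_per_cell) & (
        qc["pct_mito"].values <= max_pct_mito
    )
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filters")
    out = adata[keep_cells].copy()
    X = _counts(out)
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("all genes removed by QC filters")
    return out[:, keep_genes].copy()


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: ``ln(scale_factor * c / n_umi + 1)``.

    Stores the result in ``adata.layers["lognorm"]``; zero counts map to zero.
    """
    X = _counts(adata)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    if (n_umi == 0).any():
        raise ValueError("cells with zero total UMI present; run QC filtering first")
    norm = X.astype(np.float64).multiply(scale_factor / n_umi[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm
    return adata


def _nb_irls(y: np.ndarray, x: np.ndarray, n_iter: int = 25, tol: float = 1e-8):
    """Vectorized per-gene Poisson-mean IRLS of counts on a single covariate.

    ``y`` is genes x cells, ``x`` the shared covariate (log total UMI).
    Returns fitted means ``mu`` (genes x cells) and a converged mask.
    The mean model exp(b0 + b1*x) is shared between the Poisson and NB
    families (same score equations up to weights), so the NB Pearson
    residual is formed from this mean fit plus a moments dispersion.
    """
    n_genes, n_cells = y.shape
    gene_mean = y.mean(axis=1)
    b0 = np.log(np.maximum(gene_mean, 1e-8)) - x.mean()
    b1 = np.ones(n_genes)
    converged = np.zeros(n_genes, dtype=bool)
    xs = np.stack([np.ones_like(x), x])  # 2 x cells
    for _ in range(n_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        # weighted least squares with working response z = eta + (y-mu)/mu
        w = mu
        S0 = w.sum(axis=1)
        S1 = w @ x
        S2 = w @ (x * x)
        wz = w * eta + (y - mu)
        T0 = wz.sum(axis=1)
        T1 = wz @ x
        det = S0 * S2 - S1 * S1
        ok = det > 1e-12
        nb0 = np.where(ok, (S2 * T0 - S1 * T1) / np.where(ok, det, 1.0), b0)
        nb1 = np.where(ok, (S0 * T1 - S1 * T0) / np.where(ok, det, 1.0), b1)
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        converged = converged | (step < tol) | ~ok
        b0, b1 = nb0, nb1
        if converged.all():
            break
    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    bad = ~np.isfinite(mu).all(axis=1) | ~np.isfinite(b0) | ~np.isfinite(b1)
    return mu, ~bad & converged


def regress_and_scale(adata: ad.AnnData, clip_value: float = 10.0) -> ad.AnnData:
    """NB-regress sequencing depth out of each gene and z-score the residuals.

    Per gene: fit counts ~ NB(exp(b0 + b1 * log n_umi)) (IRLS mean fit with a
    method-of-moments dispersion), take Pearson residuals, center to mean 0 /
    sd 1, clip to ``+-clip_value``.  Zero-variance genes map to all-zero rows.
    Genes whose fit does not converge fall back to a linear regression of the
    log-normalized values on log n_umi (logged).

    Stores a dense genes-scaled matrix in ``adata.layers["scaled"]`` and
    records ``adata.var["regression_fallback"]``.
    """
    X = _counts(adata)
    Y = np.asarray(X.todense(), dtype=np.float64).T  # genes x cells
    n_umi = np.asarray(X.sum(axis=1)).ravel().astype(np.float64)
    if (n_umi == 0).any():
        raise ValueError("cells with zero total UMI present; run QC filtering first")
    x = np.log(n_umi)

    y_const = Y.std(axis=1) < 1e-12

    mu, converged = _nb_irls(Y, x)
    # moments dispersion alpha_g: Var = mu + alpha mu^2
    resid_sq = (Y - mu) ** 2
    alpha = np.maximum((resid_sq - mu).sum(axis=1), 0.0) / np.maximum(
        (mu**2).sum(axis=1), 1e-12
    )
    pearson = (Y - mu) / np.sqrt(mu + alpha[:, None] * mu**2)

    fallback = ~converged
    if fallback.any():
        logger.warning(
            "NB regression fallback to linear model for %d gene(s): %s",
            fallback.sum(), list(adata.var_names[fallback])[:10],
        )
        if "lognorm" not in adata.layers:
            normalize_log(adata)
        L = np.asarray(sp.csr_matrix(adata.layers["lognorm"]).todense()).T[fallback]
        xc = x - x.mean()
        beta = (L @ xc) / (xc @ xc)
        pearson[fallback] = L - L.mean(axis=1, keepdims=True) - beta[:, None] * xc[None, :]

    m = pearson.mean(axis=1, keepdims=True)
    s = pearson.std(axis=1, keepdims=True)
    zero_var = (s.ravel() < 1e-12) | ~np.isfinite(s.ravel()) | y_const
    s[zero_var.reshape(-1, 1)] = 1.0
    scaled = (pearson - m) / s
    scaled[zero_var] = 0.0
    scaled = np.clip(scaled, -clip_value, clip_value)

    adata.layers["scaled"] = scaled.T  # cells x genes
    adata.var["regression_fallback"] = fallback
    adata.uns["scaled_clip_value"] = float(clip_value)
    return adata


def select_hvg(
    adata: ad.AnnData,
    n_bins: int = 20,
    mean_low: float = 0.0125,
    mean_high: float = 3.0,
    dispersion_z: float = 0.5,
) -> list[str]:
    """Highly variable genes by binned mean/dispersion on the log-normalized layer.

    Genes are binned by mean expression; the dispersion (variance/mean on the
    exp scale) is z-scored within bins; returned genes satisfy
    mean in (mean_low, mean_high) and dispersion z > dispersion_z.
    Flags ``adata.var["highly_variable"]``.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_log first")
    tmp = ad.AnnData(
        X=sp.csr_matrix(adata.layers["lognorm"]),
        obs=adata.obs[[]].copy(),
        var=adata.var[[]].copy(),
    )
    sc.pp.highly_variable_genes(
        tmp, flavor="seurat", n_bins=n_bins,
        min_mean=mean_low, max_mean=mean_high, min_disp=dispersion_z,
    )
    adata.var["highly_variable"] = tmp.var["highly_variable"].values
    return list(adata.var_names[adata.var["highly_variable"]])
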