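"""Lineage clustering and AUC-classifier marker detection.

PCA on the scaled residual matrix, shared-nearest-neighbor (SNN) graph
clustering by modularity optimization, and cluster-vs-rest marker genes
ranked by ROC AUC with log-fold-change and detection-fraction filters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["Embedding", "run_pca", "cluster_snn", "find_markers_auc"]


@dataclass
class Embedding:
    """Cells x components coordinates with per-component variance fractions."""

    coords: np.ndarray
    variance_ratio: np.ndarray
    loadings: np.ndarray  # genes x components
    gene_names: list[str]


def run_pca(scaled: np.ndarray, n_components: int, gene_names=None) -> Embedding:
    """PCA of cells over genes (input cells x genes, already standardized).

    Deterministic: each component's sign is fixed so the gene with the
    largest |loading| has a positive loading.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = np.asarray(scaled, dtype=np.float64)
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # genes x comps
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            coords[:, k] *= -1
    names = list(gene_names) if gene_names is not None else [f"g{i}" for i in range(X.shape[1])]
    return Embedding(coords, pca.explained_variance_ratio_.copy(), loadings, names)


def _snn_graph(coords: np.ndarray, k_neighbors: int) -> sp.csr_matrix:
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(n * k_neighbors), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()  # |N(i) & N(j)|
    jacc = shared.data / (2 * k_neighbors - shared.data)
    keep = (shared.row < shared.col) & (jacc > 0)
    return sp.coo_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    ).tocsr()


def cluster_snn(
    embedding: Embedding | np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """SNN-graph modularity clustering of cells in embedding space.

    k-nearest-neighbor graph (self included) -> Jaccard shared-neighbor edge
    weights -> modularity community detection (RBConfiguration partition,
    seeded).  Labels are 0..K-1 ordered by decreasing cluster size.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = coords.shape[0]
    if n < k_neighbors + 1:
        raise ValueError(f"need >= {k_neighbors + 1} cells for k={k_neighbors} neighbors")
    if np.allclose(coords, coords[0]):
        warnings.warn("degenerate embedding (all points identical): single cluster")
        return np.zeros(n, dtype=int)
    W = _snn_graph(coords, k_neighbors)
    coo = W.tocoo()
    g = igraph.Graph(
        n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
    )
    raw = np.asarray(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in range(raw.max() + 1)], kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in raw], dtype=int)


def find_markers_auc(
    lognorm,
    gene_names,
    labels,
    cluster_id,
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
) -> pd.DataFrame:
    """Cluster-vs-rest marker genes by ROC AUC.

    Per gene: AUC of the log-normalized expression as a classifier of the
    cluster against all other cells (ties counted 1/2, the Mann-Whitney
    convention); ``log_fc = ln(mean(expm1(in)) + 1) - ln(mean(expm1(out)) + 1)``;
    ``pct_in``/``pct_out`` are detection (value > 0) fractions.  Returns genes
    with ``log_fc >= min_logfc`` and ``pct_in >= min_pct``, AUC descending.
    """
    labels = np.asarray(labels)
    in_grp = labels == cluster_id
    if not in_grp.any():
        raise ValueError(f"cluster {cluster_id!r} not present in labels")
    if in_grp.all():
        raise ValueError("comparison group is empty")
    X = lognorm
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    n1, n2 = int(in_grp.sum()), int((~in_grp).sum())
    ranks = rankdata(X, axis=0)  # average ranks over cells, per gene
    r1 = ranks[in_grp].sum(axis=0)
    auc = (r1 - n1 * (n1 + 1) / 2) / (n1 * n2)
    mean_in = np.expm1(X[in_grp]).mean(axis=0)
    mean_out = np.expm1(X[~in_grp]).mean(axis=0)
    log_fc = np.log(mean_in + 1) - np.log(mean_out + 1)
    pct_in = (X[in_grp] > 0).mean(axis=0)
    pct_out = (X[~in_grp] > 0).mean(axis=0)
    tab = pd.DataFrame(
        {
            "gene": list(gene_names),
            "auc": auc,
            "log_fc": log_fc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "cluster": cluster_id,
        }
    )
    tab = tab[(tab["log_fc"] >= min_logfc) & (tab["pct_in"] >= min_pct)]
    return tab.sort_values("auc", ascending=False).reset_index(drop=True)
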