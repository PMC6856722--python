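"""Reading and writing the CellRanger v2 MTX triplet and pipeline tables.

On disk the count matrix follows the CellRanger v2 layout: ``matrix.mtx``
(Matrix Market coordinate, integer, genes x cells, 1-based), ``genes.tsv``
(gene id TAB gene name) and ``barcodes.tsv``.  In memory counts live in an
AnnData (cells x genes).  ``conditions.tsv`` (barcode TAB condition) and the
simulator's ``truth.tsv`` travel alongside.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_counts_mtx", "write_counts_mtx", "write_truth", "read_truth"]


def read_counts_mtx(directory: str | Path) -> ad.AnnData:
    """Load a CellRanger v2 triplet (plus optional conditions.tsv).

    Raises ``FileNotFoundError`` for a missing member, ``ValueError`` on
    dimension mismatches, non-integer entries or duplicate names.
    """
    d = Path(directory)
    for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"{d / fname} is missing")
    m = scipy.io.mmread(d / "matrix.mtx")  # genes x cells on disk
    if not np.issubdtype(m.dtype, np.integer):
        data = np.asarray(m.data if sp.issparse(m) else m)
        if not np.allclose(data, np.round(data)):
            raise ValueError("matrix.mtx contains non-integer entries")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None, names=["gene_id", "gene_name"])
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None, names=["barcode"])
    if m.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {m.shape} but genes.tsv has {len(genes)} rows "
            f"and barcodes.tsv {len(barcodes)}"
        )
    if genes["gene_name"].duplicated().any():
        raise ValueError("duplicate gene names in genes.tsv")
    if barcodes["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in barcodes.tsv")
    X = sp.csr_matrix(m.T.astype(np.int64))
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes["barcode"], name="barcode")),
        var=pd.DataFrame(
            {"gene_id": genes["gene_id"].values},
            index=pd.Index(genes["gene_name"], name="gene_name"),
        ),
    )
    cond_path = d / "conditions.tsv"
    if cond_path.exists():
        cond = pd.read_csv(cond_path, sep="\t", header=None, names=["barcode", "condition"])
        cond = cond.set_index("barcode")["condition"]
        adata.obs["condition"] = cond.reindex(adata.obs_names).values
    return adata


def write_counts_mtx(adata: ad.AnnData, directory: str | Path) -> Path:
    """Write the CellRanger v2 triplet (+ conditions.tsv when present)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)  # genes x cells on disk
    scipy.io.mmwrite(str(d / "matrix.mtx"), X, field="integer")
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    pd.DataFrame({"gene_id": np.asarray(gene_ids), "gene_name": adata.var_names}).to_csv(
        d / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    if "condition" in adata.obs:
        pd.DataFrame(
            {"barcode": adata.obs_names, "condition": adata.obs["condition"].astype(str)}
        ).to_csv(d / "conditions.tsv", sep="\t", header=False, index=False)
    return d


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    """Write the simulator ground-truth table as TSV (lossless round-trip)."""
    if len(truth) == 0:
        raise ValueError("refusing to write an empty truth table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(
        Path(path), sep="\t",
        dtype={"barcode": str, "condition": str, "lineage": str},
    )
    for col in ("activated", "proliferating", "qc_fail"):
        if col in truth:
            truth[col] = truth[col].astype(bool)
    return truth
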