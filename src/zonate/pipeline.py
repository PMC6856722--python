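"""End-to-end pipeline: simulate/load -> QC -> cluster -> zonation -> quantify.

`run_pipeline` wires the stages of the mesenchyme zonation analysis into a
single deterministic run driven by a validated `RunConfig`: every random
draw flows from one global seed through named per-stage substreams, every
intermediate is written as TSV, and a machine-readable `summary.json`
collects the headline quantities (cluster sizes, signature gene lists,
PaHSC/CaHSC counts, the myofibroblast 2x2 table and CaHSC fraction,
retained SOM spots).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as zio
from . import qc as zqc
from .cluster import cluster_snn, find_markers_auc, run_pca
from .scoring import COLLAGEN_GENES, binarize_kmeans, quantify_myofibroblast_zonation, score_signature
from .simulate import SimConfig, simulate_dataset
from .som import filter_population_signatures, metagene_expression, select_cell_signatures, train_som
from .zonation import classify_zonation, extract_zonation_signature, run_ica, select_anchor_component

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), abs(hash_stable(stage))])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def hash_stable(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**61 - 1)
    return h


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    input_dir: str | None = None          # CellRanger triplet; None => simulate
    output_dir: str = "zonate_run"
    sim: dict = field(default_factory=dict)           # SimConfig overrides
    min_genes_per_cell: int = 300
    max_pct_mito: float = 0.30
    min_cells_per_gene: int = 3
    mito_prefix: str = "mt-"
    n_pcs: int = 10
    k_neighbors: int = 20
    resolution: float = 0.1
    run_clustering: bool = True
    anchor_gene: str = "Ngfr"
    n_ica_components: int = 10
    loading_sd: float = 3.5
    hsc_cluster: str | int | None = None  # None => all cells treated as HSCs
    signature_condition: str = "uninjured"
    collagen_genes: tuple[str, ...] = COLLAGEN_GENES
    run_som: bool = False
    som_grid: tuple[int, int] = (20, 20)
    som_epochs: int = 100
    som_ratio: float = 0.95
    som_min_fraction: float = 0.30

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
    }}
    logger.info("pipeline parameters: %s", summary["parameters"])

    # --- input ------------------------------------------------------------
    if config.input_dir is None:
        sim_cfg = SimConfig(**{"seed": stage_seed(config.seed, "simulate"), **config.sim})
        adata, truth = simulate_dataset(sim_cfg)
        zio.write_counts_mtx(adata, out / "counts")
        zio.write_truth(truth, out / "counts" / "truth.tsv")
    else:
        adata = zio.read_counts_mtx(config.input_dir)
    summary["n_cells_raw"] = int(adata.n_obs)
    summary["n_genes_raw"] = int(adata.n_vars)

    # --- QC / normalization ------------------------------------------------
    qc = zqc.compute_qc_metrics(adata, mito_prefix=config.mito_prefix)
    qc.to_csv(out / "qc_metrics.tsv", sep="\t")
    adata = zqc.filter_cells_genes(
        adata, qc, min_cells_per_gene=config.min_cells_per_gene,
        min_genes_per_cell=config.min_genes_per_cell, max_pct_mito=config.max_pct_mito,
    )
    zqc.normalize_log(adata)
    zqc.regress_and_scale(adata)
    hvg = zqc.select_hvg(adata)
    summary["n_cells_qc"] = int(adata.n_obs)
    summary["n_genes_qc"] = int(adata.n_vars)
    summary["n_hvg"] = len(hvg)
    pd.Series(hvg).to_csv(out / "hvg.tsv", sep="\t", index=False, header=False)

    scaled = np.asarray(adata.layers["scaled"])
    lognorm = adata.layers["lognorm"]
    hvg_mask = adata.var["highly_variable"].values

    # --- clustering ---------------------------------------------------------
    if config.run_clustering:
        emb = run_pca(scaled[:, hvg_mask], config.n_pcs, gene_names=np.array(hvg))
        labels = cluster_snn(emb, k_neighbors=config.k_neighbors,
                             resolution=config.resolution,
                             seed=stage_seed(config.seed, "cluster"))
        adata.obs["cluster"] = labels
        pd.DataFrame({"barcode": adata.obs_names, "cluster": labels}).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        summary["cluster_sizes"] = {
            str(c): int((labels == c).sum()) for c in np.unique(labels)
        }
        markers = pd.concat([
            find_markers_auc(lognorm, adata.var_names, labels, c)
            for c in np.unique(labels)
        ])
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        if config.hsc_cluster is not None:
            hsc_mask = labels == config.hsc_cluster
        else:
            hsc_mask = np.ones(adata.n_obs, dtype=bool)
    else:
        hsc_mask = np.ones(adata.n_obs, dtype=bool)

    # --- zonation signature (discovered on the reference condition) --------
    cond = adata.obs["condition"].astype(str).values if "condition" in adata.obs else \
        np.full(adata.n_obs, config.signature_condition)
    ref_mask = hsc_mask & (cond == config.signature_condition)
    if ref_mask.sum() < 10:
        raise ValueError(
            f"fewer than 10 HSCs in condition {config.signature_condition!r} "
            "for signature discovery")
    # the homeostatic reference is preprocessed on its own (its HVG set and
    # residual scaling are not distorted by injury-induced programs)
    ref = adata[ref_mask].copy()
    zqc.regress_and_scale(ref)
    ref_hvg = zqc.select_hvg(ref)
    ref_hvg_mask = ref.var["highly_variable"].values
    ica = run_ica(np.asarray(ref.layers["scaled"])[:, ref_hvg_mask], ref_hvg,
                  n_components=config.n_ica_components,
                  seed=stage_seed(config.seed, "ica"))
    comp, orient = select_anchor_component(
        ica, ref.layers["lognorm"], list(ref.var_names),
        anchor_gene=config.anchor_gene)
    sig = extract_zonation_signature(ica, comp, orient, threshold_sd=config.loading_sd,
                                     anchor_gene=config.anchor_gene)
    sig.to_frame().to_csv(out / "zonation_signature.tsv", sep="\t", index=False)
    summary["signature"] = {
        "component_index": int(comp),
        "n_portal": len(sig.portal_genes),
        "n_central": len(sig.central_genes),
        "portal_genes": sig.portal_genes,
        "central_genes": sig.central_genes,
    }

    # --- per-condition classification --------------------------------------
    call_labels = np.empty(adata.n_obs, dtype=object)
    portal_score = np.full(adata.n_obs, np.nan)
    central_score = np.full(adata.n_obs, np.nan)
    for c in pd.unique(cond):
        m = hsc_mask & (cond == c)
        if m.sum() < 10:
            logger.warning("condition %r has %d HSCs; skipped", c, int(m.sum()))
            continue
        call = classify_zonation(
            scaled[m], lognorm[m], adata.var_names, sig,
            seed=stage_seed(config.seed, f"classify-{c}"),
            barcodes=list(adata.obs_names[m]))
        call_labels[m] = call.labels
        portal_score[m] = call.portal_score
        central_score[m] = call.central_score
    called = pd.notna(call_labels)
    pd.DataFrame({
        "barcode": adata.obs_names[called], "condition": cond[called],
        "label": call_labels[called], "portal_score": portal_score[called],
        "central_score": central_score[called],
    }).to_csv(out / "zonation_calls.tsv", sep="\t", index=False)
    summary["zonation_counts"] = {
        str(c): {lab: int(((cond == c) & (call_labels == lab)).sum())
                 for lab in ("PaHSC", "CaHSC")}
        for c in pd.unique(cond)
    }

    # --- myofibroblast quantification ---------------------------------------
    m = called
    col_score = score_signature(lognorm[m], adata.var_names, config.collagen_genes,
                                "collagen", barcodes=list(adata.obs_names[m]))
    col_call = binarize_kmeans(col_score)
    try:
        myo = quantify_myofibroblast_zonation(col_call, call_labels[m])
        myo["counts"].to_csv(out / "myofibroblast_table.tsv", sep="\t")
        summary["myofibroblast"] = {
            "table": {str(k): {str(kk): int(vv) for kk, vv in row.items()}
                      for k, row in myo["counts"].to_dict(orient="index").items()},
            "fraction_CaHSC_among_positive": myo["fraction_CaHSC_among_positive"],
            "n_positive": myo["n_positive"],
        }
    except ValueError as err:
        logger.warning("myofibroblast quantification skipped: %s", err)
        summary["myofibroblast"] = None

    # --- SOM metagenes (optional) -------------------------------------------
    if config.run_som:
        model = train_som(scaled[:, hvg_mask][m], hvg, grid=tuple(config.som_grid),
                          epochs=config.som_epochs,
                          seed=stage_seed(config.seed, "som"))
        mm = metagene_expression(model, scaled[:, hvg_mask][m],
                                 barcodes=list(adata.obs_names[m]))
        sels = select_cell_signatures(mm, ratio=config.som_ratio)
        retained, prev = filter_population_signatures(
            sels, call_labels[m], min_fraction=config.som_min_fraction)
        prev.to_csv(out / "som_spot_prevalence.tsv", sep="\t")
        summary["som_retained_spots"] = retained

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
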