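# zonate

Zonation analysis of the hepatic mesenchyme from single-cell RNA-seq UMI
counts.

Hepatic stellate cells (HSCs) are the liver's dominant fibrogenic cell
type. Their transcriptional state varies systematically along the
portal-vein → central-vein axis of the liver lobule, and after
centrilobular injury (e.g. CCl₄) the collagen-producing myofibroblasts
arise overwhelmingly from the central end of that axis. `zonate`
implements the computational side of this analysis as a tested, reusable
Python library:

* **Zonation signature discovery** — independent component analysis of
  uninjured HSCs, selection of the component most correlated with the
  portal anchor gene *Ngfr*, and thresholding of its gene loadings into
  two opposed gene lists: a portal program (including *Ngfr*, *Itgb3*) and
  a central program (including *Adamtsl2*, *Rspo3*).
* **Signature scoring and unbiased binarization** — per-cell score
  `s(c) = (∏_g (x_gc + 1))^{1/|G|} − 1` (geometric mean over the gene set
  on log-normalized expression), min–max scaled to [0, 1]; thresholding by
  exact 1-D 2-means clustering. Canonical sets: fibrillar collagen
  {*Col1a1*, *Col1a2*, *Col3a1*} and proliferation {*Mki67*, *Cdca8*,
  *Cdc20*, *Ccna2*, *Ccnb1*}.
* **Zonal classification and myofibroblast quantification** — supervised
  two-way clustering of HSCs on the signature genes into portal-associated
  (PaHSC) and central-associated (CaHSC) cells, then a 2×2 cross of the
  binarized collagen call against the zone call: the CaHSC share among
  collagen-positive cells quantifies which zone supplies the
  myofibroblasts.
* **Preprocessing** — CellRanger-v2 MTX triplet I/O, per-cell QC
  (`n_genes ≥ 300`, mitochondrial fraction ≤ 30%, genes expressed in ≥ 3
  cells), `ln(10⁴·c/N + 1)` normalization, per-gene negative-binomial
  depth regression with standardized Pearson residuals, binned
  mean/dispersion highly-variable-gene selection, PCA, SNN modularity
  clustering, and ROC-AUC marker detection.
* **Profiles and modules** — cell orderings from signature scores scaled
  to [0, 1], GCV cubic smoothing-spline profiles, a spline-basis F-test
  for expression change along the ordering (BH q ≤ 1e-20), and k = 3
  hierarchical gene modules.
* **SOM metagenes** — batch-trained self-organizing map over gene vectors,
  per-cell metagene selection at `e ≥ 0.95·e_max`, contiguous map spots,
  and retention of spots expressed by ≥ 30% of the cells of some cluster.
* **A synthetic-data generator** — negative-binomial UMI counts with three
  mesenchymal lineages (FB/HSC/VSMC), a continuous lobule coordinate `z`
  per HSC driving the two opposed programs, zone-biased injury activation,
  proliferation, and labelled QC failures — so every stage is testable
  against a known ground truth without downloads.

## Worked example

`examples/03_zonation_signature.py` simulates 3,000 uninjured HSCs with 52
portal and 29 central genes implanted among 2,000 background genes
(4-fold opposed gradients), preprocesses them, and discovers the signature:

```
anchor component: 2 (orientation -1)
extracted 81 genes: 52 portal + 29 central
top portal genes:  Zport04, Ngfr, Itgb3, Zport11, Zport44
top central genes: Zcent13, Rspo3, Spon2, Adamtsl2, Zcent16
portal  precision 1.00  recall 1.00
central precision 1.00  recall 1.00
PaHSC/CaHSC classification agrees with the simulated lobule coordinate for 95.9% of cells
```

The 81 extracted genes are exactly the implanted opposed programs, the
anchor gene sits on the portal side, and the two-way classification
matches the simulated lobule coordinate for ~96% of cells (errors sit at
the lobule midline, where the two programs are equal by construction).

`examples/04_myofibroblast_quantification.py` adds a chronically injured
condition (activation probability 0.44 in the central half of the lobule
vs 0.06 in the portal half, 20-fold collagen induction) and crosses the
binarized collagen score with the zone call:

```
collagen threshold 0.494 (cluster centroids 0.189 / 0.799); 943 collagen-high cells
CaHSC share among myofibroblasts: 83.9%
```

The designed share of central cells among activated cells is 88%; the
recovered share is slightly lower because zone classification blurs the
exact midline (see `docs/methods.md`).

The other examples cover QC (`01`), lineage clustering and markers (`02`),
profiles and gene modules (`05`), SOM metagenes (`06`), and the end-to-end
pipeline bundle (`07`). Each runs in well under a minute:

```bash
python examples/03_zonation_signature.py
```

## Layout

```
src/zonate/        simulate, io, qc, cluster, zonation, scoring,
                   profiles, som, pipeline
examples/          one short narrative script per capability
tests/             pytest suite (unit, property and recovery tests)
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
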