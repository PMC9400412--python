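# ecaxis

Analysis of lung endothelial-cell (EC) single-cell RNA-seq in experimental
pulmonary arterial hypertension (PAH), rebuilt as a reusable, tested Python
pipeline.  The target design is a lineage-reporter (TdTomato) sorted
experiment with three Control and three PAH (SU5416/hypoxia) mice: sparse
UMI count matrices per sample, seven EC subpopulations (arterial, venous,
two capillary types, lymphatic, proliferating, surfactant-high) plus
immune/mesenchymal contaminants, and a continuous arteriovenous axis
running artery → capillary → vein.

The package covers, stage by stage:

- **QC and normalization** — per-sample 3-MAD outlier removal on
  log library size, log genes detected and mitochondrial fraction;
  `value = ln(1 + count · 10⁴ / library)` normalization; binned-dispersion
  HVG selection; PCA with per-sample centering as a simple batch
  correction.
- **Annotation** — SNN-graph Leiden clustering, Spearman-correlation
  reference typing, canonical-marker panel labelling (Cxcl12/Mgp artery,
  Vwf/Prss23/Vcam1 vein, Nrp1/Sema3c capillary-A, Car4 capillary-B,
  Ccl21a/Prox1 lymphatic, Sftpa1-d, Tyrobp, Gsn/Col1a1/Acta2), lineage
  reporter gating for contaminants, and EndMT assessment (fraction of
  reporter⁺ cells expressing Acta2/Col1a1).
- **Differential expression** — Wilcoxon rank-sum (midranks,
  tie-corrected normal approximation with continuity correction; exact
  enumeration for small tie-free inputs) with natural-log fold change
  `ln[(mean(expm1 case)+1)/(mean(expm1 control)+1)]`, a 0.25 threshold,
  a 10% detection gate and Bonferroni correction; a **replicate-consensus
  ("stringent") analysis** that calls a gene only if every
  case-sample × control-sample pair is individually significant with a
  consistent direction; hierarchical-clustering **specificity selection**
  for subpopulation-restricted responses; hypergeometric
  over-representation with BH correction.
- **Signatures** — binned-control module scores, S/G2M cell-cycle phase
  assignment, and unpaired t-tests on log10 population proportions.
- **Zonation** — a centroid-initialized Hastie–Stuetzle principal curve
  orders artery/capillary/vein cells along the arteriovenous axis
  (position λ ∈ [0,1], oriented by an arterial anchor gene); reflected
  kernel densities per condition; the consensus DE analysis repeated in 10
  equal-width axis sections yields gene × section log-fold-change
  profiles and localizes zonation-dependent condition effects.
- **Cross-species overlap** — ortholog mapping (case-normalized symbols by
  default), direction-aware sharing fractions against external DEG
  tables, and validation against a bulk RNA-seq table at a 1.5-fold
  threshold.
- **Synthetic data** — a negative-binomial (Gamma–Poisson) generator that
  plants all of the structure above (populations with marker and program
  genes, logistic/Gaussian zonation profiles on a latent λ, global /
  population-specific / section-localized / replicate-inconsistent
  condition effects, per-sample batch multipliers, damaged high-mito
  cells, a lineage reporter) together with complete ground-truth tables,
  so every stage is testable by recovery.

## Worked example

```python
import ecaxis

matrix, ann, truth = ecaxis.simulate_experiment(ecaxis.SimulationParams(seed=1))
pre = ecaxis.preprocess(matrix, ann)            # QC + normalize + PCA
ann = ecaxis.annotate_populations(pre)          # cluster + marker labels

degs = ecaxis.de_population(pre.norm, ann, "CapillaryA")
case = sorted(ann.loc[ann.condition == "PAH", "sample_id"].unique())
ctrl = sorted(ann.loc[ann.condition == "Control", "sample_id"].unique())
stringent = ecaxis.consensus_de(pre.norm, ann, "CapillaryA", case, ctrl)
print(len(degs), len(stringent.consensus_genes()))
```

prints

```
157 134
```

— of 2000 simulated genes carrying 150 planted global 1.5–3× condition
effects, the pooled analysis reports 157 significant CapillaryA genes
(recall 0.99 at empirical FDR 0.006 against the ground truth) and the
stringent nine-pair consensus keeps 134 of them, losing the weaker
effects, with no false calls.  Continuing,

```python
ordering = ecaxis.fit_axis(pre, ann)
profile = ecaxis.sectioned_consensus_de(pre.norm, ann, ordering, case, ctrl)
```

orders the vascular cells (Spearman ρ = 0.986 against the planted axis
position in this run) and the gene × 10-section profile places the peak
response of the planted junction-localized genes in sections 4–5,
i.e. at the capillary–arterial junction where they were planted
(λ* = 0.45).

A CLI mirrors the stages:

```sh
ecaxis --seed 1 --outdir sim simulate
ecaxis --outdir out qc sim
ecaxis --outdir out annotate sim
ecaxis --outdir out de sim --population CapillaryA --mode consensus
ecaxis --outdir out zonation sim
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` simulates the
default six-sample experiment with the given seed, runs the full pipeline
(QC → annotation → pooled and consensus DE per population → specificity →
axis ordering → sectioned DE), prints a JSON summary of what it found, and
writes the result mapping to `--out`.

## Layout

- `src/ecaxis/core_io.py` — data model, MTX/TSV/GMT I/O, config, logging
- `src/ecaxis/synthetic.py` — the generator and ground-truth tables
- `src/ecaxis/qc_norm.py` — QC, normalization, HVG, PCA
- `src/ecaxis/annotate.py` — clustering, reference typing, marker panels
- `src/ecaxis/diffexpr.py` — rank-sum DE, consensus, specificity, ORA
- `src/ecaxis/signatures.py` — module scores, cell cycle, proportions
- `src/ecaxis/zonation.py` — principal curve, densities, sectioned DE
- `src/ecaxis/crossspecies.py` — ortholog mapping and DEG overlap
- `docs/methods.md` — models, assumptions, parameter choices, limitations
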