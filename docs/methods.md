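# Methods

This note documents the models, defaults and numerical choices of the
package, what the synthetic world does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The synthetic world

`simulate_experiment` draws a 3 Control + 3 PAH lineage-reporter
experiment.  Counts are Gamma–Poisson:

    y_gc ~ NB(mean = L_c · m_gc / Σ_g m_gc,  size = 10)
    m_gc = μ_g · pop_boost_g(pop_c) · exp(β_g f_g(λ_c))
               · exp(δ_g · w_g(c) · 1[case & affected]) · exp(ε_gs)

with per-cell library budget `L_c ~ Lognormal(ln 5000, 0.3)`.  The NB
size 10 gives the over-Poisson dispersion typical of droplet UMI data
without zero inflation; droplet zeros are adequately produced by the NB
itself.

**Populations.**  Nine populations at proportions 0.60 CapillaryA,
0.12 CapillaryB, 0.08 Artery, 0.08 Vein, 0.04 Lymphatic,
0.03 Proliferating, 0.004 Sftp⁺, 0.03 Immune, 0.016 Mesenchymal — a
capillary-dominated endothelium with deliberately enlarged contaminant
fractions so the contaminant-detection path is actually exercised (real
sorted data had an order of magnitude less contamination).

**Gene architecture.**  Baselines `μ_g ~ Lognormal(0, 1)`.  Each
population owns (i) its canonical markers, planted at a high baseline with
a 12× own-population boost and 0.05× elsewhere (1× among vascular
populations, whose markers instead carry zonation gradients), and (ii) a
block of 30 anonymous "program" genes boosted 2–5×.  The program blocks
are essential realism: real cell types differ in broad expression
programs, and populations that differ by one to four genes are not
clusterable by any method — without them the stated seven-cluster
structure would not exist in the data.  Acta2 and Col1a1 are calibrated to
an expected 0.005 UMIs per endothelial cell (no EndMT is planted) and are
strongly induced only in the mesenchymal contaminants.  Cell-cycle panel
genes (shipped mouse S/G2M lists, config-replaceable) are boosted 4× in
Proliferating.  Ten `mt-*` genes carry a 5% mitochondrial share — or
Uniform(0.25, 0.6) in the 2% of cells flagged damaged — and the `TdTomato`
reporter averages 20 UMIs in lineage cells versus 0.05 in contaminants.

**The arteriovenous axis.**  Vascular cells carry a latent coordinate
λ: Artery ~ U(0, 0.30), CapillaryA ~ U(0.25, 0.75),
CapillaryB ~ U(0.30, 0.70), Vein ~ U(0.70, 1.0); the overlaps make the
three axis clusters adjacent, as in the real vasculature.  Zonation
profiles are unit-amplitude logistic (arterial: falling around a center
in 0.2–0.5; venous: rising around 0.5–0.8; width 0.05) or Gaussian
(junction; center 0.3–0.7, σ 0.05–0.15), with amplitudes
β ~ U(ln 3, ln 8) on 70 + 70 + 25 anonymous genes plus the vascular
markers.  These counts and amplitudes were set by an identifiability
argument: the per-cell information about λ in the counts bounds how well
any ordering method can recover it, and weaker gradients put that
information ceiling (Spearman ≈ 0.93) below the recovery level the
planted-structure tests demand.  The chosen values put the ceiling near
0.99 while staying within the several-fold dynamic range real zonated
genes show.

**Condition effects.**  150 global effects (half up, half down,
|δ| ~ U(ln 1.5, ln 3); one sentinel fixed at exactly +ln 2), 40
CapillaryB-specific effects (all up — the emulated capillary-B response is
an up-regulation signature), 10 section-localized effects
(δ = ln 2, Gaussian weight centered at λ* = 0.45, σ = 0.08 — the
capillary–arterial junction), and optionally n replicate-inconsistent
effects active in only the first and third case samples.  Effects are
planted on the more-abundant half of the unassigned generic genes
(section-localized ones on the most abundant picks): a fold-change gate of
0.25 on log-normalized means is only observable for genes expressed at the
simulated depth, so planting effects on near-silent genes would test
nothing.  Per-gene-per-sample batch multipliers `ε_gs ~ N(0, 0.1)` create
the replicate-level confounding that the consensus analysis exists to
guard against.  `SimulationParams.null()` switches off both the condition
effects and the batch variation: under batch variation pooled cell-level
p-values are *not* uniform — that is the replicate-confounding phenomenon
itself, not a calibration failure — so the calibration null removes it.

**Not emulated:** ambient RNA, doublets, zero inflation beyond NB,
read-level structure, EndMT, cluster-free continuous cell states outside
the vascular axis.  A green recovery test therefore establishes that the
method recovers the stated structure under NB sampling, batch scaling and
contamination — not that it is robust to artifacts the generator does not
produce.

## QC and normalization

Per sample, cells more than `nmads = 3` MADs (1.4826-scaled) below the
median of log1p library size or log1p detected genes, or above it in
mitochondrial fraction, are removed.  The rule is iterated to a fixed
point (re-estimating medians/MADs on survivors) so that filtering the
filtered set removes nothing; a zero MAD flags nothing.  Normalization is
`ln(1 + count · 10⁴ / library)`.  HVGs are the top 2000 genes by
within-mean-bin (20 bins) z-score of log dispersion (variance/mean of
expm1 values), ties broken lexicographically; values are z-scaled per gene
(clipped at ±10), centered per sample — the deliberate, simple stand-in
for anchor-based integration, sufficient for location-shift batch effects
like the simulated ones and never used for DE — and reduced to 30
principal components (randomized SVD, seeded, signs fixed by the largest
loading).

## Annotation

Clustering: SNN graph (k = 20 neighbors including self, Jaccard weights)
with Leiden modularity at resolution 0.8, labels ordered by cluster size.
Over-clustering is harmless because population labels come from the
marker panel, not the cluster count.  Reference typing is a single-pass
per-cell Spearman argmax against labelled mean profiles (ties:
lexicographic; zero-variance cells: Unassigned); the iterative
fine-tuning of the classifiers used on real data is intentionally not
reproduced — recovery of known truth, not replication of a tool, is the
measured property.  Cluster labels: per population, the mean
direction-signed z-score (across clusters) of its panel genes; a cluster
whose pan-EC score (Cdh5, Pecam1) is below its Immune or Mesenchymal score
and whose median reporter count is zero is a contaminant.  Reporter
positivity is ≥ 1 UMI: on sorted material the reporter is expressed high,
so a single UMI is already informative.  EndMT is quantified as the
fraction of reporter-positive cells with nonzero Acta2 (or Col1a1),
with pan-EC means of the positive/negative subsets as context.

## Differential expression

Wilcoxon rank-sum on midranks; tie-corrected normal approximation with
continuity correction; exact enumeration when n₁+n₂ ≤ 12 and tie-free;
zero-variance input returns p = 1.  Fold change is
`ln[(mean(expm1 case)+1)/(mean(expm1 control)+1)]` — the pseudocount-1
convention under which the 0.25 threshold is conventionally interpreted.
Genes are tested when detected in ≥ 10% of either group and past the
fold-change gate; Bonferroni correction over tested genes (BH is reserved
for ORA; both config-switchable).  Pooled DE pools cells across replicates
within condition, deliberately not pseudobulk; the consensus procedure is
the replicate-aware counterpart: a gene is consensus iff every
case × control sample pair (9 at the design size) is significant, past the
gate, and sign-consistent.  The all-pairs rule is the strictest reading of
"common changes"; `consensus_min_frac` relaxes it to m-of-n, in which case
sign consistency is required over the passing pairs (near-zero non-passing
pairs have arbitrary sign).  An untestable pair (empty cell group) vetoes
consensus under the all-pairs rule.  Specificity selection z-scores the
gene × (population × condition) mean matrix, clusters genes
(average linkage, correlation distance, 4 clusters) and keeps clusters
whose mean |Δ(PAH−Control)| in the target population is ≥ 2× the largest
mean |Δ| elsewhere; the magnitude comparison (not signed Δ) is what
"stronger response" means for down-regulated clusters.  ORA is the
upper-tail hypergeometric on a declared universe with BH across sets.

## Signatures and proportions

Module scores use the standard binned-control construction: genes ranked
by mean expression, 24 equal-size bins, 100 controls sampled without
replacement per set gene from its bin (the whole bin when smaller), score
= mean(set) − mean(pooled controls), seeded.  Single random-set score
means scatter with sd ≈ 0.08 — set by the within-bin spread of gene
means — while the estimator is unbiased; interpret single-set scores
comparatively (between conditions or cell groups), not absolutely.
Cell-cycle phase: G1 if both S and G2M scores ≤ 0, else the larger.
Population proportions are compared by a two-sided pooled-variance t-test
on log10 per-sample proportions among QC-passing endothelial cells, with
a 1/(n+1) floor for absent populations and p = 1 returned (logged) for
zero-variance inputs.

## Zonation

The axis is a Hastie–Stuetzle principal curve in PCA space, initialized
on the piecewise-linear Artery → CapillaryA → Vein centroid path with the
end segments extended to cover tail cells.  Each iteration projects cells
onto the polyline, averages the projections in equal-count arc-length bins
(≈ n/20, at most 100 — the scatterplot-smoother step that keeps the GCV
spline well-posed), fits a cubic smoothing spline per coordinate with
GCV-chosen penalty (linear extrapolation beyond the bin range),
re-parameterizes by chord length, and stops when the mean |Δλ| < 10⁻³ or
after a 3-iteration stall (the iteration oscillates around its fixed
point with small amplitude on noisy data; the last iterate is returned
with a warning).  λ is min-max normalized and oriented so the anchor
(Cxcl12 by default) is high at λ = 0.  Rotation of the component space
leaves λ unchanged on clean data; under noise the per-coordinate GCV
penalties make equivariance approximate.  Densities are Gaussian KDEs
reflected at both boundaries and renormalized on [0, 1].  Sections are 10
equal-width λ bins (an `equal_count` option exists); each section with
≥ 20 cells per sample gets the full consensus analysis, others are
reported missing rather than zero.

## Cross-species overlap

Ortholog mapping defaults to case-normalized symbol equality, overridden
by any two-column TSV; one-to-one maps reject duplicate symbols; unmapped
genes are reported and stay in denominators unless `mapped_denominator`
is set.  A reference DEG is shared-any if any external table carries its
ortholog as significant (per-table choice of raw vs adjusted p, matching
sources analysed without multiple-testing correction) with the same
direction; k-way intersections are reported.  Bulk validation first
restricts the single-cell DEGs to ≥ 1.5-fold on the linear scale
(ln 1.5 ≈ 0.405 internally) and counts same-direction significant bulk
entries; an empty filtered set yields an explicit "not evaluable" result.

## Known limitations

- Anchor/MNN integration is out of scope; per-sample centering only
  corrects location shifts in the reduced space.
- The consensus analysis at ~150 cells per group per pair has limited
  power for < 2-fold effects; sectioned profiles of weak or lowly
  expressed genes can be empty even when an effect is planted.
- Principal-curve convergence to the literal 10⁻³ mean-shift tolerance is
  not guaranteed on noisy data (stall stop); positions are stable but the
  `converged` flag may be False.
- The generator plants location-scale structure only; methods are not
  stress-tested against doublets, ambient RNA or nonlinear batch effects.
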