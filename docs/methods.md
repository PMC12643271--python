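# Methods

This note documents the models, algorithms, defaults and design decisions
behind `mbmindex`, and what the synthetic benchmark does and does not
establish about real data.

## Data model and normalization

Expression travels as a genes × observations matrix with an explicit layer
tag. `counts` must be finite and non-negative; `tpm` columns must sum to
10⁶ (relative tolerance 10⁻⁶); `lognorm` is ln(1 + s·x/total) with scale
factor s = 10⁴ per cell. TPM requires explicit per-gene transcript
lengths (base pairs); no default length table ships with the package, so
results cannot silently depend on an annotation version. Gene identifiers
are matched case-sensitively with no alias resolution.

Cell QC keeps a cell when its mitochondrial count fraction is ≤ 0.20 and
its detected-gene count lies in [500, 5000]. The exclusions are strict
inequalities ("fewer than 500 or more than 5000", "exceeding 20%"), so the
boundary values are retained; the bounds, and the mitochondrial
identifier prefix (default `MT-`), are configurable. Bulk cohorts drop
(in this order) samples with an excluded designation (e.g. "normal"),
samples without a survival record, and samples with overall survival
shorter than 30 days (strict; day 30 itself stays).

## MBMATC signature

The target malignant cluster is contrasted against all other malignant
cells, per gene, with a two-sided Wilcoxon rank-sum test
(tie-corrected asymptotic p), Benjamini–Hochberg FDR across tested genes,
a Seurat-style log2 fold-change of mean(expm1(lognorm)) + 1, and the
fraction of target cells detecting the gene. Defaults: log2FC ≥ 0.25,
FDR ≤ 0.05, detection ≥ 10% — conventional marker-gene thresholds. The
signature is returned ranked by log2FC with the fold-changes as weights.

## One-class logistic regression and the MBM-Index

The OCLR objective over centered training columns x_i is

    J(w) = -(1/n) Σ log σ(wᵀx_i) + λ1‖w‖₁ + (λ2/2)‖w‖₂²

minimized by proximal gradient descent: gradient step on the smooth part,
soft-thresholding for the L1 term, backtracking line search (halving)
against the quadratic upper bound, with the step allowed to grow back
between iterations. The objective sequence is therefore non-increasing;
convergence is declared when the relative objective change falls below
`tol` (default 10⁻⁶, cap 10⁴ iterations). Non-convergence returns a
flagged model with a warning, never an exception.

**Centering.** Centering the genes by the *training* mean makes the
one-class objective degenerate: the training columns then sum to zero, the
gradient vanishes at w = 0, and since J is convex, w = 0 is the global
minimum. The stemness-index lineage avoids this by centering every gene
with its mean over the full reference population and fitting on the
positive-class columns only, which preserves a non-zero class-mean
direction. `fit_oclr` therefore accepts an explicit `center_by` vector;
the pipeline passes the gene means over *all malignant cells* and trains
on the MBMATC columns. Training-mean centering remains the fallback when
no reference is supplied, and centering can be disabled.

Penalty defaults are λ1 = 0, λ2 = 1, the convention of the cited OCLR
lineage; both are exposed. Training instances are MBMATC cells subsampled
to at most 2000 (seed-controlled); per-sample pseudobulk aggregation is a
trivial pre-step the caller can apply to the training matrix.

**Scoring.** A cohort sample's score is the Spearman correlation
(average ranks for ties) between the weight vector and the sample's raw
expression over the shared signature genes — the centering vector is not
applied at score time, matching the stemness-index workflow; rank
correlation makes the score invariant to any per-sample monotone
transform, so whether the cohort is supplied as TPM or log-TPM is
immaterial and no log transform is applied (verified by the cube-root
invariance test). At least 3 shared genes
are required; a warning fires below 50% signature coverage. Cohort
correlations are rescaled linearly so the cohort minimum is exactly 0 and
the maximum exactly 1. Stratification defaults to a median split
(quantile and fixed cutpoints available); ties at the cutpoint go to the
low group.

## Cell-state scoring and tissue enrichment

Module scores follow the binned-control scheme: genes are ranked by mean
expression across cells and cut into 24 equal-frequency bins (ties broken
by gene id so the result is independent of gene order); each signature
gene draws 100 control genes from its bin, excluding signature genes,
without replacement unless the bin is smaller than the draw; when the
signature exhausts a bin entirely, the pool widens symmetrically to
neighbouring bins. The score is the signature mean minus the pooled
control mean per cell, making it exactly invariant to adding a constant
to one cell. Control sampling is seeded; its noise shrinks as the control
count grows. Missing signature genes are dropped with a warning; only a
fully absent signature is an error.

Ro/e is the observed cell count of a (cell type, tissue) pair divided by
the expected count under independence (row total × column total / grand
total) — the chi-square expected-counts construction. A ratio above 1
flags enrichment; a zero margin yields NaN rather than an error. No
significance test is attached: the ratio itself is the statistic reported.

## Survival analysis

Kaplan–Meier estimation and Cox proportional-hazards regression are
delegated to lifelines (Efron tie handling; Wald confidence intervals and
p-values, matching forest-plot presentation). The two-group log-rank test
is implemented in-module from the observed-minus-expected construction
with hypergeometric variance at each distinct event time, so the package
carries its own reference implementation (cross-checked against lifelines
in the tests). Categorical covariates are one-hot encoded with the first
(sorted) level as reference, recorded in the term names. Rank-deficient
designs and non-convergent fits return flagged results.

## Drug screen

Sensitivity imputation is a deliberately simplified calcPhenotype: per
drug, a ridge regression of reference cell-line response on standardized
shared-gene expression (λ by leave-one-out selection over the grid
10⁻²…10⁴ unless fixed), predicted on identically standardized target
samples — no batch homogenization between reference and target, a
documented divergence from the cited tool. Drugs with under 3 responses
or constant response are skipped with warnings.

The screen computes, per database, arm and drug, log2FC =
log2(mean target score / mean comparator score) — means of raw scores by
default (median optional; the source analysis does not define the
statistic) — and a two-sided Mann–Whitney U p-value. Direction is
enforced by the signed fold-change gate (< −0.1), not by a one-sided
test. The U statistic counts (a > b) pairs with half-weight ties; the
p-value is exact by full enumeration of group assignments when the
combined size is ≤ 12 (fidelity/runtime balance), otherwise a
tie-corrected normal approximation with continuity correction. Candidates
per arm are the drugs passing in every database; the two arms
(cell-state contrast and high-vs-low index contrast) are reported jointly
and their intersection is the final set. Index–sensitivity association is
a Spearman correlation with an exact permutation p for n ≤ 9 and the
t approximation above that.

## Synthetic-data generator

The generator emulates the study design end to end, with one global seed
and fixed per-stage sub-streams (cells 0, bulk 1, drugs 2, lengths 3) so
stages regenerate independently and runs are bit-reproducible.

* **Cells.** Counts are NB2 (variance μ + αμ², dispersion α = 0.5) with
  log-normal gene baselines (ln-mean ln 0.5, ln-sd 1.2) and per-type
  profile jitter (ln-sd 0.7). Default composition: melanoma 400 cells per
  tissue; T cells depleted outside PT; a Treg-like type and macrophages
  over-represented in MBM — the enrichment structure Ro/e should detect.
  30% of malignant cells are flagged MBMATC. Planted signature genes
  (default 100, the size of the study's branch-gene set) are drawn from a
  moderate-expression band (0.5–3 mean counts) — a marker that is not
  detectable is a contradiction — and shifted by per-gene log2 effects ~
  Uniform(floor, 2·effect − floor) with floor = min(0.5, effect/4) and
  mean equal to the configured effect (default 2.0). Heterogeneous
  effects are essential: a uniform shift would leave within-signature
  ranks unchanged and carry no rank-correlation signal at all. The band
  also keeps the signature from dominating library size, which would
  otherwise let depth normalization cancel the planted shift (a 100-gene
  signature in a 2000-gene transcriptome is proportionally 10× a real
  one). Optional deliberately pathological cells (50× mitochondrial
  means) exercise the QC filter.
* **Bulk.** Sample s mixes the non-MBMATC cluster mean profiles with
  Dirichlet(1) weights scaled by 1 − f_s plus f_s times the MBMATC
  profile, f_s ~ Beta(2, 3), then multiplies per-gene log-normal noise
  (ln-sd 0.5). Default cohort size 200. Gene lengths ~ U(500, 10000) bp.
* **Survival.** Exponential event times with hazard
  h₀·exp(β·f_s), h₀ = 10⁻³/day, β = 2.0 (median-split group hazard ratio
  ≈ 1.9, the magnitude reported for the real cohort), independent
  exponential censoring at 5·10⁻⁴/day — the closed-form oracle used by
  the calibration tests.
* **Drugs.** 50 drugs, 5 effective: score = a_d − 0.3·f_s + N(0, 0.1²)
  (lower = more sensitive), null drugs have zero slope; the two
  database-like tables share a_d and the effect structure but draw
  independent noise. Baselines a_d ~ U(0.65, 0.95): IC50-like magnitudes
  of order 1 chosen so that a slope-sized group shift is expressible as a
  log2 fold-change beyond the −0.1 gate (for a ≈ 1.2 the group-mean ratio
  cannot reach 2^−0.1 even noise-free).

**What passing tests show — and don't.** The generator reproduces the
*statistical skeleton* the analysis assumes: a transcriptionally shifted
malignant subpopulation, bulk mixtures monotone in its latent fraction,
hazard increasing with that fraction, and drugs linearly coupled to it.
It deliberately omits real gene–gene correlation structure, realistic
library-size and dropout distributions, batch effects between cohorts,
microarray/RNA-seq platform differences, and real drug identities.
Recovery on this benchmark therefore validates the implementation and its
operating characteristics, not the biological performance of the index on
any particular cohort.

## Numerical choices

Spearman correlations use average ranks; constant vectors are errors that
name the offending sample. The scaled index requires at least two
distinct correlations. The OCLR line search guards against floating-point
objective increases by stopping rather than accepting one. Module-score
binning uses a canonical (mean, gene id) ordering so results are
invariant to gene and cell order. All writers emit genes-as-rows with
fixed float formatting and LF line endings, making outputs byte-stable.

## Problem sizes

Default test and demonstration sizes — 2000 genes, ~2300 cells, a
200-sample cohort, 500/200-replicate calibration runs, and a 1200-gene
demo pipeline — were chosen so the full suite and the acceptance script
each complete in well under a minute of compute while leaving the
Monte-Carlo tolerances meaningful.

## Known limitations

* The signature deriver implements the differential-expression route; the
  upstream trajectory/branch analysis that produced the study's actual
  gene list is consumed as an annotation, not recomputed, and any
  externally supplied list is accepted.
* Whether the published index was trained on cells or pseudobulk, and
  with which penalties, is not stated in the source; both are exposed as
  configuration rather than guessed.
* The log2FC statistic of the drug screen (means of raw scores) is an
  interpretation; a median option is provided.
* No proportional-hazards diagnostics are provided, and no
  time-to-brain-metastasis endpoint is modelled.
* T-cell functional-state gene lists (naive, activation/effector,
  exhaustion, cytotoxicity) and AXL/MITF program lists are external
  inputs; the package ships only synthetic placeholders.
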