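# mbmindex

Melanoma brain metastasis (MBM) is the lethal endpoint of melanoma
progression: once the brain is colonized, median survival is measured in
months, and no routine biomarker flags the patients most at risk *before*
dissemination. Single-cell atlases of primary tumors (PT), extracranial
metastases (ECM) and brain metastases have identified a malignant
subpopulation — brain-metastasis-associated tumor cells (**MBMATC**) —
whose transcriptional state marks cells primed for brain tropism.

`mbmindex` turns that observation into a tested, reusable analysis
pipeline for computational oncologists:

1. **Signature derivation** — differential expression (Wilcoxon rank-sum,
   Benjamini–Hochberg FDR, log2 fold-change and detection-fraction gates)
   of the MBMATC cluster against all other malignant cells.
2. **One-class model** — a one-class logistic regression (OCLR) with
   elastic-net penalty fitted on MBMATC cells over the signature genes,
   the same paradigm as the stemness index (mRNAsi).
3. **MBM-Index** — each bulk transcriptome (TPM) is scored by the Spearman
   correlation between the model weights and its expression over the
   signature genes; cohort correlations are rescaled linearly to [0, 1].
   Higher index ⇒ greater resemblance to the MBMATC state ⇒ greater
   inferred brain-metastasis risk.
4. **Survival analysis** — Kaplan–Meier curves, an in-house log-rank test
   and Cox proportional-hazards models over index groups and covariates.
5. **Cell-state statistics** — binned-control per-cell module scores
   (AddModuleScore-style) and Ro/e tissue-enrichment ratios
   (observed / expected counts under cell-type × tissue independence).
6. **Drug screen** — calcPhenotype-style ridge imputation of IC50-like
   sensitivity scores, then a two-tiered screen: a drug is a candidate
   when its scores are lower (log2FC < −0.1, Mann–Whitney p < 0.05) in
   both the MBMATC-state arm and the high-index patient arm, intersected
   across two response databases.

A bundled synthetic-data generator emulates the whole study design —
negative-binomial single cells with a planted MBMATC subpopulation, bulk
cohorts as mixtures with a latent MBMATC fraction, survival coupled to
that fraction, and drug-response tables with known effective drugs — so
every stage is testable against ground truth without downloads.

## The model

Given centered training columns $x_i \in \mathbb{R}^p$ (MBMATC cells over
the signature genes, centered by the reference-population gene means), the
OCLR weights minimize

$$J(w) = -\frac{1}{n}\sum_{i=1}^{n} \log \sigma(w^\top x_i)
         + \lambda_1 \lVert w \rVert_1
         + \frac{\lambda_2}{2}\lVert w \rVert_2^2,$$

solved by proximal gradient descent with backtracking (soft-thresholding
for the L1 term); the objective sequence is non-increasing by
construction. A sample $s$ with expression $y_s$ over the signature genes
gets $\rho_s = \mathrm{Spearman}(w, y_s)$ and the cohort-scaled index
$\mathrm{MBMIndex}_s = (\rho_s - \min_t \rho_t) / (\max_t \rho_t - \min_t \rho_t)$.

## Worked example

```python
import scipy.stats
import mbmindex as mx

cfg = mx.SimulationConfig(seed=1)                     # default study conditions
cells, ann, truth = mx.simulate_cells(cfg)
lognorm = mx.log_normalize(cells)
signature = mx.derive_signature(lognorm, ann, target_label="MBMATC")
print(f"signature: {len(signature.genes)} genes")

bulk, surv, truth = mx.simulate_bulk_cohort(cfg, truth)
bulk, surv, _ = mx.filter_bulk_cohort(bulk, surv, min_os_days=30)
tpm = mx.tpm_normalize(bulk)

malignant = ann.table.index[ann.table.is_malignant]
mbmatc = [c for c in malignant if ann.table.loc[c, "cluster"] == "MBMATC"]
train = lognorm.subset_genes(signature.genes).subset_obs(mbmatc)
reference = lognorm.subset_genes(signature.genes).values[malignant].mean(axis=1)
model = mx.fit_oclr(train, center_by=reference)
results = mx.stratify(mx.scale_index(mx.score_samples(model, tpm)))

rho = scipy.stats.spearmanr(results["index"], truth.f_s[results.index]).statistic
print(f"Spearman(MBM-Index, latent fraction) = {rho:.3f}")

chi2, p = mx.logrank_test(surv, results["group"])
cox = mx.cox_fit(surv.assign(high=(results['group'] == 'high').astype(float)), ["high"])[0]
print(f"log-rank p = {p:.4g}")
print(f"Cox HR (high vs low index) = {cox.hr:.2f} [{cox.ci_low:.2f}, {cox.ci_high:.2f}]")
```

Output:

```
signature: 99 genes
Spearman(MBM-Index, latent fraction) = 0.832
log-rank p = 0.0007461
Cox HR (high vs low index) = 1.78 [1.27, 2.51]
```

The derived signature recovers 99/100 planted genes; the index orders the
cohort almost exactly by the latent MBMATC fraction; and the median split
separates survival with a hazard ratio near the planted group effect
(~1.9).

## Command line

```
mbmindex simulate | qc | normalize | score | roe | derive-signature |
         fit-index | score-cohort | survival | drug-screen | run | validate
```

`mbmindex run --seed 1 --out out/` executes the whole chain on the
bundled generator and writes every artifact plus a `manifest.json` with
content hashes; reruns with the same config are byte-identical. Exit
codes: 0 success, 2 config/validation error, 1 runtime failure.

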