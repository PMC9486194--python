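# Methods

This note records the models, statistical procedures, and design choices
behind `cmskit`, in the spirit of a statistical-methods appendix. Nothing
here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scientific setting

Consensus molecular subtype 4 (CMS4) colon cancer is the mesenchymal,
stroma-rich subtype with the worst prognosis. The analysis chain implemented
here supports a CMS4-directed treatment study design:

1. **Target screen** — find kinases whose expression tracks the CMS4
   signature across cohorts, then rank kinase inhibitors by how selectively
   they bind those kinases (Kd profiles).
2. **Diagnosis** — call CMS4 per tumor from multi-region biopsies scored by a
   4-gene panel (PDGFRA, PDGFRB, PDGFC, KIT), with explicit handling of
   intra-tumor heterogeneity; call all four subtypes for RNA-seq samples by
   pooling with a balanced labeled reference ("piggyback" pooling).
3. **Phenotype shift** — quantify pre-vs-post treatment transcriptomic
   changes (signatures, genes, genome-wide DE, PCA, CMS re-calls) in a
   paired, patient-clustered design.
4. **Stratification** — split an independent cohort by expression of the
   treatment-induced gene set and compare CMS composition and survival
   between strata.

Patient data are not shipped; every stage is validated on synthetic cohorts
with planted ground truth (`cmskit.synthetic`), generated at the study's
design points (5 patients × 3+3 biopsies; 2–3 biopsies per tumor; ~38% CMS4
prevalence; stringent p < 1e-6 kinome threshold; 3 µM Kd cutoff).

## Synthetic data model

Expression is Gaussian on the log2 scale: a baseline of 7.0 log2 units,
residual SD 1.0 (`noise_sd`), and additive mean shifts for structure. This
matches the scale on which all downstream statistics operate; a thin Poisson
layer (`as_counts`, λ = 2^x) feeds the count-normalization path. The
generators emulate:

- **Reference cohort** — four subtypes with per-subtype marker blocks
  shifted by `effect_size` (default 2.0 log2 units) within their subtype.
  Default subtype proportions (0.14, 0.37, 0.13, 0.23) leave a 13% unlabeled
  background, mirroring a large real-world cohort in which not every sample
  receives a confident label; the default size is 3232 samples. Tests use
  smaller balanced cohorts (stated per test).
- **Kinome layer** — each kinase row is ρ·z(score) + √(1−ρ²)·noise with the
  noise residualized against the signature score, so the empirical
  correlation with the CMS4 signature score matches the target ρ closely at
  moderate n; ρ = 1 degenerates to an affine transform of the score.
- **Kd matrix** — background inhibitor–kinase Kd values are log-normal
  (median 10 µM, log-SD 1.5, a realistic spread for broad kinase panels);
  the planted inhibitor has `on_target_kd` (default 0.01 µM) at its targets
  and `off_target_kd` (100 µM) elsewhere; cells are untested independently
  with probability 1 − `fraction_tested`.
- **Multi-region biopsies** — tumor-level binary CMS4 labels; a
  heterogeneous tumor (probability `heterogeneity_rate`) has 1..b−1 of its b
  biopsies drawn from the opposite class's 4-gene distribution (a biopsy-
  level label flip, not continuous admixture — matching the binary
  heterogeneity notion in the study design). Class separation defaults to 3
  log2 units on the panel genes.
- **Paired treatment** — each patient draws one random intercept (SD
  `patient_sd`, default 1.0) shared across all their PRE and POST biopsies;
  POST samples receive −shift on the mesenchymal set and +shift on the
  epithelial/proliferation set. The spec of the design (5 patients, 3
  biopsies per arm → 15+15 samples) matches the treated cohort. A
  `residual_sd` field (default 1.0) sets within-patient noise. There is no
  gene×patient interaction, matching the fitted model's structure.
- **Survival** — exponential event times with the flagged group's hazard
  multiplied by exp(log HR); independent exponential censoring truncated at
  `max_follow_up` (default 120 months; baseline hazard 0.02/month ≈ 58%
  5-year survival, censor rate 0.005/month).

What the generators do **not** emulate: count overdispersion beyond Poisson,
gene–gene correlation outside planted structure, batch effects, non-
proportional hazards, and any RT-qPCR measurement model. Passing recovery
tests therefore demonstrates correctness of the analysis chain under its own
assumptions, not performance on real tumors.

## Statistical procedures

- **Signature score** — per-sample mean of gene-wise z-scores (gene centered
  and scaled across the scored matrix's samples, sample SD, ddof = 1).
  Absent and zero-variance genes are dropped with a logged warning.
- **Kinome screen** — Pearson r of each kinase against the signature score,
  one kinase at a time (one test per kinase rather than all classifier-gene ×
  kinase pairs; this matches the reported per-kinase count structure).
  One-sided p for positive correlation from the t transform with n−2 df;
  pass requires r > 0 and p < 1e-6 in **every** cohort. No further multiple-
  testing correction — the fixed stringent threshold is the rule.
- **Selectivity** — S = (# kinases with Kd strictly < 3 µM) / (# tested);
  untested (missing) kinases count in neither numerator nor denominator.
  Ranking keeps inhibitors with ≥1 screen kinase below the cutoff, sorts S
  ascending, breaks ties by more screen-kinase hits then inhibitor id.
- **4-gene scorer** — logistic model on z-scored panel expression with
  non-negative weight bounds (L-BFGS-B on the convex ridge-regularized
  loss, α = 1e-3 to keep separable fits finite), so the CMS4 probability is
  monotone non-decreasing in each panel gene. The published test's fitted
  coefficients are proprietary; re-training on a labeled reference is the
  supported path.
- **Tumor aggregation** — weighted mean of per-biopsy probabilities over
  QC-passing biopsies (default weight 1; weights are an exposed input since
  the weighting scheme of the original weighted mean is unspecified). CMS4
  iff the mean is **strictly** above 0.5; heterogeneity flag = disagreement
  of per-biopsy binary calls.
- **Piggyback classification** — query and reference pooled on shared
  genes, jointly normalized (median-of-ratios size factors then log2(x+1)
  when counts; per-gene z-scores over the pool), then a random forest (500
  trees, fixed seed) trained on reference labels. Call = argmax subtype if
  its probability is strictly above 0.5, else indeterminate. Any
  probabilistic classifier could be substituted behind the same contract.
- **Size factors** — median-of-ratios with the geometric-mean reference
  restricted to genes with no zero count; the absolute factor scale is
  arbitrary (only ratios matter), which the tests check against an
  independent implementation.
- **Mixed model** — REML fit of value ~ condition + (1 | patient) via
  statsmodels `MixedLM`. The default optimizer occasionally stalls off the
  τ² = 0 boundary, so the model is also refit with Powell's method and the
  solution with the higher restricted likelihood is kept. Inference is a
  Wald test on the condition contrast against a **t reference with n−2 df**
  (no Satterthwaite): with the variance component at zero this reduces
  exactly to the pooled two-sample t-test, and in the study design (5
  patients × 3+3) it keeps the type-I error at the nominal level (measured
  in the acceptance run). Variance components are bounded at zero.
- **Clustered marginal correlation** — point estimate is the pooled Pearson
  correlation over all pairs; variance from the cluster-summed influence
  function of the correlation (sandwich estimator), two-sided normal p.
  When every cluster is a singleton the procedure dispatches to the
  classical exact Pearson test, making the reduction to the independent
  case exact rather than approximate.
- **DE screen** — per-gene one-way ANOVA (vectorized), Benjamini–Hochberg
  across genes, significance at q ≤ 0.001; direction from the group-mean
  contrast. Genes with zero within-group variance receive the limiting F
  (p = 0 if group means differ, else p = 1) and are flagged.
  Signature-level comparisons use Bonferroni (p × m, capped at 1, flag at
  ≤ 0.001), matching the hallmark-collection analysis style.
- **Contingency tests** — two-sided Fisher exact with the point-probability
  rule for 2×2 (needed to reproduce the printed study tables); Pearson χ²
  **without** continuity correction otherwise. `auto` uses Fisher for a 2×2
  with any expected count < 5; for larger tables auto falls back to χ²
  (no r×c exact test is implemented). Wilcoxon rank-sum: exact enumeration
  when the combined n ≤ 20 without ties, else the tie-corrected normal
  approximation.
- **Survival** — Kaplan–Meier product-limit with Greenwood variance (events
  precede censorings at tied times); k-sample log-rank χ² with k−1 df.
  Cohort stratification restricts to stage II–III by default.
- **k-means split** — k = 2 on per-gene z-scored expression, 10 restarts,
  fixed seed, samples ordered by sorted id before fitting so the split is
  invariant to input order; the HIGH label goes to the cluster with the
  larger mean z-score. Whether the original analysis z-scored before
  clustering is unstated; z-scoring is this package's choice (it stops
  high-variance genes from dominating the Euclidean metric).
- **PCA** — on per-gene z-scores, full SVD, deterministic sign convention
  (each component's largest-magnitude loading made positive).

## Numerical conventions

- All expression values are log2-scale unless flagged as counts; counts are
  validated non-negative integers.
- Matrix TSVs are written with 8 significant digits so reruns diff cleanly.
- Every generator and analysis taking randomness accepts an integer seed and
  is a pure function of its inputs including that seed.
- Strict inequalities at every 0.5 call threshold and at the 3 µM Kd cutoff.

## Validation experiment sizes

`cmskit.benchmarks` runs the recovery/calibration experiments at these
design points (used by both the test suite and the reproduction script):
screen recovery over 100 replicates of two 500-sample cohorts; tumor-call
accuracy on 1500 tumors per heterogeneity rate; mixed-model calibration on
2000 null and 500 planted-shift fits; clustered correlation over 500
replicates of 20 clusters × 10; DE screen over 500 null and 25 planted
replicates of 2000 genes × 10+10 samples; log-rank calibration over 1000
null replicates (100/arm) and 100 powered replicates (500/arm);
Fisher-vs-enumeration on 1000 random tables with margins ≤ 60; end-to-end
stratification over 100 replicates of 400-sample cohorts.

## Known limitations

- The published 273-gene random-forest classifier object and its gene panel
  are not reproduced; the piggyback path trains a fresh probabilistic
  classifier on whatever labeled reference is supplied.
- The shipped GMT gene sets are small illustrative stand-ins (labelled as
  such); substitute full published collections for real analyses.
- The clustered-correlation sandwich variance is asymptotic in the number of
  clusters; with very few clusters its p-values are approximate.
- Fisher's exact test is implemented for 2×2 tables only.
- No Cox regression or multivariate survival adjustment; survival
  comparisons are KM/log-rank only.
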