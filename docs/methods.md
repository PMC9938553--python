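# Methods

`crcmeth` implements a stool/blood DNA-methylation diagnostic workflow for
colorectal cancer (CRC) and advanced adenoma (AA): discovery-stage CpG-site
screening on 450K-style beta-value matrices, qMSP (quantitative
methylation-specific PCR) Ct processing and positivity calling, a combined
two-marker logistic diagnostic score, and cohort-level performance
evaluation. This note records the models, the parameters that matter, the
synthetic-data design, and the numerical and design choices made where the
procedure left room.

## Screening cascade (`crcmeth.screening`)

The substrate is a matrix of beta values (fraction methylated, β ∈ [0, 1])
over CpG sites × samples, with each sample in a tumor, adjacent-normal, or
peripheral-blood arm. Stages, each a pure set filter over per-site
statistics:

1. **Differential filter.** Keep sites with Δβ = mean β(tumor) − mean
   β(normal) ≥ `delta_min` (default 0.2), two-sided Wilcoxon rank-sum
   P < `p_max` (default 0.01, uncorrected), and mean tumor β ≥
   `beta_tumor_min` (default 0.2). The P threshold is applied raw by
   design; Benjamini–Hochberg correction is available via
   `p_adjust="fdr_bh"` for users who want FDR control.
2. **Blood rescreen.** A stool or plasma assay fails if the marker has
   background methylation in blood leukocyte DNA. The default rule keeps
   sites whose tumor-minus-blood mean β margin is ≥ `blood_margin_min`
   (default 0.25). The criterion is ambiguous between a difference and an
   absolute blood level; both are implemented
   (`blood_rule="margin" | "absolute"`) with the difference reading as
   default.
3. **Ranking** by Δβ descending, ties by ascending P then site id — fully
   deterministic.
4. **Optional gene restriction** to a whitelist of prior-evidence genes
   (e.g. SDC2, SHOX2). This encodes a literature judgement, not an
   algorithm, and is therefore a plain configuration input.
5. **Random-forest selection.** A tumor-vs-normal forest (500 trees,
   impurity importance, fixed seed) ranks the candidates; within the top
   `2 × n_select` by importance, sites with lower mean normal-tissue β are
   preferred (an unmethylated normal background is what makes a marker
   usable), and exactly `n_select` (default 2) sites are returned.

Arm summaries are means by default (`summary="median"` available). The
rank-sum test uses exact enumeration when both arms have ≤ 8 untied values
and the normal approximation with tie and continuity correction otherwise.

## qMSP processing (`crcmeth.qmsp`)

Each sample is measured in triplicate wells per target (two CpG markers
plus the ACTB reference). The rulebook, applied per sample:

* **Reference QC:** invalid if ACTB exceeds Ct 33 (or is undetected) in at
  least 2 of 3 wells. The inequality is strict: Ct = 33.0 passes.
* **Aggregation:** mean Ct over detected wells when ≥ 2 of 3 amplified,
  else the target is undetected. Averaging only the detected wells is the
  one reading consistent with tolerating 2-of-3 detection.
* **Imputation:** on a QC-valid sample an undetected target is assigned
  Ct 33 and flagged. Since 33 exceeds every positivity bound, imputed
  targets are always negative — non-amplification is treated as absence of
  methylated template, never discarded.
* **Calling:** positive iff mean Ct is strictly below the (matrix, marker)
  bound — stool: 31 (cg13096260) and 32 (cg12993163); blood: 25 for either
  marker. Equality is negative.
* **Tissue samples** are summarised as ΔCt = Ct(target) − Ct(ACTB) (lower
  ΔCt ⇔ more methylated template) and are exempt from the stool/blood
  bounds; tumor-vs-normal comparisons are paired on ΔCt.

A sample whose ACTB is valid but whose marker amplified in only 1 of 3
wells fails the 2-of-3 rule and is imputed (the single well is not used);
this case is underdetermined by the rulebook and the conservative reading
was chosen.

## Diagnostic model (`crcmeth.model`)

The combined score is the linear predictor of a logistic regression of
disease status (1 = CRC or AA, 0 = NED) on the two marker mean Cts:

    score = β₀ + β₁·Ct(cg13096260) + β₂·Ct(cg12993163)

Marker coefficients are negative — lower Ct (more methylated template) is
more disease-like. A frozen published instance
(β₀ = 15.7174, β₁ = −0.3146, β₂ = −0.2224) ships as packaged JSON; it is
evaluated by pure arithmetic and never refit.

* **Fitting** uses maximum-likelihood GLM (binomial family). Under
  (quasi-)complete separation the MLE diverges; the fit falls back to a
  ridge-penalised logistic regression (C = 100) with a warning.
* **Stratified 2:1 split:** per stratum (clinical group, CRC sub-stratified
  by stage I–II vs III–IV) the training count is round-half-up of
  ratio × n; membership is seeded, counts are deterministic. Round half up
  is what reproduces a 31/15 training/validation split of 46 AA samples.
* **ROC/AUC:** empirical curve over all distinct thresholds, trapezoidal
  AUC (ties get half credit, making AUC identical to the Mann–Whitney
  U/(n₁n₂) identity, which the tests verify by brute-force pair counting).
* **Cut-off:** Youden index (sens + spec − 1) maximised on the training
  set by default; ties break toward higher specificity. The returned
  cut-off is the midpoint between the optimal decision boundary and the
  next higher observed score. Whether cut-offs should come from the
  training or validation set is genuinely ambiguous in practice; both are
  supported and training-set selection is the default, matching standard
  practice. Classification is strict: positive iff score > cut-off.
* **AUC confidence intervals** are not emitted by default; a bootstrap is
  the recommended route if needed (no analytic CI method is canonical
  here).

## Evaluation (`crcmeth.evaluate`)

* **Sensitivity/specificity** are k-of-n binomial proportions over disjoint
  denominators (diseased / NED controls) with two-sided 95%
  Clopper–Pearson intervals by default (`ci_method="wilson"` available).
  Clopper–Pearson was chosen as the exact method whose widths best match
  conventional clinical reporting at these sample sizes.
* **Interfering-disease negative rates** are reported per subgroup and
  pooled; pooling is total negatives over total n, never the unweighted
  mean of subgroup rates.
* **Paired tissue comparison** counts pairs with tumor ΔCt below the paired
  normal and tests the paired differences with the Wilcoxon signed-rank
  test.
* **Group-level comparisons** (NED / AA / CRC I–II / CRC III–IV) use
  pairwise two-sided rank-sum tests with a presentation-only star
  convention (*P<0.05, **P<0.01, ***P<0.001).
* **Association tests** use chi-square when all expected cell counts are
  ≥ 5 and Fisher's exact test otherwise; Fisher is only defined here for
  2×2 tables, and sparse r×c tables fall back to chi-square with a notice.
* **Flow accounting** places every participant in exactly one arm (main /
  interfering / excluded-by-reason) and validates flag consistency.

Display percentages round half-up to 2 decimals; raw fractions are always
retained in machine-readable output.

## Synthetic data (`crcmeth.synth`)

The generators emulate the structure of the study's data, not any real
cohort:

* **Beta matrices.** Background sites are iid Beta(2, 8) (mean β = 0.2) in
  all arms; spiked CRC-hypermethylated sites keep that background in the
  normal and blood arms and have the tumor mean raised by `delta_spike`
  (default 0.4) at matched concentration. Defaults: 1000 sites, 40 samples
  per arm, 50 spiked sites — sized so the screening cascade runs in
  seconds while the spiked effect (≈ 7 standard errors of a mean
  difference at n = 40/arm) mirrors the near-certain recovery a Δβ ≥ 0.2
  filter has on genuinely hypermethylated sites at discovery-cohort sizes.
  What this does **not** model: probe-level noise structure, spatial
  correlation along the genome, cell-type composition effects, or
  missingness patterns of real arrays — so passing recovery tests says the
  cascade logic is right, not that the thresholds are optimal on real 450K
  data.
* **qMSP plates.** Each sample's true Ct per marker is Normal around its
  (group, target) plate mean with between-sample spread `sample_sd`
  (default 2 cycles) of which a fraction `marker_rho` (default 0.8) is
  shared between the two markers — both ride on the same tumor-DNA
  fraction. Replicate wells add Normal noise `ct_sd` (default 0.5). Draws
  past the 40-cycle run, or random dropout (`p_well_dropout`), come back
  undetected — an explicit sentinel, never a number. Reference failures
  (`p_actb_fail`) shift ACTB above the QC bound. Default group means are
  placed so that threshold calling lands in the sensitivity/specificity
  range typical of stool methylation assays (diseased groups a few cycles
  below the bound, NED above it); they are calibration knobs describing a
  plausible assay, not estimates of any dataset.
* **Rosters** assign exactly the requested exclusion-flag counts; the
  default CLI parameters reproduce the study-scale flow (515 enrolled,
  12 + 25 + 32 excluded, 24 interfering, 422 analysed).

All generators are bit-reproducible under a fixed seed; the end-to-end
pipeline derives per-stage seeds from one global seed via
`numpy.random.SeedSequence` so every stage is independently rerunnable.

## Numerical and testing choices

* Exact small-sample rank-sum enumeration switches to the asymptotic
  approximation above 8 per arm; at one observation per arm the two-sided
  P is 1 (underpowered, never significant).
* Type-I calibration of the rank-sum and Fisher tests is computed
  *exactly* rather than by Monte Carlo: the rank-sum p-value for
  continuous data depends on the data only through U, so the rejection
  rate is the exact null-pmf mass of the rejection region (counting
  recurrence for the U distribution); Fisher's rejection rate is an exact
  expectation over enumerated 2×2 tables with Binomial(100, 0.5) margins.
  Both land near 0.04–0.048 at α = 0.05 — slightly conservative, as exact
  tests are. The calibration sizes (30 per arm; 100 per row) were chosen
  so discreteness does not dominate: at very small n both tests are
  markedly conservative and a ±2% calibration band around α is not a
  meaningful check.
* Clopper–Pearson coverage is likewise verified by exact enumeration over
  binomial outcomes (coverage ≥ 95% at every (p, n) checked), which is
  noise-free where an empirical estimate at a few hundred replicates is
  not.
* Logistic parameter recovery is exercised at n = 2000 with marker Cts
  drawn Normal(30, 5) clipped to (12, 39) — a spread wide enough that the
  Fisher information identifies both coefficients to well within 15%
  relative error per fit.
* Degenerate inputs: single-class labels refuse to fit; a single distinct
  score value yields a flagged degenerate cut-off; empty strata are
  allowed in the split; empty groups are skipped with a notice in group
  comparisons.

## Problem sizes

The shipped tests and the acceptance script run the screening cascade at
1000 sites × 120 samples (10 seeds), logistic recovery at 20 × 2000
observations, the AUC identity on 100 random instances of n ≤ 50, and the
end-to-end demo at ~100 stool samples — sizes at which every quantity of
interest is already stable, chosen as the package's own defaults for fast,
reproducible verification.

## Known limitations

* The screening module assumes pre-normalised beta values; no IDAT/array
  preprocessing, probe filtering, or batch correction is provided.
* Ct values are taken as instrument output; there is no amplification-curve
  fitting or baseline correction.
* The combined model is deliberately the plain two-marker logistic score;
  no regularised or multi-marker alternatives are offered.
* Synthetic defaults describe a plausible assay, and results on them do not
  transfer quantitatively to any real cohort.
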