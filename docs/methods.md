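# Methods

## Scope and data model

The package analyses one cross-sectional patient table (one row per adult
ARDS patient: age, sex, comorbidity-count category, SOFA, PaO₂/FiO₂,
baseline RDW, and nested ICU / in-hospital / 90-day death flags) and one
long-format table of RDW measurements (patient, days since diagnosis,
RDW %). Outcome nesting (ICU ⇒ in-hospital ⇒ 90-day death) is enforced at
validation: an ICU death is by definition an in-hospital death, and an
in-hospital death precedes day 90. Missing required fields are hard
errors — the models are complete-case by construction, and silent listwise
deletion is deliberately not offered.

## Risk models

Both mortality models are plain maximum-likelihood logistic regressions
(IRLS, deviance tolerance 1e-8, 50-iteration cap), with the comorbidity
category dummy-coded against "0 conditions" and sex as a male indicator.
Confidence intervals are Wald: exp(β ± 1.96·SE). PaO₂/FiO₂ enters per
unit (mmHg), so its odds ratio is close to 1 by scale, not by weakness.
No regularisation is applied; complete separation therefore surfaces as a
non-converged fit that the reporting layer refuses to summarise, rather
than being silently penalised. Linearity diagnostics (e.g. restricted
cubic splines) are out of scope in this version; terms are linear.

## Added-value metrics

All three comparisons use apparent (in-sample) performance: both models
are fitted and evaluated on the same cohort, with no cross-validation or
optimism correction. That matches common clinical-literature practice and
keeps every number reproducible from one table, but it overstates
out-of-sample gains; the limitation is inherited deliberately.

* AUC: Mann–Whitney estimator (mid-ranks; ties contribute ½).
* ΔAUC inference: DeLong's paired structural-components variance,
  normal-theory two-sided p. The implementation agrees with an
  independent reference implementation to 7 significant figures on a
  frozen fixture, and its 5% rejection rate is nominal (measured 0.049
  over 2,000 replicates) when the two score vectors are fixed, the
  setting the variance theory assumes. Applied to *nested models refit on
  the same data* under the null of a useless added covariate, the test is
  known to be severely conservative (measured rejection rate ≈ 0.002 at
  n = 300); the package still exposes it in that role because that is how
  the comparison is conventionally reported, but a paired bootstrap
  (`model_comparison.bootstrap_ci`, seeded, 2,000 resamples by default)
  is provided for users who want resampling-based intervals instead.
* Continuous NRI: net version (event and non-event components each in
  [−1, 1]; exact ties in predicted risk count in neither direction). The
  gross one-directional variant is available via `net=False` for
  comparison with the older verbal definition. The asymptotic SE is
  √(v_e/n_e + v_ne/n_ne) with v = p_up + p_down − (p_up − p_down)².
* IDI: difference of mean risk-change between events and non-events, SE
  from the two group sample variances.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable at will.
Its defaults encode the published study conditions:

| quantity | default | source of the target |
|---|---|---|
| n | 318 | cohort size |
| age | mean 58.6, SD 18.3, truncated [18, 100] | baseline table |
| male proportion | 165/318 | baseline table |
| SOFA | mean 10.1, SD 4.6, integer, [0, 24] | baseline table |
| PaO₂/FiO₂ | mean 140.8, SD 73.3, [40, 400] | baseline table |
| baseline RDW | mean 15.3, SD 2.3, [11, 30] | baseline table |
| comorbidity-category probabilities | (0.30, 0.30, 0.20, 0.20) | chosen; only condition prevalences were published, not the joint count distribution |
| outcome log-ORs | ln(1.05), ln(1.53), ln(1.02), ln(0.88), ln(0.84), ln(1.08), ln(0.995), ln(1.22) | enhanced-model odds ratios |
| target ICU mortality | 0.355 | reported rate |
| extra in-hospital death probability q_hosp | (0.44 − 0.355)/(1 − 0.355) | makes the in-hospital marginal 0.44 |
| extra 90-day death probability q_90 | 0.05 | chosen: modest additional mortality between discharge and day 90 (no 90-day rate was published) |
| trajectory mixture | (26, 24, 174, 29, 19)/272 | trajectory-class frequencies |
| class-conditional hospital mortality | 8/26, 8/24, 70/174, 14/29, 11/19 | class mortality table |
| ≥ 4-measurement proportion | 272/318 | reported exclusion count |

Distributional choices:

* **Moment-matched truncation.** Covariates are truncated normals whose
  *parent* mean/SD are solved (once, cached) so the truncated
  distribution has exactly the target mean/SD. Naive truncation of
  N(15.3, 2.3) at [11, 30] would bias the RDW mean upward by ≈ 0.17;
  moment matching removes that bias at the source. Covariates are drawn
  independently — only marginals were published — so real-data
  correlations (e.g. SOFA with PaO₂/FiO₂) are absent.
* **Intercept calibration.** The logistic intercept is found by bisection
  on [−20, 20] against the mean predicted risk over a ≥ 10n covariate
  sample (tolerance 1e-3), so the simulated ICU mortality hits its target
  marginally rather than per-patient.
* **Two mortality modes.** The cross-sectional model and the
  class-conditional mortality table cannot both be exactly generative at
  once. `mortality_mode="model"` (default) draws ICU death from the
  logistic model and adds independent conditional extra mortality for the
  wider outcomes; `"class_linked"` draws in-hospital death from the
  class-conditional rates (marginal 111/272 ≈ 0.408) and thins it to keep
  the ICU marginal at 0.355. The flag makes the choice explicit per
  experiment.
* **Trajectories.** Each patient's series is b₀ + b₁t + b₂t² + N(0, σ)
  with b₀ the patient's own baseline RDW, coefficient signs fixed by the
  class, times uniform over a 14-day follow-up, and values floored at
  11% so they stay physiologic. Default ranges (|b₁| 0.2–0.5 %/day,
  |b₂| 0.02–0.045 %/day², σ = 0.3) give roughly 75–90% per-class
  detection power at ~10 measurements. Because classes are defined by
  per-patient significance, weak draws are absorbed into "none": the
  classified shares of a default cohort under-represent the trend classes
  relative to the generating mixture, exactly as underpowered patients
  would be in real data. Measurement counts mix short stays (2–3
  measurements, later excluded) with adequately sampled stays (4 +
  Poisson(6), near-daily CBCs), hitting the 272/318 ≥ 4-measurement
  proportion.
* **Seeding.** One master integer seed; every covariate, outcome layer,
  class assignment, and patient series draws from its own named
  substream, so identical (config, seed) pairs are bit-identical and
  enlarging the cohort leaves earlier patients' draws untouched.

What passing generator-based tests shows: the estimators recover known
generating parameters (odds-ratio CI coverage ≥ 90/100 at n = 5,000),
discrimination gains appear when the biomarker signal is real and vanish
when it is zeroed, and trajectory classification recovers strong signals
(≥ 90% per class at σ = 0.1). What it does not show: behaviour under
covariate correlation, informative measurement timing, missingness, or
model misspecification — none of which the generator emulates.

## Trajectory classification

Per-patient OLS with t-tests on b₂ then b₁ (residual df = n − 3), α = 0.05
two-sided, minimum 4 measurements and ≥ 3 usably distinct times
(quadratic identifiability). The quadratic check takes precedence over
the linear one. Exact fits (zero residual variance, e.g. noiseless
prototypes) make t-statistics undefined; there a coefficient counts as
significant iff |b| > 1e-10. Concave (b₂ < 0) series end falling and are
grouped "late-down" with downtrending; convex end rising, grouped
"late-up" with uptrending. A pooled linear mixed model (fixed 1 + t + t²,
random per-patient intercept and slope, REML) is reported as a
cohort-level description; it does not drive the labels, because a
per-patient significance rule is the only fully specified classification
procedure, whereas BLUP-based class tests admit many variants.

## Contingency tests

Pearson chi-square without continuity correction; two-sided Fisher tests
use the point-probability rule (sum of same-margin tables no more
probable than the observed one, with a 1e-7 log-probability tolerance
against ties lost to rounding). The R×C exact test enumerates all
same-margin tables (default bound 10⁷; the 5×2 trajectory table has
~4×10⁵) and the Monte-Carlo variant samples tables from the
margin-conditional null via sequential multivariate-hypergeometric row
draws, reporting (1 + hits)/(1 + N). For the combined late-up vs
late-down 2×2 comparison the package reports both the Fisher p (0.065 on
the published counts) and the uncorrected chi-square p (0.044) without
claiming either is "the" published test, since the two straddle 0.05.

## Pipeline and reporting

`run_pipeline` chains simulate/load → baseline table → model fits →
added-value comparisons (three outcomes) → trajectory classification →
association tests, and emits a JSON report at full precision plus a text
report at display precision (AUC 3 dp, OR 2 dp, percentages 1 dp).
Timestamps and timings go to the stage log on stderr, never into the
report, so identical (config, seed) runs produce byte-identical JSON.

## Numerical and degenerate-input choices

* Predicted probabilities are clipped to the open unit interval at float
  resolution so downstream logs never see exactly 0 or 1.
* Rank deficiency is detected on the column-normalised design via QR
  (threshold 1e-8) and reported with the offending column names.
* A 2×2 table with a zero margin yields Fisher p = 1 with a degenerate
  flag; chi-square on a zero margin is an error.
* Single-patient groups report SD as not-available rather than 0 or a
  division error.
* Baseline-SD of the generator's SOFA is matched before integer rounding;
  rounding changes the SD by < 2%.

## Problem sizes in the test suite

The statistical suites run at: 100 replicates of n = 5,000 for
generator→fit odds-ratio recovery and AUC dominance; 2,000 replicates of
n = 300 for the null-rejection study; 500 series per class for trajectory
recovery; 2,000 replicates of n = 200 for the fixed-scores DeLong
calibration check. These sizes put Monte-Carlo error comfortably inside
the asserted bands while keeping the whole suite inside a few minutes on
one CPU.
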