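# rdwprog

Does red-cell distribution width (RDW) — a routine, no-extra-cost component
of the complete blood count — add prognostic value to a clinical mortality
model for acute respiratory distress syndrome (ARDS)? `rdwprog` is a tested
Python library for answering that class of question: it fits base and
biomarker-enhanced logistic mortality models, quantifies the biomarker's
incremental value, classifies longitudinal biomarker trajectories, and
tests trajectory–mortality association — together with a synthetic ICU
cohort generator calibrated to published ARDS summary tables, so the whole
pipeline is exercisable without access to the original restricted ICU
database.

It is written for biostatisticians and clinical researchers evaluating
candidate prognostic markers on patient-level data (their own CSVs) or on
simulated cohorts.

## The statistics at the core

For each outcome (ICU, in-hospital, 90-day death) two nested logistic
models are fitted by IRLS:

* base: logit P(death) = β₀ + β·(age, male, comorbidity category, SOFA, PaO₂/FiO₂)
* enhanced: base + β_RDW · RDW at diagnosis

with Wald 95% intervals on the odds ratios. Added value is quantified
three ways, on in-sample predicted risks p̂_base, p̂_new:

* **ΔAUC** — Mann–Whitney AUCs compared with DeLong's paired
  placement-value variance: z = ΔAUC / SE(ΔAUC).
* **Continuous NRI** — net proportion of events with p̂_new > p̂_base plus
  net proportion of non-events with p̂_new < p̂_base (range −2 to 2; ties
  count in neither direction).
* **IDI** — (mean p̂_new − mean p̂_base | events) + (mean p̂_base − mean
  p̂_new | non-events).

Each patient's longitudinal RDW series (≥ 4 measurements) gets a quadratic
fit RDW = b₀ + b₁t + b₂t²; a significant quadratic term classifies the
trajectory as concave (b₂ < 0) or convex (b₂ > 0), else a significant
linear term as up/downtrending, else no trend. Class–mortality association
uses the uncorrected Pearson chi-square and Fisher exact tests (2×2 and
enumerated/Monte-Carlo R×C).

## Worked example

```python
from rdwprog import GeneratorConfig, generate_cohort, compare_models

cohort, series = generate_cohort(GeneratorConfig(n=318, seed=1))
c = compare_models(cohort, outcome="icu")
print(f"AUC {c.auc_base:.3f} -> {c.auc_new:.3f}, p = {c.delong.p:.3f}")
print(f"NRI {c.nri.total:.3f}, IDI {c.idi.total:.3f}")
```

prints

```
AUC 0.772 -> 0.797, p = 0.046
NRI 0.316, IDI 0.039
```

i.e. on this simulated 318-patient cohort adding RDW raises the model's
probability of ranking a death above a survival from 0.772 to 0.797
(DeLong p = 0.046), with a net 31.6% of patients reclassified in the right
direction and a 0.039 gain in mean risk separation between deaths and
survivors. Longer narrative scripts live in `examples/` — one per
capability (simulation, incremental value, trajectory classification,
association tests, full pipeline report).

A thin CLI wraps the same functions:

```bash
rdwprog simulate --n 318 --seed 1 --out-dir out/
rdwprog report --config config.yaml --out-dir out/
```

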