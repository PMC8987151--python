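# hkburden

Matched-cohort burden-of-illness analysis of hyperkalemia (HK) in
patients with chronic kidney disease (CKD), built for administrative
claims data. The package takes longitudinal claims tables — enrollment
and demographics, inpatient/outpatient claims with ICD-10 diagnosis
codes and itemized costs, and drug-class prescriptions — and produces a
complete study: new-onset CKD cohort construction, HK vs. non-HK
assignment, two-stage propensity matching with balance diagnostics,
survival analysis, and survival-adjusted annual cost / healthcare
resource utilization (HRU) estimation with bootstrap confidence
intervals.

It is aimed at health-economics and pharmacoepidemiology analysts who
need a tested, reproducible implementation of this design — in
particular of the survival-weighted cost estimator, which is rarely
available off the shelf. Because real claims systems (e.g. UEBMI) are
restricted, the package ships a synthetic-claims generator with known
ground truth (true hazard ratio, closed-form true mean annual cost per
arm) so every stage is testable at desk scale.

## The statistical core

**Why not just average annual costs?** When one cohort dies much faster
than the other, naive annualized means confound cost intensity with
survival time. The Kaplan-Meier sample average (KMSA, a Lin-type
estimator) corrects this: with 30-day intervals *k = 1..12* post-index,

&nbsp;&nbsp;&nbsp;&nbsp;Ĉ = Σₖ Ŝ(t₍ₖ₋₁₎) · C̄ₖ

where Ŝ is the cohort's Kaplan-Meier survival at the interval start and
C̄ₖ the mean cost (or HRU count) in interval *k* among patients alive
and enrolled at the interval start; patients dying mid-interval
contribute their observed partial-interval outcomes. With no deaths the
estimator reduces exactly to the plain mean of annual totals.
Confidence intervals come from a paired bootstrap that resamples
matched pairs and recomputes both cohorts' KM curves and estimates in
each iteration.

Around that core: cohort rules (index-period diagnosis, 1-year washout,
12-month pre/post enrollment with death allowed), 1:30 coarse matching
on sex / diagnosis year / age, a logistic propensity model over the
baseline covariates (demographics, CCI, comorbidities, drug classes,
baseline HRU and cost), greedy 1:1 nearest-neighbor matching on the
logit score with a 0.2-SD caliper, standardized-difference balance
checks (|d| ≤ 0.10), Kaplan-Meier / log-rank / Cox mortality analysis,
and malignancy-exclusion and survivors-only sensitivity analyses.

## Worked example

```python
from hkburden import SimulationConfig, simulate_population, AnalysisConfig, run_pipeline

config = SimulationConfig(n_patients=6000, rng_seed=11)
dataset, truth = simulate_population(config)
report = run_pipeline(AnalysisConfig(seed=5, n_bootstrap=500), data=dataset)

print(report.mortality[["period", "mortality_hk", "mortality_control", "hr",
                        "hr_ci_low", "hr_ci_high"]].round(3).to_string(index=False))
cost = report.hru_cost.set_index("outcome").loc["cost_total"]
print(f"difference: {cost['difference']:.0f} "
      f"[{cost['diff_lo']:.0f}, {cost['diff_hi']:.0f}]")
```

prints

```
  period  mortality_hk  mortality_control    hr  hr_ci_low  hr_ci_high
12-month         0.399              0.113 4.261      2.876       6.311
   total         0.700              0.254 4.433      3.368       5.836
difference: 37334 [30931, 43094]
```

Reading it: among 283 matched pairs drawn from 6,000 simulated CKD
patients, 39.9% of the HK cohort vs. 11.3% of matched controls died
within 12 months (Cox hazard ratio 4.26, 95% CI 2.88–6.31; the
generator's true HR is 5.39 and sits inside the CI). The
survival-weighted annual cost difference is ¥37,334 (bootstrap 95% CI
30,931–43,094) against a generator ground truth of ¥37,302 — the
estimator recovers the configured burden. `report` also carries the
attrition table, pre/post-match balance tables, the monthly cost
series, per-admission/per-visit subset summaries, and both sensitivity
analyses; `report.write(out_dir)` emits everything as CSV plus a JSON
manifest from which `hkburden report` can regenerate the run.

A CLI covers the same flow: `hkburden simulate --config sim.yaml --seed 1
--out data/`, `hkburden run --config analysis.yaml --out report/`,
`hkburden report --manifest report/manifest.json --out report2/`.

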