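# Methods

This note documents the statistical procedures the package implements,
the conventions and defaults it fixes, what the synthetic-data
generator does and does not emulate, and the numerical choices that
matter for reproducibility.

## Conventions

* **Calendar.** Dates are integer days; a *month* is exactly 30 days
  everywhere. Post-index intervals are half-open, interval *k* =
  `[30(k-1), 30k)` days from the index date; the 12-month horizon is
  360 days. Age is `floor(days / 365.25)` years.
* **Currency** is unitless in computation; reports label it with a
  configurable symbol (default ¥).
* **Determinism.** Every stochastic step (generator, bootstrap) takes a
  seed; identical configuration and seed reproduce byte-identical
  tables. Matching is fully deterministic; all ties break by ascending
  patient id.

## Cohort construction

New-onset CKD = earliest CKD-coded claim (configurable ICD-10 prefix
list; prefix matching, so `N18` covers `N18.5`) falls inside the index
period, the patient is ≥ 18 at that date, and enrollment covers a
360-day pre-diagnosis washout (length configurable). HK membership
requires an HK-coded claim (default `E87.5`) strictly *after* the CKD
diagnosis; its earliest date is the index date. Non-HK candidates have
no HK-coded claim anywhere in the data window (the window is
configurable; default = full data). Patients whose only HK claims
precede the CKD diagnosis are in neither cohort.

The enrollment rule keeps members whose merged enrollment spans
(adjacent spans are fused) cover `[index − 360, index + 360]`, or
`[index − 360, death]` when death comes first — discontinuation due to
death is allowed. Follow-up ends at the earliest of enrollment end,
death, and the study end. Baseline covariates come strictly from the
window `[index − 360, index)`: comorbidity flags via a configurable
code map, drug-class flags from prescriptions, baseline HRU and total
cost from claims, and the Charlson index via a Quan-style ICD-10
mapping with the original weights, shipped as an editable CSV
(`src/hkburden/data/charlson_icd10.csv`) with the usual severity
hierarchy (metastatic > non-metastatic cancer, etc.).

## Matching

The phrase "1:30 propensity score matching on sex, year and age" in
this design family is internally inconsistent (three variables do not
define a propensity score), so stage 1 is implemented as a
deterministic coarse pool: exact match on sex and CKD-diagnosis
calendar year, nearest by age at diagnosis, up to 30 per HK member,
without replacement. Selection is **round-robin** — every HK member
takes its nearest unused candidate before any member takes a second —
so a scarce stratum is shared rather than exhausted by the members
processed first; with candidate-to-case ratios below 30 the sequential
alternative would leave later HK members with no controls at all.
Selected controls inherit their partner's index date, after which the
enrollment filter is re-applied (this also removes controls already
dead at the inherited index).

Stage 2 fits a maximum-likelihood logistic model of HK membership on
the full baseline covariate vector (constant columns dropped;
convergence tolerance 1e-8, 100 iterations; perfect separation falls
back, with a warning, to a ridge penalty of 1e-6). Greedy 1:1
nearest-neighbor matching without replacement runs on the logit score,
HK members in descending score order, caliper 0.2 × SD of the logit
score (configurable, including none). These are the standard Austin
recommendations; the original study does not state its algorithm, so
the report manifest records the choices as assumptions.

Balance is reported as signed standardized differences (HK minus
control): continuous `d = (m₁−m₂)/√((s₁²+s₂²)/2)` with sample SDs,
binary `d = (p₁−p₂)/√((p₁(1−p₁)+p₂(1−p₂))/2)`; 0/0 defines d = 0, and
zero pooled variance with unequal means is an error rather than a
silent infinity. |d| ≤ 0.10 is flagged as balanced. The t-test / χ²
p-values in the balance tables are descriptive only; matching never
selects on them.

## Survival analysis

Kaplan-Meier estimation, the two-group log-rank test, and Cox
estimation of the HK indicator are delegated to lifelines and
statsmodels (`PHReg`). Tied deaths and censorings on the same day are
resolved deaths-first (the product-limit convention). Cox tie handling
is Breslow by default — adequate at daily resolution — with Efron
available; Wald 95% CIs and p-values are reported. A cohort with zero
events makes the partial likelihood monotone: the fit warns and
reports a lightly penalized estimate instead. Two horizons are
analyzed: 360 days and the full follow-up. The Cox model is
unstratified (cohorts are balanced by matching; pair-stratified
estimation was considered and left out because the matched-pair
structure is already respected by the bootstrap).

## KMSA estimation

For each cohort, outcome and interval, the conditional mean C̄ₖ is
taken over patients alive **and enrolled** at the interval start;
patients dying or disenrolling mid-interval contribute their observed
partial-interval outcomes, with no within-interval survival adjustment
(the known bias of this convention is small on a monthly grid). An
admission's full cost and length of stay (discharge − admission + 1)
belong to the interval containing the admission date, so the index
hospitalization lands in interval 1. The point estimate is
Ĉ = Σₖ Ŝ(30(k−1))·C̄ₖ with Ŝ the cohort's own KM curve estimated from
the same sample (and re-estimated inside every bootstrap iteration).
Costs and HRU counts flow through identical machinery. Two exact
reductions are enforced by tests: with all weights 1 the estimate
equals the plain mean of annual totals, and the six cost components
always sum to the corresponding totals.

Inside the bootstrap a vectorized integer-day product-limit routine
supplies Ŝ at the twelve interval starts; it is tested to agree with
lifelines to 1e-12 on random samples. Percentile intervals (simplest
valid choice for heavily skewed costs) are computed per cohort and for
the HK-minus-control difference; the difference's two-sided p-value is
the proportion of resampled differences crossing zero, labelled as
bootstrap-based since the original design names no test for it. Each
iteration resamples matched *pairs* with replacement. The default
resamples as many pairs as exist (full-n, the statistically standard
choice); the m-out-of-n variant (e.g. 500 of ~1,000 pairs), which
widens intervals, is available via `pairs_per_iteration`. Reported
differences are computed before any rounding.

## Sensitivity analyses

Both are pair-level exclusions that preserve the matched design and do
not re-match: (1) drop every pair in which either member has a
malignancy-coded claim anywhere in the data window; (2) keep only pairs
in which both members are alive and enrolled through day 360 — there
the KM weights degenerate to 1 and the estimates equal plain annual
means (an exact property, tested). The survivors-only table omits
12-month mortality, which is zero by construction.

## The synthetic-claims generator

The generator emulates the data-generating structure this design
assumes, with defaults chosen to mirror the emulated study's reported
conditions: ~5% of 20,000 new-onset CKD patients become HK (≈ 1,000
matched pairs), mean age 67.2 (SD 14.3), 40% female, study-like
comorbidity and drug-class prevalences, a control-arm 12-month
mortality near 8.3% and an HK log hazard ratio of ln 5.39, ~3
outpatient visits per person-month, and steady monthly cost levels
(¥3,775 HK / ¥1,800 control) plus a mean ¥22,204 index-month inpatient
spike, chosen so the annual survival-weighted costs land near the
reported ¥59k / ¥21k levels. Costs are log-normal per claim, split
across the six components by configured shares.

Key mechanisms:

* **Confounding.** Comorbidity flags shift both the log-odds of HK
  membership (intercept solved numerically so the marginal HK fraction
  matches `hk_fraction`) and the log death hazard, so the raw cohorts
  are imbalanced and matching has real work to do.
* **Death clocks.** HK patients draw an exponential death time from
  their index date (no pre-index HK deaths). Control patients draw one
  from their CKD diagnosis; memorylessness then makes the residual time
  from *any* later assigned index exactly exponential at the same rate,
  which is what lets matched controls inherit index dates without
  distorting the configured hazard. Controls dead before an inherited
  index are removed by the enrollment filter.
* **Cost process.** Steady costs arrive as Poisson streams of
  outpatient visits and admissions whose expected monthly total equals
  the configured mean; claims never post after the death day. Hence,
  conditional on being alive at an interval start, the expected
  interval cost is the monthly mean times an exact discrete retention
  factor `F(h) = (2 + Σ_{i=1..28} e^{−hi})/30` (per-day hazard h;
  F → 1 as h → 0). `truth_mean_annual_cost` evaluates
  Σₖ S(30(k−1))·M·F(h) (+ the spike for HK) exactly, enumerating the
  2^J comorbidity combinations that enter either the membership or the
  hazard model and weighting them by the HK arm's covariate
  distribution — the estimand of a treated-anchored matched design.
  The idealized continuous-time geometric sum `M·Σₖ e^{−30h(k−1)}` is
  recovered in the zero-hazard limit and differs by < 2% at the default
  hazards; tests assert the exact discrete form against an independent
  claim-day enumeration oracle.

What the generator does **not** emulate, and what passing tests
therefore do not establish about real claims: recurrent/relapsing HK
episodes, laboratory potassium values and CKD-stage progression,
free-text diagnoses, claim adjudication and transfer admissions,
seasonal or calendar-time cost trends, and cost dependence on
covariates beyond arm and survival. Recovery results show the
*estimators* are correct under the assumed structure, not that the
structure holds in any particular claims system.

## Problem sizes used in the test suite

Unit tests run on hand fixtures and populations of a few hundred to a
few thousand patients. The recovery checks use the sizes that make
their targets meaningful: Cox recovery uses 200 replicates of 1,000
patients per arm; bootstrap coverage uses 100 generator datasets of 600
patients with 400 full-n iterations each; the end-to-end run uses the
default 20,000-patient study with a 200-iteration bootstrap (CIs are
not the target there). The acceptance script runs the full default
study with the complete 1,000-iteration bootstrap.

## Known limitations

* The coarse 1:30 stage assigns each control to exactly one HK member;
  with very scarce strata this is a design choice, not the only
  reading of the original description.
* Percentile bootstrap intervals can undercover for extremely skewed
  cost outcomes at small pair counts; BCa intervals are not
  implemented.
* The Cox model reports a marginal HR; under covariate-dependent
  hazards this attenuates slightly relative to the conditional HR even
  after perfect matching.
* No competing-risk handling, regression-based cost modeling, or
  proportional-hazards diagnostics — deliberately out of scope for
  this design.
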