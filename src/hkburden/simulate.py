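"""Synthetic UEBMI-style claims generator with known ground truth.

The generator emulates the statistical structure a matched-cohort
hyperkalemia (HK) burden analysis assumes in real claims:

* new-onset CKD patients diagnosed inside a configurable index period,
  with continuous enrollment spans, optional coverage gaps, and an
  observed death mechanism;
* ICD-10-coded diagnoses (CKD codes, the HK code E87.5, comorbidity
  codes) on outpatient/inpatient claims with a six-component cost split;
* confounding: comorbidity flags shift both the probability of becoming
  an HK patient and the post-index death hazard, so the raw cohorts are
  imbalanced and propensity matching has real work to do;
* an exponential post-index death process with a configurable log hazard
  ratio for HK, and a cost process with a sharp inpatient spike in the
  first post-index month (the index hospitalization).

Death clocks
------------
Designated HK patients draw an exponential death time from their index
date (no pre-index deaths). Control-arm patients draw an exponential
death time from their CKD diagnosis date; by memorylessness the residual
time from *any* later assigned index date is again exponential with the
same rate, which is exactly what the recovery tests require. Controls
who die before an assigned index are removed by the enrollment filter.

Cost process and its closed form
--------------------------------
Steady costs arrive as a homogeneous Poisson stream of outpatient visits
and inpatient admissions whose expected total is the configured monthly
mean. Claims never post after the death day, so conditional on being
alive at an interval start the expected cost incurred in that 30-day
interval is the monthly mean times a within-interval retention factor

    F(h) = (2 + sum_{i=1..28} exp(-h*i)) / 30

for per-day hazard h (F -> 1 as h -> 0). :func:`truth_mean_annual_cost`
uses this exact discrete form, so the generator's own expectation — not
an idealized continuous-time limit — is the recovery target.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import COST_COMPONENTS, HK, NON_HK, ClaimsDataset, from_day

#: ICD-10 code attached to every synthetic CKD diagnosis.
CKD_CODE = "N18.9"
#: ICD-10 code identifying hyperkalemia.
HK_CODE = "E87.5"

#: Comorbidity name -> representative ICD-10 code emitted on claims.
COMORBIDITY_CODES: dict[str, str] = {
    "hypertension": "I10",
    "dyslipidemia": "E78.5",
    "t2dm": "E11.9",
    "heart_failure": "I50.0",
    "arrhythmia": "I48",
    "stroke": "I63.9",
    "pvd": "I73.9",
    "peptic_ulcer": "K27.9",
    "copd": "J44.1",
    "rheumatic_disease": "M06.9",
    "malignancy": "C34.9",
}


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_comorbidities() -> dict[str, float]:
    return {
        "hypertension": 0.75,
        "dyslipidemia": 0.45,
        "t2dm": 0.40,
        "heart_failure": 0.18,
        "arrhythmia": 0.27,
        "stroke": 0.30,
        "pvd": 0.15,
        "peptic_ulcer": 0.09,
        "copd": 0.06,
        "rheumatic_disease": 0.05,
        "malignancy": 0.20,
    }


def _default_drug_classes() -> dict[str, float]:
    return {
        "ARB": 0.48,
        "MRA": 0.30,
        "ACEi": 0.23,
        "calcium_channel_blocker": 0.64,
        "loop_diuretic": 0.54,
        "NSAID": 0.53,
        "beta_blocker": 0.43,
        "anti_platelet": 0.47,
        "insulin": 0.37,
        "statin": 0.40,
    }


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters; defaults are the emulated study conditions.

    Rates are per person-month with a fixed 30-day month; dates are
    ISO-8601 strings. ``steady_monthly_cost`` is the *total* expected
    monthly post-index cost per arm, internally split between a Poisson
    admission stream (``admission_rate`` or ``hk_postindex_admission_rate``
    times the mean ``admission_cost``) and outpatient visit claims.
    """

    n_patients: int = 20_000
    index_period: tuple[str, str] = ("2012-01-01", "2016-12-31")
    study_period: tuple[str, str] = ("2011-01-01", "2017-12-31")
    age_distribution: tuple[float, float] = (67.2, 14.3)
    female_fraction: float = 0.40
    comorbidity_prevalences: dict[str, float] = dataclasses.field(
        default_factory=_default_comorbidities
    )
    drug_class_prevalences: dict[str, float] = dataclasses.field(
        default_factory=_default_drug_classes
    )
    hk_fraction: float = 0.05
    #: deaths per person-month for the control arm at zero comorbidity
    #: load; with the default comorbidity hazard effects (mean hazard
    #: multiplier ~1.4) this puts the marginal control-arm 12-month
    #: mortality near 8.3%
    baseline_hazard: float = 0.00514
    hk_log_hazard_ratio: float = math.log(5.39)
    monthly_outpatient_rate: float = 3.0
    #: admissions per person-month in the stationary (baseline/control) process
    admission_rate: float = 0.058
    #: extra post-index admission intensity for the HK arm
    hk_postindex_admission_rate: float = 0.075
    index_month_inpatient_cost: tuple[float, float] = (22204.0, 25000.0)
    steady_monthly_cost: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {HK: (3775.0, 3000.0), NON_HK: (1800.0, 1500.0)}
    )
    admission_cost: tuple[float, float] = (16637.0, 20000.0)
    admission_los: tuple[float, float] = (13.0, 9.0)
    cost_component_shares: tuple[float, ...] = (0.45, 0.15, 0.23, 0.01, 0.09, 0.07)
    enrollment_gap_prob: float = 0.05
    #: days from CKD diagnosis to the HK index event (gamma mean, sd)
    ckd_to_index_delay: tuple[float, float] = (385.0, 300.0)
    #: comorbidity -> additive log-odds of HK membership (confounding)
    comorbidity_hk_log_odds: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"heart_failure": 0.7, "t2dm": 0.4, "hypertension": 0.4}
    )
    #: comorbidity -> additive log hazard of death (confounding)
    comorbidity_log_hazard: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"heart_failure": 0.5, "t2dm": 0.25, "malignancy": 0.5}
    )
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        for name in ("hk_fraction", "female_fraction", "enrollment_gap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        for name in ("monthly_outpatient_rate", "admission_rate", "hk_postindex_admission_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        shares = np.asarray(self.cost_component_shares, dtype=float)
        if len(shares) != len(COST_COMPONENTS):
            raise ConfigError("cost_component_shares must have six entries")
        if (shares < 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigError("cost_component_shares must be non-negative and sum to 1")
        for name, prevs in (
            ("comorbidity_prevalences", self.comorbidity_prevalences),
            ("drug_class_prevalences", self.drug_class_prevalences),
        ):
            for key, p in prevs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{key!r}] must be in [0, 1], got {p}")
        for name, eff in (
            ("comorbidity_hk_log_odds", self.comorbidity_hk_log_odds),
            ("comorbidity_log_hazard", self.comorbidity_log_hazard),
        ):
            unknown = set(eff) - set(self.comorbidity_prevalences)
            if unknown:
                raise ConfigError(f"{name} refers to unknown comorbidities {sorted(unknown)}")
        for arm in (HK, NON_HK):
            if arm not in self.steady_monthly_cost:
                raise ConfigError(f"steady_monthly_cost missing arm {arm!r}")
            if self._outpatient_monthly_mean(arm) <= 0:
                raise ConfigError(
                    "steady_monthly_cost must exceed the expected admission cost "
                    f"for arm {arm!r}"
                )
        p0, p1 = (pd.Timestamp(d) for d in self.index_period)
        s0, s1 = (pd.Timestamp(d) for d in self.study_period)
        if not (s0 <= p0 < p1 <= s1):
            raise ConfigError("index_period must lie inside study_period")
        return self

    # -- derived quantities -------------------------------------------

    def _admission_rate(self, arm: str, post_index: bool) -> float:
        rate = self.admission_rate
        if arm == HK and post_index:
            rate += self.hk_postindex_admission_rate
        return rate

    def _outpatient_monthly_mean(self, arm: str) -> float:
        """Expected monthly outpatient cost left after the admission stream."""
        total = self.steady_monthly_cost[arm][0]
        adm_rate = self._admission_rate(arm, post_index=True)
        return total - adm_rate * self.admission_cost[0]

    def membership_intercept(self) -> float:
        """Logistic intercept solved so E[P(HK | z)] equals hk_fraction."""
        if not 0.0 < self.hk_fraction < 1.0:
            raise ConfigError("membership_intercept requires hk_fraction in (0, 1)")
        probs, _, gamma, _ = _enumerate_confounders(self)
        if not gamma.any():
            return float(np.log(self.hk_fraction / (1 - self.hk_fraction)))
        lin = _confounder_matrix(self) @ gamma

        def gap(alpha: float) -> float:
            return float(probs @ expit(alpha + lin)) - self.hk_fraction

        return float(brentq(gap, -40.0, 40.0, xtol=1e-12))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in (
            "index_period",
            "study_period",
            "age_distribution",
            "index_month_inpatient_cost",
            "admission_cost",
            "admission_los",
            "cost_component_shares",
            "ckd_to_index_delay",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "steady_monthly_cost" in kwargs:
            kwargs["steady_monthly_cost"] = {
                arm: tuple(v) for arm, v in kwargs["steady_monthly_cost"].items()
            }
        return cls(**kwargs).validate()


@dataclasses.dataclass
class GroundTruth:
    """The generator's known quantities, for recovery testing."""

    true_hr: float
    true_mean_annual_cost_hk: float
    true_mean_annual_cost_control: float
    #: per-patient latent state: arm, comorbidity flags, hazards, death days
    latent: pd.DataFrame


# ---------------------------------------------------------------------
# closed-form ground truth


def _confounder_names(config: SimulationConfig) -> list[str]:
    keys = set(config.comorbidity_hk_log_odds) | set(config.comorbidity_log_hazard)
    return sorted(keys)


def _confounder_matrix(config: SimulationConfig) -> np.ndarray:
    """All 2^J combinations of the effect-bearing comorbidity flags."""
    names = _confounder_names(config)
    J = len(names)
    if J == 0:
        return np.zeros((1, 0))
    combos = np.array(
        [[(i >> j) & 1 for j in range(J)] for i in range(2**J)], dtype=float
    )
    return combos


def _enumerate_confounders(config: SimulationConfig):
    """Return (P(z), flag matrix, HK log-odds vector, log-hazard vector)."""
    names = _confounder_names(config)
    combos = _confounder_matrix(config)
    prev = np.array([config.comorbidity_prevalences[n] for n in names])
    probs = np.prod(np.where(combos == 1, prev, 1 - prev), axis=1)
    gamma = np.array([config.comorbidity_hk_log_odds.get(n, 0.0) for n in names])
    beta = np.array([config.comorbidity_log_hazard.get(n, 0.0) for n in names])
    return probs, combos, gamma, beta


def _retention_factor(h_day: np.ndarray | float) -> np.ndarray | float:
    """E[fraction of a 30-day interval's claims kept | alive at its start].

    Claims land on integer days with uniform intensity and are kept up to
    and including the (ceiled) death day, hence the first two days of the
    interval are always kept.
    """
    h = np.asarray(h_day, dtype=float)
    i = np.arange(1, 29, dtype=float)
    return (2.0 + np.exp(-np.outer(h.ravel(), i)).sum(axis=1)).reshape(h.shape) / 30.0


def truth_mean_annual_cost(
    config: SimulationConfig, arm: str, horizon_months: int = 12
) -> float:
    """Analytic survival-weighted mean cost over the follow-up horizon.

    The expectation sum_k S(t_{k-1}) * E[cost in interval k | alive at its
    start] is evaluated under the generator's own discrete-day death and
    cost processes, marginalized over the comorbidity distribution of the
    HK arm (the estimand of a matched, treated-anchored design). For the
    HK arm the index-month inpatient spike enters interval 1 with weight
    S(0) = 1.
    """
    config.validate()
    if arm not in (HK, NON_HK):
        raise ConfigError(f"unknown arm {arm!r}; expected {HK!r} or {NON_HK!r}")
    probs, combos, gamma, beta = _enumerate_confounders(config)
    if gamma.any() and 0.0 < config.hk_fraction < 1.0:
        alpha = config.membership_intercept()
        weights = probs * expit(alpha + combos @ gamma)
        weights = weights / weights.sum()
    else:
        weights = probs

    h_day = (config.baseline_hazard / 30.0) * np.exp(combos @ beta)
    if arm == HK:
        h_day = h_day * math.exp(config.hk_log_hazard_ratio)

    k = np.arange(horizon_months, dtype=float)
    surv = np.exp(-np.outer(h_day, 30.0 * k))  # S at interval starts
    monthly = config.steady_monthly_cost[arm][0] * _retention_factor(h_day)
    value = float(weights @ (surv.sum(axis=1) * monthly))
    if arm == HK:
        value += config.index_month_inpatient_cost[0]
    return value


# ---------------------------------------------------------------------
# population simulation


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal draws parameterized by their arithmetic mean and SD."""
    if size == 0:
        return np.zeros(0)
    if mean <= 0:
        raise ConfigError(f"log-normal mean must be > 0, got {mean}")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _poisson_days(
    rng: np.random.Generator,
    start: np.ndarray,
    end: np.ndarray,
    rate_per_month: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson event days on [start, end] per patient.

    Returns (patient row index, event day), both int64. Empty windows
    (end < start) yield no events.
    """
    length = np.maximum(end - start + 1, 0)
    counts = rng.poisson(rate_per_month / 30.0 * length)
    idx = np.repeat(np.arange(len(start)), counts)
    u = rng.random(counts.sum())
    days = start[idx] + np.floor(u * length[idx]).astype(np.int64)
    return idx, days


def _split_costs(total: np.ndarray, shares: Sequence[float]) -> dict[str, np.ndarray]:
    return {comp: total * share for comp, share in zip(COST_COMPONENTS, shares)}


def simulate_population(config: SimulationConfig) -> tuple[ClaimsDataset, GroundTruth]:
    """Generate a claims dataset plus its ground truth.

    Deterministic given the config (including ``rng_seed``): the same
    config yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    day0 = np.datetime64(config.study_period[0], "D").astype(np.int64)
    day1 = np.datetime64(config.study_period[1], "D").astype(np.int64)
    p0 = np.datetime64(config.index_period[0], "D").astype(np.int64)
    p1 = np.datetime64(config.index_period[1], "D").astype(np.int64)

    patient_id = np.arange(1, n + 1, dtype=np.int64)
    female = rng.random(n) < config.female_fraction

    comorb_names = list(config.comorbidity_prevalences)
    comorb = {
        name: rng.random(n) < prev
        for name, prev in config.comorbidity_prevalences.items()
    }
    drugs = {
        name: rng.random(n) < prev
        for name, prev in config.drug_class_prevalences.items()
    }

    # HK membership with comorbidity confounding
    if config.hk_fraction == 0.0:
        is_hk = np.zeros(n, dtype=bool)
    elif config.hk_fraction == 1.0:
        is_hk = np.ones(n, dtype=bool)
    else:
        alpha = config.membership_intercept()
        lin = alpha + sum(
            eff * comorb[name]
            for name, eff in config.comorbidity_hk_log_odds.items()
        )
        is_hk = rng.random(n) < expit(np.asarray(lin, dtype=float) + np.zeros(n))

    # CKD diagnosis day and (for HK) the index event day
    dmean, dsd = config.ckd_to_index_delay
    shape = (dmean / dsd) ** 2 if dsd > 0 else 1e6
    scale = dmean / shape
    delay = np.clip(np.round(rng.gamma(shape, scale, n)), 30, p1 - p0).astype(np.int64)
    diag_day = np.where(
        is_hk,
        p0 + np.floor(rng.random(n) * np.maximum(p1 - p0 - delay, 1)).astype(np.int64),
        p0 + np.floor(rng.random(n) * (p1 - p0 + 1)).astype(np.int64),
    )
    index_day = np.where(is_hk, diag_day + delay, -1)

    age_mean, age_sd = config.age_distribution
    age = np.clip(rng.normal(age_mean, age_sd, n), 18.5, 99.0)
    birth_day = diag_day - np.round(age * 365.25).astype(np.int64)

    # death process: exponential clocks (controls from diagnosis, HK from index)
    log_beta = sum(
        eff * comorb[name] for name, eff in config.comorbidity_log_hazard.items()
    )
    h_ctrl_day = (config.baseline_hazard / 30.0) * np.exp(
        np.asarray(log_beta, dtype=float) + np.zeros(n)
    )
    h_day = np.where(is_hk, h_ctrl_day * math.exp(config.hk_log_hazard_ratio), h_ctrl_day)
    anchor = np.where(is_hk, index_day, diag_day)
    tau = rng.exponential(1.0, n) / h_day
    death_day = anchor + np.ceil(tau).astype(np.int64)
    death_observed = death_day <= day1

    # enrollment spans: lookback before diagnosis through study end or death
    enroll_start = np.maximum(diag_day - 400 - rng.integers(0, 200, n), day0)
    enroll_end = np.minimum(death_day, day1)
    has_gap = rng.random(n) < config.enrollment_gap_prob
    # gaps start well after the anchor so an HK index event (and its
    # claim) always falls inside covered time
    gap_start = anchor + rng.integers(150, 900, n)
    gap_len = 90
    has_gap &= gap_start + gap_len < enroll_end

    span_rows = [
        pd.DataFrame(
            {
                "patient_id": patient_id,
                "start": enroll_start,
                "end": np.where(has_gap, gap_start - 1, enroll_end),
            }
        ),
        pd.DataFrame(
            {
                "patient_id": patient_id[has_gap],
                "start": gap_start[has_gap] + gap_len,
                "end": enroll_end[has_gap],
            }
        ),
    ]
    enrollment = pd.concat(span_rows, ignore_index=True)
    enrollment = enrollment.sort_values(["patient_id", "start"], ignore_index=True)

    in_gap = lambda idx, day: has_gap[idx] & (day >= gap_start[idx]) & (
        day < gap_start[idx] + gap_len
    )

    # ---- claims -----------------------------------------------------
    comorb_flat, comorb_offset, comorb_count = _ragged_codes(comorb, comorb_names)
    pieces: list[pd.DataFrame] = []

    def visit_codes(idx: np.ndarray, days: np.ndarray) -> np.ndarray:
        """Diagnosis strings for outpatient visits: CKD code post-diagnosis
        (coin flip) plus one randomly chosen active comorbidity code."""
        m = len(idx)
        ckd = (days >= diag_day[idx]) & (rng.random(m) < 0.5)
        pick = rng.random(m) < 0.7
        k = np.floor(rng.random(m) * np.maximum(comorb_count[idx], 1)).astype(np.int64)
        has = comorb_count[idx] > 0
        code_idx = comorb_offset[idx] + np.minimum(k, np.maximum(comorb_count[idx] - 1, 0))
        code_idx = np.minimum(code_idx, len(comorb_flat) - 1)  # zero-count rows are masked out
        com = np.where(pick & has, comorb_flat[code_idx], "")
        out = np.where(ckd, CKD_CODE, "")
        both = ckd & (com != "")
        joined = np.where(both, np.char.add(np.char.add(out, ";"), com), np.where(ckd, out, com))
        return joined

    def add_outpatient(idx, days, cost_total, codes):
        keep = ~in_gap(idx, days)
        idx, days, cost_total = idx[keep], days[keep], cost_total[keep]
        codes = codes[keep] if isinstance(codes, np.ndarray) else codes
        frame = pd.DataFrame(
            {
                "patient_id": patient_id[idx],
                "setting": "outpatient",
                "service_day": days,
                "admission_day": np.int64(-1),
                "discharge_day": np.int64(-1),
                "diagnosis_codes": codes,
                **_split_costs(cost_total, config.cost_component_shares),
            }
        )
        pieces.append(frame)

    def add_inpatient(idx, days, cost_total, codes):
        keep = ~in_gap(idx, days)
        idx, days, cost_total = idx[keep], days[keep], cost_total[keep]
        codes = codes[keep] if isinstance(codes, np.ndarray) else codes
        los = np.maximum(
            np.round(_lognormal(rng, *config.admission_los, len(idx))), 1
        ).astype(np.int64)
        discharge = np.minimum(days + los - 1, np.minimum(death_day[idx], day1))
        frame = pd.DataFrame(
            {
                "patient_id": patient_id[idx],
                "setting": "inpatient",
                "service_day": days,
                "admission_day": days,
                "discharge_day": discharge,
                "diagnosis_codes": codes,
                **_split_costs(cost_total, config.cost_component_shares),
            }
        )
        pieces.append(frame)

    # the CKD diagnosis visit itself
    diag_cost = _lognormal(rng, 300.0, 300.0, n)
    add_outpatient(np.arange(n), diag_day, diag_cost, np.full(n, CKD_CODE, dtype=object))

    # stationary (control-type) outpatient stream: whole enrollment for
    # controls, pre-index only for HK patients
    ctrl_end = np.where(is_hk, index_day - 1, enroll_end)
    rate = config.monthly_outpatient_rate
    idx, days = _poisson_days(rng, enroll_start, ctrl_end, rate)
    per_visit_ctrl = config._outpatient_monthly_mean(NON_HK) / max(rate, 1e-12)
    add_outpatient(
        idx, days, _lognormal(rng, per_visit_ctrl, per_visit_ctrl, len(idx)),
        visit_codes(idx, days),
    )

    # stationary admission stream
    idx, days = _poisson_days(rng, enroll_start, ctrl_end, config.admission_rate)
    add_inpatient(
        idx, days, _lognormal(rng, *config.admission_cost, len(idx)),
        visit_codes(idx, days),
    )

    # HK post-index streams (outpatient visits + admissions + index stay)
    hk_rows = np.flatnonzero(is_hk)
    if hk_rows.size:
        start = index_day[hk_rows]
        end = enroll_end[hk_rows]
        sub, days = _poisson_days(rng, start, end, rate)
        idx = hk_rows[sub]
        per_visit_hk = config._outpatient_monthly_mean(HK) / max(rate, 1e-12)
        add_outpatient(
            idx, days, _lognormal(rng, per_visit_hk, per_visit_hk, len(idx)),
            visit_codes(idx, days),
        )
        sub, days = _poisson_days(
            rng, start, end, config.admission_rate + config.hk_postindex_admission_rate
        )
        idx = hk_rows[sub]
        add_inpatient(
            idx, days, _lognormal(rng, *config.admission_cost, len(idx)),
            visit_codes(idx, days),
        )
        # the index hospitalization: HK code, month-1 cost spike
        add_inpatient(
            hk_rows,
            index_day[hk_rows],
            _lognormal(rng, *config.index_month_inpatient_cost, hk_rows.size),
            np.full(hk_rows.size, f"{HK_CODE};{CKD_CODE}", dtype=object),
        )

    claims = pd.concat(pieces, ignore_index=True)
    claims = claims.sort_values(
        ["patient_id", "service_day", "setting"], kind="mergesort", ignore_index=True
    )
    claims.insert(0, "claim_id", np.arange(1, len(claims) + 1, dtype=np.int64))
    claims["service_date"] = from_day(claims.pop("service_day")).values
    adm = claims.pop("admission_day").to_numpy()
    dis = claims.pop("discharge_day").to_numpy()
    claims["admission_date"] = np.where(
        adm >= 0, adm.astype("datetime64[D]"), np.datetime64("NaT")
    )
    claims["discharge_date"] = np.where(
        dis >= 0, dis.astype("datetime64[D]"), np.datetime64("NaT")
    )
    claims["admission_date"] = pd.to_datetime(claims["admission_date"])
    claims["discharge_date"] = pd.to_datetime(claims["discharge_date"])

    # prescriptions: quarterly fills per active drug class
    rx_pieces = []
    for name, flag in drugs.items():
        rows = np.flatnonzero(flag)
        if not rows.size:
            continue
        n_fills = np.maximum((enroll_end[rows] - enroll_start[rows]) // 90, 1)
        idx = np.repeat(rows, n_fills)
        offsets = np.concatenate([np.arange(c) for c in n_fills]) if rows.size else []
        fill_day = enroll_start[idx] + 45 + 90 * np.asarray(offsets, dtype=np.int64)
        keep = (fill_day <= enroll_end[idx]) & ~in_gap(idx, fill_day)
        rx_pieces.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id[idx[keep]],
                    "day": fill_day[keep],
                    "drug_class": name,
                }
            )
        )
    if rx_pieces:
        prescriptions = pd.concat(rx_pieces, ignore_index=True)
        prescriptions = prescriptions.sort_values(
            ["patient_id", "day", "drug_class"], kind="mergesort", ignore_index=True
        )
        prescriptions["date"] = from_day(prescriptions.pop("day")).values
    else:
        prescriptions = pd.DataFrame(
            {"patient_id": pd.Series(dtype=np.int64), "date": pd.Series(dtype="datetime64[ns]"),
             "drug_class": pd.Series(dtype=object)}
        )
    prescriptions = prescriptions[["patient_id", "date", "drug_class"]]

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": np.where(female, "F", "M"),
            "birth_date": from_day(birth_day).values,
            "death_date": pd.to_datetime(
                np.where(
                    death_observed, death_day.astype("datetime64[D]"), np.datetime64("NaT")
                )
            ),
        }
    )
    enrollment = pd.DataFrame(
        {
            "patient_id": enrollment["patient_id"].to_numpy(),
            "start_date": from_day(enrollment["start"].to_numpy()).values,
            "end_date": from_day(enrollment["end"].to_numpy()).values,
        }
    )
    claims = claims[
        [
            "claim_id",
            "patient_id",
            "setting",
            "service_date",
            "admission_date",
            "discharge_date",
            "diagnosis_codes",
            *COST_COMPONENTS,
        ]
    ]
    dataset = ClaimsDataset(patients, enrollment, claims, prescriptions).validate()

    latent = pd.DataFrame(
        {
            "patient_id": patient_id,
            "is_hk": is_hk,
            "female": female,
            "diag_day": diag_day,
            "index_day": index_day,
            "death_day": death_day,
            "hazard_per_day": h_day,
            **{f"comorb_{name}": comorb[name] for name in comorb_names},
            **{f"drug_{name}": drugs[name] for name in drugs},
        }
    )
    if config.hk_fraction > 0.0:
        cost_hk = truth_mean_annual_cost(config, HK)
        cost_ctrl = truth_mean_annual_cost(config, NON_HK)
    else:
        cost_hk = float("nan")
        cost_ctrl = truth_mean_annual_cost(config, NON_HK)
    truth = GroundTruth(
        true_hr=math.exp(config.hk_log_hazard_ratio),
        true_mean_annual_cost_hk=cost_hk,
        true_mean_annual_cost_control=cost_ctrl,
        latent=latent,
    )
    return dataset, truth


def _ragged_codes(comorb: dict[str, np.ndarray], names: list[str]):
    """Flatten each patient's active comorbidity codes for O(1) sampling."""
    n = len(next(iter(comorb.values()))) if comorb else 0
    flags = (
        np.column_stack([comorb[name] for name in names])
        if names
        else np.zeros((n, 0), dtype=bool)
    )
    counts = flags.sum(axis=1).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]]) if n else np.zeros(0, np.int64)
    codes = np.array([COMORBIDITY_CODES.get(nm, nm) for nm in names], dtype=object)
    flat = np.concatenate(
        [codes[np.flatnonzero(row)] for row in flags]
    ) if n and counts.sum() else np.array([""], dtype=object)
    return flat, offsets, counts
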