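"""Kaplan-Meier sample average (KMSA) estimation of annual costs and HRU.

Simple annualization of observed costs is biased when mortality differs
between cohorts: patients who die early accrue less. The KMSA (Lin-type)
estimator corrects this by weighting each 30-day interval's conditional
mean outcome by the Kaplan-Meier probability of surviving to the
interval's start:

    C_hat = sum_{k=1..K} S_hat(t_{k-1}) * Cbar_k

where Cbar_k is the mean outcome in interval k over patients alive and
enrolled at the interval's start (patients dying mid-interval contribute
their observed partial-interval outcomes — no within-interval survival
adjustment; the bias of this convention is known to be small on a
monthly grid). With no deaths and full enrollment every weight is 1 and
the estimator reduces exactly to the arithmetic mean of annual totals.

HRU quantities (admissions, length of stay, outpatient visits) pass
through the identical machinery as costs.

Confidence intervals come from a paired bootstrap: the matched pair is
the resampling unit, the per-cohort KM curves and KMSA estimates are
recomputed in every iteration, and percentile intervals are reported.
By default each iteration resamples as many pairs as exist (full-n);
the m-out-of-n variant (e.g. 500 of the matched pairs per iteration) is
available through ``pairs_per_iteration``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import COST_COMPONENTS, ClaimsDataset, to_day

log = logging.getLogger(__name__)

#: Outcomes bootstrapped by default (the headline table quantities).
DEFAULT_BOOTSTRAP_OUTCOMES = (
    "cost_total",
    "cost_inpatient",
    "cost_outpatient",
    "n_admissions",
    "los_days",
    "n_outpatient",
)


class KMSAError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class IntervalGrid:
    """K consecutive half-open intervals [30(k-1), 30k) days post-index."""

    n_intervals: int = 12
    interval_days: int = 30

    @property
    def starts(self) -> np.ndarray:
        return self.interval_days * np.arange(self.n_intervals)

    @property
    def horizon(self) -> int:
        return self.n_intervals * self.interval_days


@dataclasses.dataclass
class IntervalOutcomes:
    """Per patient x interval outcome matrices for one cohort.

    ``at_risk[p, k]`` marks patients alive and enrolled at interval k's
    start; outcome rows are zero after death or disenrollment.
    ``time``/``event`` are the grid-horizon survival data used for the
    cohort's own KM weights.
    """

    members: pd.DataFrame
    grid: IntervalGrid
    at_risk: np.ndarray              # (n, K) bool
    outcomes: dict[str, np.ndarray]  # name -> (n, K) float
    time: np.ndarray                 # (n,) int days, truncated at horizon
    event: np.ndarray                # (n,) bool

    def __len__(self) -> int:
        return len(self.members)

    def annual_totals(self, name: str) -> np.ndarray:
        return self.outcomes[name].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long patient x interval table of all outcomes."""
        n, k = self.at_risk.shape
        base = pd.DataFrame(
            {
                "patient_id": np.repeat(self.members["patient_id"].to_numpy(), k),
                "interval": np.tile(np.arange(1, k + 1), n),
                "at_risk": self.at_risk.ravel(),
            }
        )
        for name, arr in self.outcomes.items():
            base[name] = arr.ravel()
        return base


def accrue_intervals(
    members: pd.DataFrame, data: ClaimsDataset, grid: IntervalGrid | None = None
) -> IntervalOutcomes:
    """Assign every follow-up claim to its 30-day post-index interval.

    Outpatient claims land in the interval containing the service date;
    an admission's full cost and length of stay (discharge - admission
    + 1 days) go to the interval containing the admission date, so the
    index hospitalization belongs to interval 1. Claims outside the
    follow-up window are ignored.
    """
    grid = grid or IntervalGrid()
    members = members.reset_index(drop=True)
    n, K = len(members), grid.n_intervals
    index_day = to_day(members["index_date"])
    death_day = to_day(members["death_date"])
    fu_day = np.minimum(to_day(members["followup_end"]), death_day)
    starts_abs = index_day[:, None] + grid.starts[None, :]
    at_risk = (death_day[:, None] > starts_abs) & (fu_day[:, None] >= starts_abs)

    time = np.minimum(fu_day - index_day, grid.horizon)
    event = (death_day - index_day) <= time

    row_of = pd.Series(np.arange(n), index=members["patient_id"].to_numpy())
    claims = data.claims[data.claims["patient_id"].isin(row_of.index)]
    rows = claims["patient_id"].map(row_of).to_numpy()
    inpat = (claims["setting"] == "inpatient").to_numpy()
    day = np.where(
        inpat, to_day(claims["admission_date"]), to_day(claims["service_date"])
    )
    rel = day - index_day[rows]
    k_all = np.clip(rel // grid.interval_days, 0, K - 1).astype(np.int64)
    # a claim counts only if its patient is alive and enrolled at the
    # start of the claim's interval (the estimator's conditioning)
    in_window = (
        (rel >= 0)
        & (rel < grid.horizon)
        & (day <= fu_day[rows])
        & at_risk[rows, k_all]
    )
    skipped = int(((rel >= 0) & (rel < grid.horizon) & ~in_window).sum())
    if skipped:
        log.debug("accrue_intervals: %d claim(s) outside follow-up ignored", skipped)

    claims = claims[in_window]
    rows = rows[in_window]
    inpat = inpat[in_window]
    k = (rel[in_window] // grid.interval_days).astype(np.int64)

    comps = {c: claims[c].to_numpy(dtype=float) for c in COST_COMPONENTS}
    total = sum(comps.values())
    los = np.where(
        inpat,
        to_day(claims["discharge_date"]) - to_day(claims["admission_date"]) + 1,
        0,
    ).astype(float)

    def matrix(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        out = np.zeros((n, K))
        if mask is None:
            np.add.at(out, (rows, k), values)
        else:
            np.add.at(out, (rows[mask], k[mask]), values[mask])
        return out

    outcomes: dict[str, np.ndarray] = {
        "cost_total": matrix(total),
        "cost_inpatient": matrix(total, inpat),
        "cost_outpatient": matrix(total, ~inpat),
        "n_admissions": matrix(np.ones_like(total), inpat),
        "los_days": matrix(los, inpat),
        "n_outpatient": matrix(np.ones_like(total), ~inpat),
    }
    for comp in COST_COMPONENTS:
        short = comp.removeprefix("cost_")
        outcomes[f"cost_total_{short}"] = matrix(comps[comp])
        outcomes[f"cost_inpatient_{short}"] = matrix(comps[comp], inpat)
        outcomes[f"cost_outpatient_{short}"] = matrix(comps[comp], ~inpat)

    return IntervalOutcomes(
        members=members, grid=grid, at_risk=at_risk, outcomes=outcomes,
        time=time.astype(np.int64), event=np.asarray(event),
    )


# ---------------------------------------------------------------------
# Kaplan-Meier weights on the interval grid


def km_grid_weights(
    times: np.ndarray, events: np.ndarray, starts: np.ndarray
) -> np.ndarray:
    """Product-limit survival evaluated at the interval starts.

    Integer-day times; censored subjects remain at risk for same-day
    deaths (deaths-first tie handling). S(0) = 1 because times are
    strictly positive.
    """
    times = np.asarray(times, dtype=np.int64)
    n = len(times)
    horizon = int(starts[-1])
    t = np.minimum(times, horizon + 1)
    deaths = np.bincount(
        t[np.asarray(events, dtype=bool) & (times <= horizon)], minlength=horizon + 2
    )
    leaves = np.bincount(t, minlength=horizon + 2)
    at_risk = n - np.concatenate([[0], np.cumsum(leaves)[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(at_risk > 0, 1.0 - deaths / np.maximum(at_risk, 1), 1.0)
    surv = np.cumprod(factors)  # surv[d] = S(d), product over days <= d
    return surv[np.asarray(starts, dtype=np.int64)]


# ---------------------------------------------------------------------
# point estimation


@dataclasses.dataclass
class KMSAEstimate:
    """Survival-weighted annual estimate for one outcome and cohort."""

    outcome: str
    survival_weights: np.ndarray
    conditional_means: np.ndarray
    point: float
    ci: tuple[float, float] | None = None


class KMSAEstimator(BaseEstimator):
    """Kaplan-Meier sample-average estimator (sklearn protocol).

    ``fit`` consumes one cohort's :class:`IntervalOutcomes`; the cohort's
    own KM curve (estimated from the same sample, truncated at the grid
    horizon) supplies the survival weights.

    Attributes
    ----------
    survival_weights_ : (K,) array, S_hat at interval starts
    conditional_means_ : dict outcome -> (K,) array
    estimates_ : dict outcome -> float, the KMSA point estimates
    n_ : number of patients
    """

    def __init__(self, outcomes: tuple[str, ...] | None = None):
        self.outcomes = outcomes

    def fit(self, interval_outcomes: IntervalOutcomes, y=None) -> "KMSAEstimator":
        io = interval_outcomes
        if len(io) == 0:
            raise KMSAError("empty cohort")
        names = list(self.outcomes) if self.outcomes is not None else list(io.outcomes)
        starts = io.grid.starts
        self.survival_weights_ = km_grid_weights(io.time, io.event, starts)
        denom = io.at_risk.sum(axis=0).astype(float)
        if (denom == 0).any():
            warnings.warn(
                "interval(s) with zero at-risk patients: conditional mean set to 0",
                RuntimeWarning, stacklevel=2,
            )
        self.conditional_means_ = {}
        self.estimates_ = {}
        for name in names:
            sums = io.outcomes[name].sum(axis=0)
            cbar = np.where(denom > 0, sums / np.maximum(denom, 1.0), 0.0)
            self.conditional_means_[name] = cbar
            self.estimates_[name] = float(self.survival_weights_ @ cbar)
        self.n_ = len(io)
        return self


def kmsa_point_estimate(
    interval_outcomes: IntervalOutcomes, outcome: str = "cost_total"
) -> KMSAEstimate:
    """Point estimate C_hat = sum_k S_hat(t_{k-1}) * Cbar_k for one outcome."""
    est = KMSAEstimator(outcomes=(outcome,)).fit(interval_outcomes)
    return KMSAEstimate(
        outcome=outcome,
        survival_weights=est.survival_weights_,
        conditional_means=est.conditional_means_[outcome],
        point=est.estimates_[outcome],
    )


# ---------------------------------------------------------------------
# paired bootstrap


@dataclasses.dataclass
class BootstrapConfig:
    n_iterations: int = 1000
    #: pairs resampled per iteration; None = as many as exist (full-n)
    pairs_per_iteration: int | None = None
    ci_level: float = 0.95
    seed: int = 0

    def validate(self, n_pairs: int) -> "BootstrapConfig":
        if self.n_iterations < 1:
            raise KMSAError("n_iterations must be >= 1")
        m = self.pairs_per_iteration
        if m is not None and not 1 <= m <= n_pairs:
            raise KMSAError(
                f"pairs_per_iteration must be in [1, {n_pairs}], got {m}"
            )
        if not 0 < self.ci_level < 1:
            raise KMSAError("ci_level must be in (0, 1)")
        if self.n_iterations < 100 and self.ci_level >= 0.95:
            warnings.warn(
                "fewer than 100 bootstrap iterations: percentile CIs unstable",
                RuntimeWarning, stacklevel=2,
            )
        return self


@dataclasses.dataclass
class BootstrapResult:
    """Percentile CIs per cohort and for the HK-minus-control difference."""

    table: pd.DataFrame      # outcome rows: point/lo/hi per cohort, diff, p
    draws_hk: pd.DataFrame   # iteration x outcome
    draws_control: pd.DataFrame
    config: BootstrapConfig


def paired_bootstrap(
    outcomes_hk: IntervalOutcomes,
    outcomes_control: IntervalOutcomes,
    config: BootstrapConfig | None = None,
    outcome_names: tuple[str, ...] = DEFAULT_BOOTSTRAP_OUTCOMES,
) -> BootstrapResult:
    """Pair-resampled percentile CIs for the KMSA estimates.

    Row i of the HK and control outcome sets must belong to the same
    matched pair; each iteration draws pairs with replacement and
    recomputes both cohorts' KM weights and KMSA estimates, preserving
    the matched structure. The two-sided bootstrap p-value for the
    difference is the proportion of resampled differences crossing zero.
    """
    n = len(outcomes_hk)
    if len(outcomes_control) != n:
        raise KMSAError("HK and control outcome sets must be pair-aligned")
    if n == 0:
        raise KMSAError("no matched pairs")
    config = (config or BootstrapConfig()).validate(n)
    m = config.pairs_per_iteration or n
    rng = np.random.default_rng(config.seed)
    names = list(outcome_names)
    starts = outcomes_hk.grid.starts

    point = {}
    for label, io in (("hk", outcomes_hk), ("control", outcomes_control)):
        est = KMSAEstimator(outcomes=tuple(names)).fit(io)
        point[label] = np.array([est.estimates_[nm] for nm in names])

    tensors = {}
    for label, io in (("hk", outcomes_hk), ("control", outcomes_control)):
        tensors[label] = (
            np.stack([io.outcomes[nm] for nm in names], axis=-1),  # (n, K, P)
            io.at_risk.astype(float),
            io.time,
            io.event,
        )

    B = config.n_iterations
    draws = {"hk": np.empty((B, len(names))), "control": np.empty((B, len(names)))}
    for b in range(B):
        idx = rng.integers(0, n, m)
        for label in ("hk", "control"):
            T, risk, time, event = tensors[label]
            w = km_grid_weights(time[idx], event[idx], starts)
            denom = risk[idx].sum(axis=0)
            sums = T[idx].sum(axis=0)  # (K, P)
            cbar = np.where(denom[:, None] > 0, sums / np.maximum(denom, 1.0)[:, None], 0.0)
            draws[label][b] = w @ cbar

    alpha = 1.0 - config.ci_level
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    diff = draws["hk"] - draws["control"]
    rows = []
    for j, nm in enumerate(names):
        d = diff[:, j]
        p_two = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
        rows.append(
            {
                "outcome": nm,
                "hk_point": point["hk"][j],
                "hk_lo": np.quantile(draws["hk"][:, j], lo_q),
                "hk_hi": np.quantile(draws["hk"][:, j], hi_q),
                "control_point": point["control"][j],
                "control_lo": np.quantile(draws["control"][:, j], lo_q),
                "control_hi": np.quantile(draws["control"][:, j], hi_q),
                "difference": point["hk"][j] - point["control"][j],
                "diff_lo": np.quantile(d, lo_q),
                "diff_hi": np.quantile(d, hi_q),
                "bootstrap_p": min(p_two, 1.0),
            }
        )
    return BootstrapResult(
        table=pd.DataFrame(rows),
        draws_hk=pd.DataFrame(draws["hk"], columns=names),
        draws_control=pd.DataFrame(draws["control"], columns=names),
        config=config,
    )


# ---------------------------------------------------------------------
# matched-subset (per admission / per visit) summaries


def summarize_subgroup(
    outcomes_hk: IntervalOutcomes,
    outcomes_control: IntervalOutcomes,
    rule: str,
) -> pd.DataFrame:
    """Raw (unweighted) per-admission / per-visit metrics among pairs in
    which *both* members used the service.

    ``rule="inpatient"``: pairs where both members have >= 1 admission;
    reports admissions per patient, LOS per admission, cost per
    admission. ``rule="outpatient"``: both members have >= 1 visit;
    reports visits per patient and cost per visit. Mean, SD and median
    over the qualifying patients; an empty subset yields an empty table.
    """
    if rule not in ("inpatient", "outpatient"):
        raise KMSAError(f"unknown subgroup rule {rule!r}")
    count_key = "n_admissions" if rule == "inpatient" else "n_outpatient"
    n_hk = outcomes_hk.annual_totals(count_key)
    n_ct = outcomes_control.annual_totals(count_key)
    both = (n_hk > 0) & (n_ct > 0)
    if not both.any():
        return pd.DataFrame(
            columns=["metric", "cohort", "n_pairs", "mean", "sd", "median"]
        )

    rows = []
    for cohort, io, counts in (
        ("HK", outcomes_hk, n_hk[both]),
        ("non-HK", outcomes_control, n_ct[both]),
    ):
        cost_key = f"cost_{rule}"
        cost = io.annual_totals(cost_key)[both]
        per_event_cost = cost / counts
        metrics = {
            f"n_{rule}_events": counts,
            f"cost_per_{'admission' if rule == 'inpatient' else 'visit'}": per_event_cost,
        }
        if rule == "inpatient":
            los = io.annual_totals("los_days")[both]
            metrics["los_per_admission"] = los / counts
        for metric, values in metrics.items():
            rows.append(
                {
                    "metric": metric,
                    "cohort": cohort,
                    "n_pairs": int(both.sum()),
                    "mean": float(np.mean(values)),
                    "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                    "median": float(np.median(values)),
                }
            )
    return pd.DataFrame(rows)
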