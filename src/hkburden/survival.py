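"""Kaplan-Meier, log-rank and Cox analyses of the HK mortality effect.

Times are integer days from the index date; the 12-month analysis
truncates follow-up at 360 days (12 x 30-day months). Tied deaths and
censorings on the same day are resolved deaths-first (the censored
remain at risk for that day's deaths), the standard product-limit
convention. Cox estimation uses a single binary HK indicator with
Breslow tie handling by default (Efron available), matching the
matched-cohort design in which no further covariate adjustment is done.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .dataset import HK, NON_HK, to_day


class SurvivalError(ValueError):
    pass


def build_survival_sample(
    members: pd.DataFrame, horizon_days: int | None = 360
) -> pd.DataFrame:
    """Per-patient (time, event, group) from cohort members.

    time = days from index to death / disenrollment / horizon, whichever
    comes first; event marks death at that time.
    """
    index_day = to_day(members["index_date"])
    death_day = to_day(members["death_date"])
    end_day = np.minimum(to_day(members["followup_end"]), death_day)
    time = end_day - index_day
    if horizon_days is not None:
        time = np.minimum(time, horizon_days)
    event = death_day - index_day <= time
    sample = pd.DataFrame(
        {
            "patient_id": members["patient_id"].to_numpy(),
            "time": time.astype(float),
            "event": event,
            "group": members["cohort"].to_numpy(),
        }
    )
    if (sample["time"] <= 0).any():
        raise SurvivalError("non-positive survival time; index/follow-up fields invalid")
    return sample


@dataclasses.dataclass
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    times: np.ndarray      # distinct event (death) times
    n_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray   # S evaluated just after each event time

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S at arbitrary times (S(0) = 1)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "deaths": self.deaths,
                "survival": self.survival,
            }
        )


def km_estimate(sample: pd.DataFrame, group: str) -> KMCurve:
    """Kaplan-Meier curve for one group of a survival sample."""
    sub = sample[sample["group"] == group]
    if sub.empty:
        raise SurvivalError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    times = ev.index.to_numpy(dtype=float)
    return KMCurve(
        times=times,
        n_risk=ev["at_risk"].to_numpy(dtype=float),
        deaths=ev["observed"].to_numpy(dtype=float),
        survival=surv.loc[ev.index].to_numpy(dtype=float),
    )


def logrank_test(sample: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = sample["group"].unique()
    if len(groups) != 2:
        raise SurvivalError("log-rank test requires exactly two non-empty groups")
    a = sample[sample["group"] == groups[0]]
    b = sample[sample["group"] == groups[1]]
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


@dataclasses.dataclass
class CoxResult:
    log_hr: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float

    @classmethod
    def from_log_hr(cls, log_hr: float, se: float) -> "CoxResult":
        z = log_hr / se if se > 0 else np.inf * np.sign(log_hr)
        return cls(
            log_hr=float(log_hr),
            se=float(se),
            hr=float(np.exp(log_hr)),
            ci95=(float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))),
            p_value=float(2 * stats.norm.sf(abs(z))),
        )


def cox_fit(sample: pd.DataFrame, ties: str = "breslow") -> CoxResult:
    """Cox proportional-hazards fit of the HK indicator.

    Partial-likelihood maximization via statsmodels ``PHReg``; Wald CI
    and p-value. A cohort with zero events yields a monotone partial
    likelihood: a warning is raised and a lightly penalized fit
    (lifelines, ridge penalizer 0.1) is reported instead.
    """
    x = (sample["group"] == HK).astype(float).to_numpy()
    if len(np.unique(x)) != 2:
        raise SurvivalError("Cox fit requires both groups present")
    events_by_group = sample.groupby("group")["event"].sum()
    if (events_by_group == 0).any():
        warnings.warn(
            "a cohort has zero events: monotone partial likelihood; "
            "reporting a penalized fit",
            RuntimeWarning, stacklevel=2,
        )
        frame = pd.DataFrame(
            {"time": sample["time"], "event": sample["event"].astype(int), "hk": x}
        )
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(frame, duration_col="time", event_col="event")
        return CoxResult.from_log_hr(
            float(cph.params_["hk"]), float(cph.standard_errors_["hk"])
        )
    model = PHReg(
        sample["time"].to_numpy(), x[:, None],
        status=sample["event"].to_numpy(dtype=int), ties=ties,
    )
    res = model.fit(tol=1e-10, disp=False)
    return CoxResult.from_log_hr(float(res.params[0]), float(res.bse[0]))


def mortality_summary(
    members: pd.DataFrame, horizons: dict[str, int | None] | None = None
) -> pd.DataFrame:
    """Table of mortality %, log-rank p and Cox HR per analysis horizon.

    Default horizons: the 12-month follow-up (360 days) and the full
    follow-up from index to the end of the study.
    """
    horizons = horizons or {"12-month": 360, "total": None}
    rows = []
    for name, horizon in horizons.items():
        sample = build_survival_sample(members, horizon_days=horizon)
        chi2, p = logrank_test(sample)
        cox = cox_fit(sample)
        by = sample.groupby("group")["event"].mean()
        rows.append(
            {
                "period": name,
                "mortality_hk": float(by.get(HK, np.nan)),
                "mortality_control": float(by.get(NON_HK, np.nan)),
                "logrank_chi2": chi2,
                "logrank_p": p,
                "hr": cox.hr,
                "hr_ci_low": cox.ci95[0],
                "hr_ci_high": cox.ci95[1],
                "cox_p": cox.p_value,
            }
        )
    return pd.DataFrame(rows)
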