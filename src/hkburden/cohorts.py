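"""Cohort construction: new-onset CKD, HK / non-HK assignment, enrollment
rules, and baseline covariates.

Conventions (fixed throughout the package): a month is 30 days; windows
are half-open ``[start, end)`` on integer day offsets from the index
date; age is ``floor(days / 365.25)`` years.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import charlson
from .codes import CodeSet, claims_matching, explode_codes
from .dataset import COST_COMPONENTS, HK, NON_HK, ClaimsDataset, to_day

log = logging.getLogger(__name__)

#: Days of enrollment required before a CKD diagnosis for it to count as
#: new-onset (the clean lookback window).
DEFAULT_WASHOUT_DAYS = 360
#: Pre/post index continuous-enrollment requirement, in days.
DEFAULT_WINDOW_DAYS = 360

#: Covariate name -> ICD-10 prefixes, mirroring the baseline comorbidity
#: list of the emulated study. Editable per analysis.
COVARIATE_CODE_MAP: dict[str, tuple[str, ...]] = {
    "hypertension": ("I10",),
    "dyslipidemia": ("E78",),
    "t2dm": ("E11",),
    "heart_failure": ("I50",),
    "arrhythmia": ("I48", "I49"),
    "stroke": ("I63",),
    "pvd": ("I73",),
    "peptic_ulcer": ("K25", "K26", "K27", "K28"),
    "copd": ("J44",),
    "rheumatic_disease": ("M05", "M06"),
}


class CohortError(ValueError):
    pass


# ---------------------------------------------------------------------
# enrollment span helpers


def merged_spans(enrollment: pd.DataFrame) -> pd.DataFrame:
    """Merge per-patient enrollment spans, treating adjacent days
    (gap of 0) as continuous. Returns patient_id / start_day / end_day."""
    spans = pd.DataFrame(
        {
            "patient_id": enrollment["patient_id"].to_numpy(),
            "start_day": to_day(enrollment["start_date"]),
            "end_day": to_day(enrollment["end_date"]),
        }
    ).sort_values(["patient_id", "start_day"], ignore_index=True)
    if spans.empty:
        return spans
    grp = spans.groupby("patient_id", sort=False)
    prev_end = grp["end_day"].cummax().groupby(spans["patient_id"]).shift(1)
    new_run = prev_end.isna() | (spans["start_day"] > prev_end + 1)
    run_id = new_run.cumsum()
    out = (
        spans.assign(run=run_id)
        .groupby("run", sort=True)
        .agg(
            patient_id=("patient_id", "first"),
            start_day=("start_day", "first"),
            end_day=("end_day", "max"),
        )
        .reset_index(drop=True)
    )
    return out


def _covering_span(
    spans: pd.DataFrame, patient_id: pd.Series, day: pd.Series
) -> pd.DataFrame:
    """For each (patient, day) return the merged span containing the day
    (start_day/end_day columns, NaN when uncovered)."""
    probe = pd.DataFrame(
        {
            "ord": np.arange(len(patient_id)),
            "patient_id": np.asarray(patient_id),
            "day": np.asarray(day),
        }
    )
    joined = probe.merge(spans, on="patient_id", how="left")
    inside = (joined["start_day"] <= joined["day"]) & (joined["day"] <= joined["end_day"])
    joined.loc[~inside, ["start_day", "end_day"]] = np.nan
    best = joined.groupby("ord")[["start_day", "end_day"]].max()
    return best.reindex(probe["ord"]).reset_index(drop=True)


# ---------------------------------------------------------------------
# operations


def find_new_onset_ckd(
    data: ClaimsDataset,
    codes: CodeSet,
    index_period: tuple[str, str],
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    min_age_years: int = 18,
) -> pd.DataFrame:
    """Identify adults whose *earliest* CKD-coded claim falls inside the
    index period, with full enrollment over the pre-diagnosis washout.

    Patients with any CKD-coded claim before the index period are
    excluded by construction (their earliest claim precedes the period).
    Returns a patient_id / ckd_diagnosis_date table.
    """
    if not codes.ckd_codes:
        raise CohortError("empty CKD code set")
    p0, p1 = (np.datetime64(d, "D").astype("int64") for d in index_period)
    claims = data.claims
    ckd_mask = claims_matching(claims, codes.ckd_codes)
    ckd_claims = claims.loc[ckd_mask, ["patient_id", "service_date"]]
    if ckd_claims.empty:
        return pd.DataFrame({"patient_id": [], "ckd_diagnosis_date": []})
    first = (
        ckd_claims.assign(day=to_day(ckd_claims["service_date"]))
        .groupby("patient_id", sort=True)["day"]
        .min()
        .reset_index()
        .rename(columns={"day": "diag_day"})
    )
    n0 = len(first)
    first = first[(first["diag_day"] >= p0) & (first["diag_day"] <= p1)]
    log.info("new-onset CKD: %d of %d CKD patients diagnosed in period", len(first), n0)

    birth = data.patients.set_index("patient_id")["birth_date"]
    birth_day = to_day(first["patient_id"].map(birth))
    age = np.floor((first["diag_day"].to_numpy() - birth_day) / 365.25)
    first = first[age >= min_age_years]
    log.info("new-onset CKD: %d adults (age >= %d)", len(first), min_age_years)

    spans = merged_spans(data.enrollment)
    cover = _covering_span(spans, first["patient_id"], first["diag_day"])
    ok = (cover["start_day"] <= first["diag_day"].to_numpy() - washout_days).fillna(False)
    first = first[ok.to_numpy()]
    log.info("new-onset CKD: %d with %d-day lookback coverage", len(first), washout_days)

    out = pd.DataFrame(
        {
            "patient_id": first["patient_id"].to_numpy(),
            "ckd_diagnosis_date": first["diag_day"].to_numpy().astype("datetime64[D]"),
        }
    )
    out["ckd_diagnosis_date"] = pd.to_datetime(out["ckd_diagnosis_date"])
    return out.reset_index(drop=True)


def assign_cohorts(
    ckd_table: pd.DataFrame, data: ClaimsDataset, codes: CodeSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split new-onset CKD patients into HK members and non-HK candidates.

    HK members have >= 1 HK-coded claim strictly after their CKD
    diagnosis; their index date is the earliest such claim. Non-HK
    candidates are free of HK-coded claims anywhere in the data window.
    Patients whose only HK claims precede the CKD diagnosis belong to
    neither set.
    """
    claims = data.claims
    hk_mask = claims_matching(claims, codes.hk_codes)
    hk_claims = claims.loc[hk_mask, ["patient_id", "service_date"]].copy()
    hk_claims["day"] = to_day(hk_claims["service_date"])

    diag = ckd_table.set_index("patient_id")["ckd_diagnosis_date"]
    diag_day = pd.Series(to_day(diag), index=diag.index)

    with_hk = set(hk_claims["patient_id"])
    after = hk_claims[
        hk_claims["patient_id"].isin(diag.index)
        & (hk_claims["day"] > hk_claims["patient_id"].map(diag_day))
    ]
    index_day = after.groupby("patient_id")["day"].min()

    hk_members = pd.DataFrame(
        {
            "patient_id": index_day.index.to_numpy(),
            "cohort": HK,
            "ckd_diagnosis_date": diag.loc[index_day.index].to_numpy(),
            "index_date": pd.to_datetime(index_day.to_numpy().astype("datetime64[D]")),
        }
    ).reset_index(drop=True)

    non_hk = ckd_table[~ckd_table["patient_id"].isin(with_hk)].copy()
    non_hk["cohort"] = NON_HK
    log.info(
        "cohort assignment: %d HK members, %d non-HK candidates, %d in neither",
        len(hk_members), len(non_hk), len(ckd_table) - len(hk_members) - len(non_hk),
    )
    return hk_members, non_hk.reset_index(drop=True)


def apply_enrollment_filter(
    members: pd.DataFrame,
    data: ClaimsDataset,
    pre_days: int = DEFAULT_WINDOW_DAYS,
    post_days: int = DEFAULT_WINDOW_DAYS,
    study_end: str | None = None,
) -> pd.DataFrame:
    """Keep members continuously enrolled over the baseline and follow-up
    windows; discontinuation due to death is allowed.

    A member passes when one merged enrollment span covers
    ``[index - pre_days, index + post_days]``, or covers
    ``[index - pre_days, death]`` when death comes first. Members dead on
    or before the index date are dropped. Adds ``death_date``,
    ``followup_end``, ``died_within_12m`` and ``ckd_duration_months``.
    """
    if members.empty:
        return members.assign(
            death_date=pd.NaT, followup_end=pd.NaT, died_within_12m=False,
            ckd_duration_months=0,
        )
    members = members.copy().reset_index(drop=True)
    death = data.patients.set_index("patient_id")["death_date"]
    members["death_date"] = members["patient_id"].map(death)
    index_day = to_day(members["index_date"])
    death_day = to_day(members["death_date"])  # sentinel max when alive

    alive_at_index = death_day > index_day
    if (~alive_at_index).any():
        log.info("enrollment filter: %d member(s) dead on/before index dropped",
                 int((~alive_at_index).sum()))

    spans = merged_spans(data.enrollment)
    cover = _covering_span(spans, members["patient_id"], pd.Series(index_day))
    span_start = cover["start_day"].to_numpy()
    span_end = cover["end_day"].to_numpy()
    has_span = ~np.isnan(span_start)

    end_required = np.minimum(index_day + post_days, death_day)
    ok = (
        alive_at_index
        & has_span
        & (np.nan_to_num(span_start, nan=np.inf) <= index_day - pre_days)
        & (np.nan_to_num(span_end, nan=-np.inf) >= end_required)
    )
    if study_end is not None:
        end_cap = np.datetime64(study_end, "D").astype("int64")
    else:
        end_cap = int(to_day(data.enrollment["end_date"]).max())
    followup_end = np.minimum(
        np.minimum(np.nan_to_num(span_end, nan=-1).astype("int64"), death_day), end_cap
    )
    members["followup_end"] = pd.to_datetime(followup_end.astype("datetime64[D]"))
    members["died_within_12m"] = (death_day - index_day) < 360
    diag_day = to_day(members["ckd_diagnosis_date"])
    members["ckd_duration_months"] = (index_day - diag_day) // 30
    kept = members.loc[ok].reset_index(drop=True)
    log.info("enrollment filter: kept %d of %d members", len(kept), len(members))
    return kept


def build_covariates(
    members: pd.DataFrame,
    data: ClaimsDataset,
    code_map: dict[str, tuple[str, ...]] | None = None,
    pre_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Baseline covariate vectors from the 360-day pre-index window.

    All quantities come strictly from claims and prescriptions dated in
    ``[index - pre_days, index)``. Returns a frame indexed by patient_id:
    demographics, CCI, CKD duration, comorbidity flags (``com_*``), drug
    class flags (``rx_*``), and baseline HRU / cost.
    """
    code_map = COVARIATE_CODE_MAP if code_map is None else code_map
    members = members.reset_index(drop=True)
    pid = members["patient_id"].to_numpy()
    index_day = to_day(members["index_date"])
    idx_of = pd.Series(np.arange(len(members)), index=pid)

    patients = data.patients.set_index("patient_id")
    birth_day = to_day(members["patient_id"].map(patients["birth_date"]))
    out = pd.DataFrame(index=pd.Index(pid, name="patient_id"))
    out["age"] = np.floor((index_day - birth_day) / 365.25)
    out["female"] = (
        members["patient_id"].map(patients["sex"]).to_numpy() == "F"
    ).astype(float)
    out["ckd_duration_months"] = (
        (index_day - to_day(members["ckd_diagnosis_date"])) // 30
    ).astype(float)

    claims = data.claims[data.claims["patient_id"].isin(set(pid))]
    day = to_day(claims["service_date"])
    start = claims["patient_id"].map(pd.Series(index_day - pre_days, index=pid)).to_numpy()
    end = claims["patient_id"].map(pd.Series(index_day, index=pid)).to_numpy()
    base = claims[(day >= start) & (day < end)]

    inpat = base[base["setting"] == "inpatient"]
    los = (to_day(inpat["discharge_date"]) - to_day(inpat["admission_date"]) + 1)
    agg = pd.DataFrame(
        {
            "baseline_n_hospitalizations": inpat.groupby("patient_id").size(),
            "baseline_los": pd.Series(los, index=inpat["patient_id"].to_numpy()).groupby(level=0).sum(),
            "baseline_n_outpatient": base[base["setting"] == "outpatient"].groupby("patient_id").size(),
            "baseline_total_cost": base.groupby("patient_id")[list(COST_COMPONENTS)].sum().sum(axis=1),
        }
    )
    out = out.join(agg)
    for col in agg.columns:
        out[col] = out[col].fillna(0.0).astype(float)

    exploded = explode_codes(base)
    exploded["patient_id"] = base.loc[exploded["row"], "patient_id"].to_numpy()
    for name, prefixes in code_map.items():
        hit = exploded.loc[
            exploded["code"].str.startswith(tuple(prefixes)), "patient_id"
        ].unique()
        out[f"com_{name}"] = out.index.isin(hit).astype(float)

    cci = charlson.cci_by_patient(
        exploded["patient_id"].to_numpy(), exploded["code"].to_numpy()
    )
    out["cci"] = out.index.map(cci).fillna(0).astype(float)

    rx = data.prescriptions[data.prescriptions["patient_id"].isin(set(pid))]
    rx_day = to_day(rx["date"])
    rx_start = rx["patient_id"].map(pd.Series(index_day - pre_days, index=pid)).to_numpy()
    rx_end = rx["patient_id"].map(pd.Series(index_day, index=pid)).to_numpy()
    rx_base = rx[(rx_day >= rx_start) & (rx_day < rx_end)]
    for drug in sorted(data.prescriptions["drug_class"].unique()):
        users = rx_base.loc[rx_base["drug_class"] == drug, "patient_id"].unique()
        out[f"rx_{drug}"] = out.index.isin(users).astype(float)

    # column order: demographics, score, flags, utilization
    front = ["age", "female", "cci", "ckd_duration_months"]
    tail = [
        "baseline_n_hospitalizations", "baseline_los",
        "baseline_n_outpatient", "baseline_total_cost",
    ]
    middle = [c for c in out.columns if c not in front + tail]
    return out[front + sorted(middle) + tail]
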