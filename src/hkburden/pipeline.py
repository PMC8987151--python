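"""End-to-end pipeline: cohorts -> matching -> survival -> KMSA -> report.

The report mirrors the standard burden-of-illness layout: an attrition
table, pre/post-match balance tables, a mortality table (12-month and
total follow-up), a survival-weighted HRU/cost table with paired-
bootstrap CIs, a monthly cost series, matched-subset (per-admission /
per-visit) summaries, and two sensitivity analyses:

1. malignancy exclusion — drop every matched pair in which either
   member carries a malignancy-coded claim anywhere in the data window
   (no re-matching), then re-run survival and KMSA;
2. survivors only — restrict to pairs in which both members are alive
   and enrolled through day 360; the KMSA weights degenerate to 1 and
   the estimates equal plain annual means.

Exclusions are pair-level in both, preserving the matched design.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CodeSet, claims_matching
from .cohorts import (
    COVARIATE_CODE_MAP,
    apply_enrollment_filter,
    assign_cohorts,
    build_covariates,
    find_new_onset_ckd,
)
from .dataset import HK, NON_HK, ClaimsDataset, to_day
from .kmsa import (
    BootstrapConfig,
    IntervalGrid,
    KMSAEstimator,
    accrue_intervals,
    paired_bootstrap,
    summarize_subgroup,
)
from .matching import PropensityMatcher, balance_report, coarse_match
from .survival import mortality_summary

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run (stored in the manifest)."""

    input_dir: str | None = None
    index_period: tuple[str, str] = ("2012-01-01", "2016-12-31")
    study_end: str | None = None
    code_set: CodeSet = dataclasses.field(default_factory=CodeSet)
    covariate_code_map: dict | None = None
    washout_days: int = 360
    coarse_ratio: int = 30
    caliper_sd: float | None = 0.2
    grid: IntervalGrid = dataclasses.field(default_factory=IntervalGrid)
    n_bootstrap: int = 1000
    pairs_per_iteration: int | None = None
    exclude_malignancy: bool = True
    survivors_only: bool = True
    currency_symbol: str = "¥"
    seed: int = 0

    def bootstrap_config(self, seed_offset: int = 0) -> BootstrapConfig:
        return BootstrapConfig(
            n_iterations=self.n_bootstrap,
            pairs_per_iteration=self.pairs_per_iteration,
            seed=self.seed + seed_offset,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["code_set"] = {
            "ckd_codes": list(self.code_set.ckd_codes),
            "hk_codes": list(self.code_set.hk_codes),
            "malignancy_codes": list(self.code_set.malignancy_codes),
        }
        out["grid"] = dataclasses.asdict(self.grid)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs = dict(raw)
        if "code_set" in kwargs and isinstance(kwargs["code_set"], dict):
            kwargs["code_set"] = CodeSet(
                **{k: tuple(v) for k, v in kwargs["code_set"].items()}
            )
        if "grid" in kwargs and isinstance(kwargs["grid"], dict):
            kwargs["grid"] = IntervalGrid(**kwargs["grid"])
        if "index_period" in kwargs:
            kwargs["index_period"] = tuple(kwargs["index_period"])
        if "covariate_code_map" in kwargs and kwargs["covariate_code_map"]:
            kwargs["covariate_code_map"] = {
                k: tuple(v) for k, v in kwargs["covariate_code_map"].items()
            }
        return cls(**kwargs)


@dataclasses.dataclass
class StudyReport:
    attrition: pd.DataFrame
    balance_pre: pd.DataFrame
    balance_post: pd.DataFrame
    mortality: pd.DataFrame
    hru_cost: pd.DataFrame
    monthly: pd.DataFrame
    subgroup_inpatient: pd.DataFrame
    subgroup_outpatient: pd.DataFrame
    pairs: pd.DataFrame
    sensitivity: dict[str, dict[str, pd.DataFrame]]
    manifest: dict
    #: (HK, control) IntervalOutcomes of the main analysis, pair-aligned;
    #: in-memory only (not serialized by write())
    interval_outcomes: tuple | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "attrition": self.attrition,
            "balance_pre": self.balance_pre,
            "balance_post": self.balance_post,
            "mortality": self.mortality,
            "hru_cost": self.hru_cost,
            "monthly_costs": self.monthly,
            "subgroup_inpatient": self.subgroup_inpatient,
            "subgroup_outpatient": self.subgroup_outpatient,
            "matched_pairs": self.pairs,
        }
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        for sens_name, sub in self.sensitivity.items():
            for table_name, frame in sub.items():
                frame.to_csv(out / f"sensitivity_{sens_name}_{table_name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _members_for(pairs: pd.DataFrame, hk_members: pd.DataFrame,
                 ctrl_members: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Member rows aligned with the pair order (row i = pair i)."""
    m_hk = hk_members.set_index("patient_id").loc[pairs["hk_id"]].reset_index()
    m_ct = ctrl_members.set_index("patient_id").loc[pairs["control_id"]].reset_index()
    return m_hk, m_ct


def _analyze_pairs(
    m_hk: pd.DataFrame,
    m_ct: pd.DataFrame,
    data: ClaimsDataset,
    grid: IntervalGrid,
    bconfig: BootstrapConfig,
    include_mortality: bool = True,
) -> dict:
    members = pd.concat([m_hk, m_ct], ignore_index=True)
    mortality = mortality_summary(members) if include_mortality else pd.DataFrame()
    io_hk = accrue_intervals(m_hk, data, grid)
    io_ct = accrue_intervals(m_ct, data, grid)
    boot = paired_bootstrap(io_hk, io_ct, bconfig)

    full_hk = KMSAEstimator().fit(io_hk)
    full_ct = KMSAEstimator().fit(io_ct)
    comp_rows = [
        {
            "outcome": nm,
            "hk_point": full_hk.estimates_[nm],
            "control_point": full_ct.estimates_[nm],
            "difference": full_hk.estimates_[nm] - full_ct.estimates_[nm],
        }
        for nm in full_hk.estimates_
        if nm not in set(boot.table["outcome"])
    ]
    hru_cost = pd.concat(
        [boot.table, pd.DataFrame(comp_rows)], ignore_index=True
    )

    monthly_rows = []
    for cohort, est in ((HK, full_hk), (NON_HK, full_ct)):
        for k in range(grid.n_intervals):
            monthly_rows.append(
                {
                    "cohort": cohort,
                    "month": k + 1,
                    "survival_weight": est.survival_weights_[k],
                    "mean_cost_total": est.conditional_means_["cost_total"][k],
                    "mean_cost_inpatient": est.conditional_means_["cost_inpatient"][k],
                    "mean_cost_outpatient": est.conditional_means_["cost_outpatient"][k],
                }
            )
    return {
        "mortality": mortality,
        "hru_cost": hru_cost,
        "monthly": pd.DataFrame(monthly_rows),
        "subgroup_inpatient": summarize_subgroup(io_hk, io_ct, "inpatient"),
        "subgroup_outpatient": summarize_subgroup(io_hk, io_ct, "outpatient"),
        "interval_outcomes": (io_hk, io_ct),
    }


def run_pipeline(
    config: AnalysisConfig, data: ClaimsDataset | None = None
) -> StudyReport:
    """Execute the full matched-cohort analysis; deterministic per seed."""
    if data is None:
        if config.input_dir is None:
            raise PipelineError("stage 'load' failed: no input_dir and no dataset")
        data = _stage("load")(ClaimsDataset.read)(config.input_dir)

    attrition: list[dict] = []

    def note(step: str, count: int) -> None:
        attrition.append({"step": step, "n": int(count)})
        log.info("pipeline: %s -> %d", step, count)

    ckd = _stage("new_onset_ckd")(find_new_onset_ckd)(
        data, config.code_set, config.index_period, config.washout_days
    )
    note("new-onset CKD adults with lookback", len(ckd))

    hk_raw, candidates = _stage("assign_cohorts")(assign_cohorts)(
        ckd, data, config.code_set
    )
    note("HK cohort (post-CKD HK claim)", len(hk_raw))
    note("non-HK candidates", len(candidates))
    if hk_raw.empty:
        raise PipelineError("stage 'assign_cohorts' failed: empty HK cohort")

    hk = _stage("enrollment_filter")(apply_enrollment_filter)(
        hk_raw, data, study_end=config.study_end
    )
    note("HK after enrollment filter", len(hk))
    if hk.empty:
        raise PipelineError("stage 'enrollment_filter' failed: empty HK cohort")

    pool, unmatched_coarse = _stage("coarse_match")(coarse_match)(
        hk, candidates, data, ratio=config.coarse_ratio, study_end=config.study_end
    )
    note("control pool after 1:30 coarse match + filter", len(pool))
    hk = hk[~hk["patient_id"].isin(unmatched_coarse)].reset_index(drop=True)
    note("HK with >= 1 coarse-matched control", len(hk))
    if pool.empty:
        raise PipelineError("stage 'coarse_match' failed: empty control pool")

    cov_hk = _stage("covariates")(build_covariates)(
        hk, data, config.covariate_code_map
    )
    cov_ct = _stage("covariates")(build_covariates)(
        pool, data, config.covariate_code_map
    )
    X = pd.concat([cov_hk, cov_ct])
    y = np.concatenate([np.ones(len(cov_hk)), np.zeros(len(cov_ct))])

    matcher = _stage("propensity_match")(PropensityMatcher(
        caliper_sd=config.caliper_sd
    ).fit)(X, y)
    pairs = matcher.pairs_.pairs
    note("matched pairs (1:1)", len(pairs))
    if pairs.empty:
        raise PipelineError("stage 'propensity_match' failed: no pairs matched")

    balance_pre = balance_report(cov_hk, cov_ct)
    balance_post = balance_report(
        cov_hk.loc[pairs["hk_id"]], cov_ct.loc[pairs["control_id"]]
    )

    m_hk, m_ct = _members_for(pairs, hk, pool)
    main = _stage("analysis")(_analyze_pairs)(
        m_hk, m_ct, data, config.grid, config.bootstrap_config()
    )

    sensitivity: dict[str, dict[str, pd.DataFrame]] = {}
    if config.exclude_malignancy:
        keep = _pairs_without_malignancy(pairs, m_hk, m_ct, data, config.code_set)
        note("pairs without malignancy (sensitivity 1)", int(keep.sum()))
        sensitivity["no_malignancy"] = _sensitivity_tables(
            m_hk[keep.to_numpy()], m_ct[keep.to_numpy()], data, config, seed_offset=1
        )
    if config.survivors_only:
        keep = _pairs_surviving(m_hk, m_ct, config.grid)
        note("pairs with both members surviving 12 months (sensitivity 2)", int(keep.sum()))
        sensitivity["survivors"] = _sensitivity_tables(
            m_hk[keep], m_ct[keep], data, config, seed_offset=2,
            include_mortality=False,  # no 12-month deaths by construction
        )

    manifest = {
        "config": config.to_dict(),
        "n_pairs": len(pairs),
        "unmatched_hk_coarse": [int(x) for x in unmatched_coarse],
        "unmatched_hk_ps": [int(x) for x in matcher.pairs_.unmatched_hk],
        "caliper_logit": matcher.caliper_,
        "attrition": attrition,
    }
    return StudyReport(
        attrition=pd.DataFrame(attrition),
        balance_pre=balance_pre,
        balance_post=balance_post,
        mortality=main["mortality"],
        hru_cost=main["hru_cost"],
        monthly=main["monthly"],
        subgroup_inpatient=main["subgroup_inpatient"],
        subgroup_outpatient=main["subgroup_outpatient"],
        pairs=pairs,
        sensitivity=sensitivity,
        manifest=manifest,
        interval_outcomes=main["interval_outcomes"],
    )


def _pairs_without_malignancy(
    pairs: pd.DataFrame, m_hk: pd.DataFrame, m_ct: pd.DataFrame,
    data: ClaimsDataset, codes: CodeSet,
) -> pd.Series:
    mask = claims_matching(data.claims, codes.malignancy_codes)
    malignant = set(data.claims.loc[mask, "patient_id"])
    bad = m_hk["patient_id"].isin(malignant).to_numpy() | m_ct["patient_id"].isin(
        malignant
    ).to_numpy()
    return pd.Series(~bad)


def _pairs_surviving(m_hk: pd.DataFrame, m_ct: pd.DataFrame, grid: IntervalGrid) -> np.ndarray:
    def ok(members: pd.DataFrame) -> np.ndarray:
        index_day = to_day(members["index_date"])
        death_day = to_day(members["death_date"])
        fu_day = to_day(members["followup_end"])
        return (death_day - index_day >= grid.horizon) & (
            fu_day - index_day >= grid.horizon
        )

    return ok(m_hk) & ok(m_ct)


def _sensitivity_tables(
    m_hk: pd.DataFrame, m_ct: pd.DataFrame, data: ClaimsDataset,
    config: AnalysisConfig, seed_offset: int, include_mortality: bool = True,
) -> dict[str, pd.DataFrame]:
    if m_hk.empty:
        return {"mortality": pd.DataFrame(), "hru_cost": pd.DataFrame()}
    res = _analyze_pairs(
        m_hk.reset_index(drop=True), m_ct.reset_index(drop=True), data,
        config.grid, config.bootstrap_config(seed_offset),
        include_mortality=include_mortality,
    )
    return {"mortality": res["mortality"], "hru_cost": res["hru_cost"]}
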