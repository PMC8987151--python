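import numpy as np
import pandas as pd
import pytest

from hkburden import ClaimsDataset, CodeSet
from hkburden.charlson import cci_score
from hkburden.cohorts import (
    CohortError,
    apply_enrollment_filter,
    assign_cohorts,
    build_covariates,
    find_new_onset_ckd,
    merged_spans,
)
from hkburden.codes import CodeSetError
from hkburden.dataset import HK, NON_HK, to_day

from .conftest import d, make_dataset, rel_day

CODES = CodeSet()
# index period days 1000..2000 relative to 2010-01-01
PERIOD = (str(d(1000).date()), str(d(2000).date()))


class TestFindNewOnsetCkd:
    def make_fixture(self):
        # 6 hand-written patients: 2 with prior CKD, 1 minor, 3 qualifying
        patients = [
            (1, "F", -20_000, None),   # ~57y: CKD claim before period -> out
            (2, "M", -20_000, None),   # CKD claim pre-period AND in period -> out
            (3, "F", 900, None),       # age ~1y at diagnosis -> out
            (4, "M", -20_000, None),   # qualifies, day 1100
            (5, "F", -25_000, None),   # qualifies, day 1500 (earliest of two)
            (6, "M", -30_000, None),   # qualifies via I12 prefix code, day 1999
        ]
        enrollment = [(i, 0, 3000) for i in range(1, 7)]
        claims = [
            (1, "outpatient", 500, "N18.5", 10.0),
            (2, "outpatient", 800, "N18", 10.0),
            (2, "outpatient", 1200, "N18", 10.0),
            (3, "outpatient", 1300, "N18.9", 10.0),
            (4, "outpatient", 1100, "N18.9;I10", 10.0),
            (5, "outpatient", 1500, "Z49.1", 10.0),
            (5, "outpatient", 1600, "N18.9", 10.0),
            (6, "inpatient", 1999, "I12.0", 10.0, 2005),
        ]
        return make_dataset(patients, enrollment, claims)

    def test_hand_fixture_selects_expected_rows(self):
        table = find_new_onset_ckd(self.make_fixture(), CODES, PERIOD)
        got = dict(zip(table["patient_id"], rel_day(table["ckd_diagnosis_date"])))
        assert got == {4: 1100, 5: 1500, 6: 1999}

    def test_washout_requires_lookback_coverage(self):
        ds = make_dataset(
            patients=[(1, "F", -20_000, None)],
            enrollment=[(1, 1050, 3000)],  # only ~50 days before diagnosis
            claims=[(1, "outpatient", 1100, "N18.9", 10.0)],
        )
        assert find_new_onset_ckd(ds, CODES, PERIOD).empty
        # shorter washout accepts the same patient
        assert len(find_new_onset_ckd(ds, CODES, PERIOD, washout_days=30)) == 1

    def test_empty_code_set_rejected(self):
        with pytest.raises(CodeSetError):
            CodeSet(ckd_codes=())


class TestAssignCohorts:
    def make_fixture(self):
        # 5 patients: HK-after (x2 claims), HK-before-only, clean non-HK,
        # HK-exactly-at-diagnosis-day (not "after")
        patients = [(i, "F", -20_000, None) for i in range(1, 6)]
        enrollment = [(i, 0, 3000) for i in range(1, 6)]
        claims = [
            (1, "outpatient", 1100, "N18.9", 1.0),
            (1, "outpatient", 1400, "E87.5", 1.0),
            (1, "outpatient", 1300, "E87.5", 1.0),   # earlier HK claim
            (2, "outpatient", 1100, "N18.9", 1.0),
            (2, "outpatient", 900, "E87.5", 1.0),    # HK before CKD only
            (3, "outpatient", 1100, "N18.9", 1.0),
            (4, "outpatient", 1100, "N18.9;E87.5", 1.0),  # same-day HK
            (5, "outpatient", 1100, "N18.9", 1.0),
            (5, "outpatient", 2500, "E87.5", 1.0),   # HK after, later
        ]
        return make_dataset(patients, enrollment, claims)

    def test_partition_and_index_dates(self):
        ds = self.make_fixture()
        ckd = find_new_onset_ckd(ds, CODES, PERIOD)
        hk, non_hk = assign_cohorts(ckd, ds, CODES)
        assert set(hk["patient_id"]) == {1, 5}
        assert set(non_hk["patient_id"]) == {3}
        # patient 2 (HK before CKD only) and 4 (same-day) are in neither
        assert dict(zip(hk["patient_id"], rel_day(hk["index_date"]))) == {
            1: 1300,  # the earlier of the two post-CKD HK claims
            5: 2500,
        }

    def test_sets_disjoint(self):
        ds = self.make_fixture()
        ckd = find_new_onset_ckd(ds, CODES, PERIOD)
        hk, non_hk = assign_cohorts(ckd, ds, CODES)
        assert not set(hk["patient_id"]) & set(non_hk["patient_id"])


class TestEnrollmentFilter:
    def make_members_and_data(self):
        # index day 1500 for everyone; baseline window [1140, 1500]
        patients = [
            (1, "F", -20_000, None),   # gap pre-index -> out
            (2, "M", -20_000, None),   # enrollment ends 90d post-index, alive -> out
            (3, "F", -20_000, 1590),   # dies 90d post-index, enrolled to death -> in
            (4, "M", -20_000, None),   # full coverage -> in
        ]
        enrollment = [
            (1, 1300, 3000),           # starts too late (gap pre-index)
            (2, 0, 1590),
            (3, 0, 1590),
            (4, 0, 3000),
        ]
        ds = make_dataset(patients, enrollment,
                          claims=[(i, "outpatient", 1200, "N18.9", 1.0) for i in (1, 2, 3, 4)])
        members = pd.DataFrame(
            {
                "patient_id": [1, 2, 3, 4],
                "cohort": [HK] * 4,
                "ckd_diagnosis_date": [d(1100)] * 4,
                "index_date": [d(1500)] * 4,
            }
        )
        return members, ds

    def test_edge_cases_two_retained(self):
        members, ds = self.make_members_and_data()
        kept = apply_enrollment_filter(members, ds, study_end=str(d(3000).date()))
        assert set(kept["patient_id"]) == {3, 4}

    def test_death_discontinuation_allowed(self):
        # death 3 months post-index with enrollment until death: retained
        members, ds = self.make_members_and_data()
        kept = apply_enrollment_filter(members, ds, study_end=str(d(3000).date()))
        row = kept[kept["patient_id"] == 3].iloc[0]
        assert bool(row["died_within_12m"])
        assert rel_day(pd.Series([row["followup_end"]]))[0] == 1590

    def test_followup_end_and_duration_fields(self):
        members, ds = self.make_members_and_data()
        kept = apply_enrollment_filter(members, ds, study_end=str(d(2100).date()))
        row = kept[kept["patient_id"] == 4].iloc[0]
        assert rel_day(pd.Series([row["followup_end"]]))[0] == 2100  # study end cap
        assert row["ckd_duration_months"] == (1500 - 1100) // 30

    def test_dead_before_index_dropped(self):
        ds = make_dataset(
            patients=[(1, "F", -20_000, 1400)],
            enrollment=[(1, 0, 1400)],
            claims=[(1, "outpatient", 1200, "N18.9", 1.0)],
        )
        members = pd.DataFrame(
            {
                "patient_id": [1],
                "cohort": [NON_HK],
                "ckd_diagnosis_date": [d(1100)],
                "index_date": [d(1500)],  # inherited index after death
            }
        )
        assert apply_enrollment_filter(members, ds).empty


class TestMergedSpans:
    def test_adjacent_spans_merge_gap_spans_do_not(self):
        ds = make_dataset(
            patients=[(1, "F", 0, None), (2, "M", 0, None)],
            enrollment=[(1, 0, 100), (1, 101, 200), (2, 0, 100), (2, 150, 200)],
            claims=[(1, "outpatient", 50, "N18.9", 1.0)],
        )
        spans = merged_spans(ds.enrollment)
        assert len(spans[spans["patient_id"] == 1]) == 1
        assert len(spans[spans["patient_id"] == 2]) == 2


class TestBuildCovariates:
    def members(self, *pids):
        return pd.DataFrame(
            {
                "patient_id": list(pids),
                "cohort": [HK] * len(pids),
                "ckd_diagnosis_date": [d(1100)] * len(pids),
                "index_date": [d(1500)] * len(pids),
            }
        )

    def test_no_baseline_claims_all_zero(self):
        ds = make_dataset(
            patients=[(1, "F", -20_000, None)],
            enrollment=[(1, 0, 3000)],
            claims=[(1, "outpatient", 2000, "N18.9", 50.0)],  # post-index only
        )
        cov = build_covariates(self.members(1), ds)
        assert cov.loc[1, "baseline_n_hospitalizations"] == 0
        assert cov.loc[1, "baseline_total_cost"] == 0
        assert cov.loc[1, "cci"] == 0
        assert cov.loc[1, "female"] == 1.0

    def test_single_admission_counts_and_los(self):
        ds = make_dataset(
            patients=[(1, "M", -20_000, None)],
            enrollment=[(1, 0, 3000)],
            claims=[(1, "inpatient", 1200, "I10", 500.0, 1209)],  # 10-day stay
        )
        cov = build_covariates(self.members(1), ds)
        assert cov.loc[1, "baseline_n_hospitalizations"] == 1
        assert cov.loc[1, "baseline_los"] == 10
        assert cov.loc[1, "baseline_total_cost"] == 500.0
        assert cov.loc[1, "com_hypertension"] == 1.0

    def test_cci_hand_summed(self):
        # diabetes with complication (2) + mild liver disease (1) = 3
        ds = make_dataset(
            patients=[(1, "M", -20_000, None)],
            enrollment=[(1, 0, 3000)],
            claims=[
                (1, "outpatient", 1200, "E11.2", 10.0),
                (1, "outpatient", 1300, "K70.3", 10.0),
            ],
        )
        cov = build_covariates(self.members(1), ds)
        assert cov.loc[1, "cci"] == 3

    def test_window_strictly_pre_index(self):
        # claims on the index day itself are follow-up, not baseline
        ds = make_dataset(
            patients=[(1, "M", -20_000, None)],
            enrollment=[(1, 0, 3000)],
            claims=[
                (1, "outpatient", 1500, "I10", 100.0),
                (1, "outpatient", 1139, "I10", 100.0),  # before window start
                (1, "outpatient", 1140, "I10", 100.0),  # first day inside
            ],
        )
        cov = build_covariates(self.members(1), ds)
        assert cov.loc[1, "baseline_n_outpatient"] == 1
        assert cov.loc[1, "baseline_total_cost"] == 100.0

    def test_drug_flags_from_prescriptions(self):
        ds = make_dataset(
            patients=[(1, "M", -20_000, None), (2, "F", -20_000, None)],
            enrollment=[(1, 0, 3000), (2, 0, 3000)],
            claims=[(1, "outpatient", 1200, "N18.9", 1.0)],
            prescriptions=[(1, 1200, "ARB"), (2, 2000, "ARB")],  # 2: post-index
        )
        cov = build_covariates(self.members(1, 2), ds)
        assert cov.loc[1, "rx_ARB"] == 1.0
        assert cov.loc[2, "rx_ARB"] == 0.0


class TestCharlsonScore:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (["E11.9"], 1),                  # uncomplicated diabetes
            (["E11.2", "E11.9"], 2),         # complication supersedes
            (["C34.9"], 2),
            (["C34.9", "C78.0"], 6),         # metastatic supersedes
            (["K70.3", "K72.9"], 3),         # severe liver supersedes mild
            (["N18.5", "I50.0", "J44.1"], 4),  # renal 2 + CHF 1 + COPD 1
            (["I10"], 0),                    # hypertension scores nothing
            ([], 0),
        ],
    )
    def test_weights_and_hierarchy(self, codes, expected):
        assert cci_score(codes) == expected


class TestSimulatedCohortProperties:
    def test_hk_index_date_carries_hk_claim(self, sim_small):
        _, ds, _ = sim_small
        ckd = find_new_onset_ckd(ds, CODES, ("2012-01-01", "2016-12-31"))
        hk, non_hk = assign_cohorts(ckd, ds, CODES)
        assert not set(hk["patient_id"]) & set(non_hk["patient_id"])
        hk_claims = ds.claims[ds.claims["diagnosis_codes"].str.contains("E87.5")]
        key = set(zip(hk_claims["patient_id"], to_day(hk_claims["service_date"])))
        assert all(
            (pid, day) in key
            for pid, day in zip(hk["patient_id"], to_day(hk["index_date"]))
        )

    def test_enrollment_filter_predicate_recheck(self, sim_small):
        _, ds, _ = sim_small
        ckd = find_new_onset_ckd(ds, CODES, ("2012-01-01", "2016-12-31"))
        hk, _ = assign_cohorts(ckd, ds, CODES)
        kept = apply_enrollment_filter(hk, ds, study_end="2017-12-31")
        spans = merged_spans(ds.enrollment)
        index_day = to_day(kept["index_date"])
        death_day = to_day(kept["death_date"])
        for pid, idx, dth in zip(kept["patient_id"], index_day, death_day):
            need_end = min(idx + 360, dth)
            sub = spans[spans["patient_id"] == pid]
            assert (
                (sub["start_day"] <= idx - 360) & (sub["end_day"] >= need_end)
            ).any()
        assert (to_day(kept["ckd_diagnosis_date"]) <= index_day).all()
        assert (kept["ckd_duration_months"] >= 0).all()
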