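import numpy as np
import pandas as pd
import pytest

from hkburden import HK, NON_HK
from hkburden.dataset import COST_COMPONENTS
from hkburden.kmsa import (
    BootstrapConfig,
    IntervalGrid,
    IntervalOutcomes,
    KMSAError,
    KMSAEstimator,
    accrue_intervals,
    km_grid_weights,
    kmsa_point_estimate,
    paired_bootstrap,
    summarize_subgroup,
)

from ._oracles import kmsa_naive

from .conftest import d, make_dataset, make_members


def synthetic_outcomes(times, events, at_risk, outcome, grid=None) -> IntervalOutcomes:
    """Hand-assembled IntervalOutcomes (bypasses claims accrual)."""
    n, K = outcome.shape
    grid = grid or IntervalGrid(n_intervals=K)
    members = pd.DataFrame({"patient_id": np.arange(1, n + 1)})
    return IntervalOutcomes(
        members=members,
        grid=grid,
        at_risk=np.asarray(at_risk, dtype=bool),
        outcomes={"cost_total": np.asarray(outcome, dtype=float)},
        time=np.asarray(times, dtype=np.int64),
        event=np.asarray(events, dtype=bool),
    )


def random_fixture(rng, n_max=10):
    """Random small cohort: integer death/censor days and lumpy outcomes."""
    n = rng.integers(2, n_max + 1)
    times = rng.integers(1, 400, n)
    events = rng.random(n) < 0.5
    t = np.minimum(times, 360)
    at_risk = (t[:, None] > 30 * np.arange(12)[None, :]) | (
        (times > 360)[:, None] & np.ones((1, 12), dtype=bool)
    )
    outcome = rng.exponential(100, (n, 12)) * (rng.random((n, 12)) < 0.6)
    outcome[~at_risk] = 0.0
    return np.minimum(times, 361), events & (times <= 360), at_risk, outcome


class TestAccrual:
    def members(self):
        return make_members(
            [
                (1, HK, 1000, None, 1360),
                (2, HK, 1000, 1045, 1045),   # dies day 45 (interval 2)
                (3, HK, 1000, None, 1180),   # disenrolls day 180
            ]
        )

    def dataset(self):
        return make_dataset(
            patients=[(1, "F", 0, None), (2, "M", 0, 1045), (3, "F", 0, None)],
            enrollment=[(1, 0, 1360), (2, 0, 1045), (3, 0, 1180)],
            claims=[
                (1, "outpatient", 1000, "N18.9", 10.0),        # day 0 -> k1
                (1, "inpatient", 1029, "E87.5", 500.0, 1045),  # adm d29 -> k1
                (2, "outpatient", 1040, "I10", 20.0),          # k2 (alive at 30)
                (3, "outpatient", 1179, "I10", 30.0),          # k6, pre-disenroll
                (3, "outpatient", 1250, "I10", 40.0),          # after followup_end
            ],
        )

    def test_hand_assignment(self):
        io = accrue_intervals(self.members(), self.dataset())
        cost = io.outcomes["cost_total"]
        assert cost[0, 0] == 510.0          # day-0 visit + day-29 admission
        assert io.outcomes["los_days"][0, 0] == 17  # 1029..1045 inclusive
        assert io.outcomes["n_admissions"][0, 0] == 1
        assert cost[1, 1] == 20.0
        assert cost[2, 5] == 30.0
        assert cost[2].sum() == 30.0        # post-disenrollment claim ignored
        assert cost.sum() == 560.0

    def test_admission_fully_attributed_to_admission_interval(self):
        io = accrue_intervals(self.members(), self.dataset())
        # the day-29 admission discharged day 45 stays wholly in interval 1
        assert io.outcomes["cost_inpatient"][0, 1] == 0.0
        assert io.outcomes["los_days"][0, 1] == 0.0

    def test_at_risk_mask(self):
        io = accrue_intervals(self.members(), self.dataset())
        assert io.at_risk[0].all()
        assert io.at_risk[1].tolist() == [True, True] + [False] * 10
        assert io.at_risk[2].tolist() == [True] * 7 + [False] * 5

    def test_setting_and_component_decomposition(self, sim_small):
        _, ds, truth = sim_small
        lat = truth.latent
        hk = lat[lat["is_hk"]].head(150)
        study_end_day = np.datetime64("2017-12-31", "D").astype("int64")
        members = pd.DataFrame(
            {
                "patient_id": hk["patient_id"].to_numpy(),
                "cohort": HK,
                "index_date": pd.to_datetime(
                    hk["index_day"].to_numpy().astype("datetime64[D]")
                ),
                "death_date": pd.to_datetime(
                    np.where(
                        hk["death_day"] <= study_end_day,
                        hk["death_day"].to_numpy().astype("datetime64[D]"),
                        np.datetime64("NaT"),
                    )
                ),
                "followup_end": pd.to_datetime(
                    np.minimum(hk["death_day"], hk["index_day"] + 360)
                    .to_numpy().astype("datetime64[D]")
                ),
            }
        )
        io = accrue_intervals(members, ds)
        total = io.outcomes["cost_total"]
        assert np.allclose(
            total, io.outcomes["cost_inpatient"] + io.outcomes["cost_outpatient"]
        )
        comp_sum = sum(
            io.outcomes[f"cost_total_{c.removeprefix('cost_')}"]
            for c in COST_COMPONENTS
        )
        assert np.allclose(total, comp_sum, rtol=1e-9, atol=1e-6)


class TestPointEstimate:
    def test_no_deaths_reduces_to_plain_mean(self):
        n = 8
        outcome = np.full((n, 12), 100.0)
        io = synthetic_outcomes(
            np.full(n, 361), np.zeros(n, bool), np.ones((n, 12), bool), outcome
        )
        est = kmsa_point_estimate(io, "cost_total")
        assert est.point == 1200.0
        assert (est.survival_weights == 1.0).all()

    def test_two_patient_hand_example(self):
        # A alive all year at 10/month; B dies in month 1 with 50 in month 1
        # KM: S(0)=1, S(30k)=1/2 -> 1*(10+50)/2 + 11 * 0.5 * 10 = 85
        times = np.array([15, 361])
        events = np.array([True, False])
        at_risk = np.zeros((2, 12), bool)
        at_risk[1] = True
        at_risk[0, 0] = True
        outcome = np.zeros((2, 12))
        outcome[1] = 10.0
        outcome[0, 0] = 50.0
        io = synthetic_outcomes(times, events, at_risk, outcome)
        est = kmsa_point_estimate(io, "cost_total")
        assert est.point == pytest.approx(85.0)
        assert est.point == pytest.approx(
            kmsa_naive(times, events, at_risk, outcome), abs=1e-10
        )

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            times, events, at_risk, outcome = random_fixture(rng)
            io = synthetic_outcomes(times, events, at_risk, outcome)
            est = kmsa_point_estimate(io, "cost_total")
            assert est.point == pytest.approx(
                kmsa_naive(times, events, at_risk, outcome), abs=1e-10
            )

    def test_zero_at_risk_interval_warns(self):
        times = np.array([40, 50])
        events = np.array([True, True])
        at_risk = (np.array([40, 50])[:, None] > 30 * np.arange(12)[None, :])
        outcome = np.ones((2, 12))
        io = synthetic_outcomes(times, events, at_risk, outcome)
        with pytest.warns(RuntimeWarning):
            est = kmsa_point_estimate(io, "cost_total")
        assert np.isfinite(est.point)

    def test_monotone_weighting_under_extra_mortality(self):
        # converting censorings to deaths lowers every KM weight, so with
        # outcomes held fixed the estimate can only decrease
        rng = np.random.default_rng(13)
        for _ in range(10):
            times, events, at_risk, outcome = random_fixture(rng, n_max=8)
            more = events | (rng.random(len(times)) < 0.5)
            w1 = km_grid_weights(times, events, 30 * np.arange(12))
            w2 = km_grid_weights(times, more, 30 * np.arange(12))
            assert (w2 <= w1 + 1e-12).all()
            cbar = outcome.sum(axis=0) / np.maximum(at_risk.sum(axis=0), 1)
            assert w2 @ cbar <= w1 @ cbar + 1e-9

    def test_estimator_sklearn_protocol(self):
        est = KMSAEstimator(outcomes=("cost_total",))
        assert est.get_params() == {"outcomes": ("cost_total",)}
        clone_params = est.set_params(outcomes=None).get_params()
        assert clone_params == {"outcomes": None}
        with pytest.raises(KMSAError):
            KMSAEstimator().fit(
                synthetic_outcomes(
                    np.zeros(0, int), np.zeros(0, bool),
                    np.zeros((0, 12), bool), np.zeros((0, 12)),
                )
            )


class TestPairedBootstrap:
    def test_degenerate_data_zero_width(self):
        n = 6
        outcome = np.full((n, 12), 42.0)
        io = synthetic_outcomes(
            np.full(n, 361), np.zeros(n, bool), np.ones((n, 12), bool), outcome
        )
        res = paired_bootstrap(
            io, io, BootstrapConfig(n_iterations=200, seed=1),
            outcome_names=("cost_total",),
        )
        row = res.table.iloc[0]
        assert row["hk_lo"] == row["hk_hi"] == pytest.approx(504.0)
        assert row["diff_lo"] == row["diff_hi"] == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        times, events, at_risk, outcome = random_fixture(rng, n_max=10)
        io1 = synthetic_outcomes(times, events, at_risk, outcome)
        times2, events2, at_risk2, outcome2 = random_fixture(rng, n_max=10)
        n = min(len(times), len(times2))
        io1 = synthetic_outcomes(times[:n], events[:n], at_risk[:n], outcome[:n])
        io2 = synthetic_outcomes(times2[:n], events2[:n], at_risk2[:n], outcome2[:n])
        cfg = BootstrapConfig(n_iterations=150, seed=99)
        r1 = paired_bootstrap(io1, io2, cfg, outcome_names=("cost_total",))
        r2 = paired_bootstrap(io1, io2, cfg, outcome_names=("cost_total",))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_m_out_of_n_validation(self):
        io = synthetic_outcomes(
            np.full(4, 361), np.zeros(4, bool), np.ones((4, 12), bool),
            np.ones((4, 12)),
        )
        with pytest.raises(KMSAError):
            paired_bootstrap(
                io, io, BootstrapConfig(pairs_per_iteration=10),
                outcome_names=("cost_total",),
            )

    def test_few_iterations_warns(self):
        io = synthetic_outcomes(
            np.full(4, 361), np.zeros(4, bool), np.ones((4, 12), bool),
            np.ones((4, 12)),
        )
        with pytest.warns(RuntimeWarning):
            paired_bootstrap(
                io, io, BootstrapConfig(n_iterations=50, seed=0),
                outcome_names=("cost_total",),
            )


class TestSubgroups:
    def build(self, hk_spec, ct_spec):
        """spec: per pair (n_admissions interval-1, los, inpatient cost)."""
        def io_from(spec):
            n = len(spec)
            outcomes = {
                "n_admissions": np.zeros((n, 12)),
                "los_days": np.zeros((n, 12)),
                "cost_inpatient": np.zeros((n, 12)),
                "n_outpatient": np.zeros((n, 12)),
                "cost_outpatient": np.zeros((n, 12)),
            }
            for i, (adm, los, cost) in enumerate(spec):
                outcomes["n_admissions"][i, 0] = adm
                outcomes["los_days"][i, 0] = los
                outcomes["cost_inpatient"][i, 0] = cost
            return IntervalOutcomes(
                members=pd.DataFrame({"patient_id": np.arange(1, n + 1)}),
                grid=IntervalGrid(),
                at_risk=np.ones((n, 12), bool),
                outcomes=outcomes,
                time=np.full(n, 361, dtype=np.int64),
                event=np.zeros(n, bool),
            )

        return io_from(hk_spec), io_from(ct_spec)

    def test_single_pair_los_per_admission(self):
        io_hk, io_ct = self.build([(2, 30, 900.0)], [(1, 5, 100.0)])
        table = summarize_subgroup(io_hk, io_ct, "inpatient")
        row = table[(table["metric"] == "los_per_admission") & (table["cohort"] == "HK")]
        assert row["mean"].iloc[0] == 15.0  # admissions of 10 and 20 days
        cost_row = table[
            (table["metric"] == "cost_per_admission") & (table["cohort"] == "HK")
        ]
        assert cost_row["mean"].iloc[0] == 450.0

    def test_pair_with_one_sided_admission_excluded(self):
        io_hk, io_ct = self.build(
            [(2, 30, 900.0), (1, 10, 100.0)], [(1, 5, 100.0), (0, 0, 0.0)]
        )
        table = summarize_subgroup(io_hk, io_ct, "inpatient")
        assert (table["n_pairs"] == 1).all()

    def test_empty_subset_returns_empty(self):
        io_hk, io_ct = self.build([(0, 0, 0.0)], [(0, 0, 0.0)])
        assert summarize_subgroup(io_hk, io_ct, "inpatient").empty
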