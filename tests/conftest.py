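import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hkburden import ClaimsDataset, SimulationConfig, simulate_population
from hkburden.dataset import COST_COMPONENTS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DAY0 = pd.Timestamp("2010-01-01")
_EPOCH_OFFSET = (DAY0 - pd.Timestamp("1970-01-01")).days


def d(day: int) -> pd.Timestamp:
    """Integer day offset -> date (day 0 = 2010-01-01)."""
    return DAY0 + pd.Timedelta(days=day)


def rel_day(dates) -> np.ndarray:
    """Datetime-like -> integer day offsets from 2010-01-01."""
    from hkburden.dataset import to_day

    return to_day(dates) - _EPOCH_OFFSET


def make_dataset(patients=(), enrollment=(), claims=(), prescriptions=()) -> ClaimsDataset:
    """Hand-fixture builder; days are integer offsets from 2010-01-01.

    patients: (pid, sex, birth_day, death_day or None)
    enrollment: (pid, start_day, end_day)
    claims: (pid, setting, day, codes, total_cost[, discharge_day])
    prescriptions: (pid, day, drug_class)
    """
    pat = pd.DataFrame(
        [
            {
                "patient_id": p[0],
                "sex": p[1],
                "birth_date": d(p[2]),
                "death_date": d(p[3]) if p[3] is not None else pd.NaT,
            }
            for p in patients
        ],
        columns=["patient_id", "sex", "birth_date", "death_date"],
    )
    pat["birth_date"] = pd.to_datetime(pat["birth_date"])
    pat["death_date"] = pd.to_datetime(pat["death_date"])
    enr = pd.DataFrame(
        [
            {"patient_id": e[0], "start_date": d(e[1]), "end_date": d(e[2])}
            for e in enrollment
        ],
        columns=["patient_id", "start_date", "end_date"],
    )
    for col in ("start_date", "end_date"):
        enr[col] = pd.to_datetime(enr[col])
    rows = []
    for i, c in enumerate(claims):
        pid, setting, day, codes, total = c[:5]
        discharge = c[5] if len(c) > 5 else day
        inpat = setting == "inpatient"
        row = {
            "claim_id": i + 1,
            "patient_id": pid,
            "setting": setting,
            "service_date": d(day),
            "admission_date": d(day) if inpat else pd.NaT,
            "discharge_date": d(discharge) if inpat else pd.NaT,
            "diagnosis_codes": codes,
        }
        for j, comp in enumerate(COST_COMPONENTS):
            row[comp] = total if j == 0 else 0.0
        rows.append(row)
    clm = pd.DataFrame(
        rows,
        columns=[
            "claim_id", "patient_id", "setting", "service_date",
            "admission_date", "discharge_date", "diagnosis_codes",
            *COST_COMPONENTS,
        ],
    )
    for col in ("service_date", "admission_date", "discharge_date"):
        clm[col] = pd.to_datetime(clm[col])
    rx = pd.DataFrame(
        [{"patient_id": r[0], "date": d(r[1]), "drug_class": r[2]} for r in prescriptions],
        columns=["patient_id", "date", "drug_class"],
    )
    rx["date"] = pd.to_datetime(rx["date"])
    return ClaimsDataset(pat, enr, clm, rx).validate()


def make_members(rows) -> pd.DataFrame:
    """Cohort-member frame from (pid, cohort, index_day, death_day|None,
    followup_end_day) tuples."""
    out = pd.DataFrame(
        [
            {
                "patient_id": r[0],
                "cohort": r[1],
                "index_date": d(r[2]),
                "death_date": d(r[3]) if r[3] is not None else pd.NaT,
                "followup_end": d(r[4]),
            }
            for r in rows
        ]
    )
    for col in ("index_date", "death_date", "followup_end"):
        out[col] = pd.to_datetime(out[col])
    return out


@pytest.fixture(scope="session")
def sim_small():
    """Moderate synthetic population reused across tests (default study
    conditions, desk scale)."""
    config = SimulationConfig(n_patients=2500, rng_seed=123)
    dataset, truth = simulate_population(config)
    return config, dataset, truth
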