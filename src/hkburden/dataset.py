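"""Claims-data container: the three linked tables every analysis stage consumes.

The package works on administrative claims in long tabular form:

* ``patients`` — one row per enrollee: demographics and death date.
* ``enrollment`` — continuous coverage spans (a patient may have several).
* ``claims`` — inpatient / outpatient claim lines with ICD-10 diagnosis
  codes and the six-component cost decomposition.
* ``prescriptions`` — drug-class dispensing records.

All dates are ``datetime64[ns]``; costs are unitless currency amounts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

#: Cohort labels used throughout the package.
HK = "HK"
NON_HK = "non-HK"

#: The six itemized cost components, in reporting order.
COST_COMPONENTS = (
    "cost_medication",
    "cost_examination",
    "cost_treatment",
    "cost_surgery",
    "cost_consumable",
    "cost_other",
)

_PATIENT_COLS = ["patient_id", "sex", "birth_date", "death_date"]
_ENROLL_COLS = ["patient_id", "start_date", "end_date"]
_CLAIM_COLS = [
    "claim_id",
    "patient_id",
    "setting",
    "service_date",
    "admission_date",
    "discharge_date",
    "diagnosis_codes",
    *COST_COMPONENTS,
]
_RX_COLS = ["patient_id", "date", "drug_class"]

_DATE_COLS = {
    "patients": ["birth_date", "death_date"],
    "enrollment": ["start_date", "end_date"],
    "claims": ["service_date", "admission_date", "discharge_date"],
    "prescriptions": ["date"],
}


class DatasetError(ValueError):
    """Raised when a claims dataset violates its structural invariants."""


@dataclasses.dataclass
class ClaimsDataset:
    """The linked claims tables, bound together by ``patient_id``.

    ``diagnosis_codes`` is a semicolon-joined string of ICD-10 codes so the
    table round-trips through delimited text unchanged.
    """

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    prescriptions: pd.DataFrame

    def validate(self) -> "ClaimsDataset":
        """Check referential and temporal invariants; return self.

        Raises
        ------
        DatasetError
            If a claim or prescription references an unknown patient, an
            inpatient stay has discharge before admission, a claim is dated
            after the patient's death, or any cost component is negative.
        """
        for name, cols in (
            ("patients", _PATIENT_COLS),
            ("enrollment", _ENROLL_COLS),
            ("claims", _CLAIM_COLS),
            ("prescriptions", _RX_COLS),
        ):
            frame = getattr(self, name)
            missing = set(cols) - set(frame.columns)
            if missing:
                raise DatasetError(f"{name} table missing columns {sorted(missing)}")

        ids = set(self.patients["patient_id"])
        if len(ids) != len(self.patients):
            raise DatasetError("duplicate patient_id in patients table")
        for name in ("enrollment", "claims", "prescriptions"):
            bad = ~getattr(self, name)["patient_id"].isin(ids)
            if bad.any():
                raise DatasetError(
                    f"{name} table references {int(bad.sum())} unknown patient_id(s)"
                )

        claims = self.claims
        inpat = claims["setting"] == "inpatient"
        if inpat.any():
            adm = claims.loc[inpat, "admission_date"]
            dis = claims.loc[inpat, "discharge_date"]
            if adm.isna().any() or dis.isna().any():
                raise DatasetError("inpatient claims require admission/discharge dates")
            if (dis < adm).any():
                raise DatasetError("discharge_date before admission_date")
        for comp in COST_COMPONENTS:
            if (claims[comp] < 0).any():
                raise DatasetError(f"negative values in {comp}")

        death = self.patients.set_index("patient_id")["death_date"]
        claim_death = claims["patient_id"].map(death)
        late = claim_death.notna() & (claims["service_date"] > claim_death)
        if late.any():
            raise DatasetError(f"{int(late.sum())} claim(s) dated after death")
        return self

    def total_cost(self) -> pd.Series:
        """Per-claim total cost: the sum of the six components."""
        return self.claims[list(COST_COMPONENTS)].sum(axis=1)

    # -- persistence ---------------------------------------------------

    def write(self, out_dir: str | Path, manifest: dict | None = None) -> None:
        """Write the tables as UTF-8 CSV with ISO-8601 dates.

        An optional ``manifest`` dict (e.g. simulation config and seed) is
        written alongside as ``manifest.json``.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("patients", "enrollment", "claims", "prescriptions"):
            frame = getattr(self, name).copy()
            for col in _DATE_COLS[name]:
                frame[col] = frame[col].dt.strftime("%Y-%m-%d")
            frame.to_csv(out / f"{name}.csv", index=False)
        if manifest is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, in_dir: str | Path) -> "ClaimsDataset":
        """Read a dataset previously written with :meth:`write`."""
        src = Path(in_dir)
        frames = {}
        for name in ("patients", "enrollment", "claims", "prescriptions"):
            frame = pd.read_csv(src / f"{name}.csv")
            for col in _DATE_COLS[name]:
                frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d")
            if name == "claims":
                frame["diagnosis_codes"] = frame["diagnosis_codes"].fillna("")
            frames[name] = frame
        return cls(**frames).validate()


def to_day(dates) -> np.ndarray:
    """Convert datetime-like values to integer days since the Unix epoch.

    Missing dates map to the sentinel ``np.iinfo(np.int64).max`` so that
    comparisons like ``day < death_day`` treat the immortal correctly.
    """
    arr = pd.to_datetime(pd.Series(np.asarray(dates)))
    days = arr.values.astype("datetime64[D]").astype("int64")
    days[arr.isna().values] = np.iinfo(np.int64).max
    return days


def from_day(days) -> pd.Series:
    """Inverse of :func:`to_day` for non-missing integer days."""
    return pd.Series(np.asarray(days, dtype="int64").astype("datetime64[D]"))
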