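"""Charlson Comorbidity Index from ICD-10 codes.

Uses a Quan-style ICD-10 condition mapping with the original Charlson
weights, shipped as an editable CSV (``data/charlson_icd10.csv``). The
usual severity hierarchy applies: mild liver disease is not counted when
moderate/severe liver disease is present, uncomplicated diabetes yields
to diabetes with complications, and non-metastatic malignancy yields to
metastatic solid tumor.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd


@functools.lru_cache(maxsize=1)
def charlson_table() -> pd.DataFrame:
    """The condition/weight/prefix mapping (one row per condition)."""
    with resources.files("hkburden.data").joinpath("charlson_icd10.csv").open() as fh:
        table = pd.read_csv(fh)
    table["prefixes"] = table["prefixes"].str.split(";")
    return table


def cci_score(codes) -> int:
    """Charlson index for one patient's collection of ICD-10 codes."""
    codes = [c for c in codes if c]
    table = charlson_table()
    present = {
        row.condition
        for row in table.itertuples()
        if any(code.startswith(tuple(row.prefixes)) for code in codes)
    }
    return _sum_weights(present, table)


def _sum_weights(present: set[str], table: pd.DataFrame) -> int:
    score = 0
    for row in table.itertuples():
        if row.condition not in present:
            continue
        if isinstance(row.supersedes, str) and row.supersedes in present:
            continue  # the more severe form is counted instead
        score += int(row.weight)
    return score


def cci_by_patient(patient_ids: np.ndarray, codes: np.ndarray) -> pd.Series:
    """Vectorized CCI over (patient_id, code) pairs.

    Parameters are parallel arrays of exploded diagnosis codes; returns a
    Series indexed by patient_id (patients with no scoring code omitted).
    """
    table = charlson_table()
    frame = pd.DataFrame({"patient_id": patient_ids, "code": codes})
    flags = {}
    codes_s = frame["code"].astype(str)
    for row in table.itertuples():
        hit = codes_s.str.startswith(tuple(row.prefixes))
        if hit.any():
            flags[row.condition] = (
                frame.loc[hit, "patient_id"].drop_duplicates()
            )
    if not flags:
        return pd.Series(dtype=int)
    all_ids = pd.Index(
        np.unique(np.concatenate([np.asarray(ids) for ids in flags.values()])),
        name="patient_id",
    )
    cond_frame = pd.DataFrame(
        {cond: all_ids.isin(ids) for cond, ids in flags.items()}, index=all_ids
    )
    score = pd.Series(0, index=cond_frame.index)
    for row in table.itertuples():
        if row.condition not in cond_frame.columns:
            continue
        counted = cond_frame[row.condition]
        if isinstance(row.supersedes, str) and row.supersedes in cond_frame.columns:
            counted = counted & ~cond_frame[row.supersedes]
        score = score + counted.astype(int) * int(row.weight)
    return score
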