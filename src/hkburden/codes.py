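"""ICD-10 code sets and prefix matching.

Cohort identification is prefix-based: the stored code ``N18`` matches any
claim code starting with ``N18`` (``N18``, ``N18.5``, ...). Free-text
diagnosis matching is out of scope; code lists are configurable instead.
"""

from __future__ import annotations

import dataclasses
import re

import pandas as pd

#: CKD-defining ICD-10 prefixes: diabetic nephropathy (E1x.2), hypertensive
#: renal disease (I12/I13), glomerular disease (N03-N05), chronic kidney
#: disease/failure (N18/N19), dialysis care (Z49) and dialysis status (Z99.2).
DEFAULT_CKD_CODES = (
    "E10.2", "E11.2", "E12.2", "E13.2", "E14.2",
    "I12", "I13", "N03", "N04", "N05", "N18", "N19", "Z49", "Z99.2",
)
#: Hyperkalemia.
DEFAULT_HK_CODES = ("E87.5",)
#: Malignant neoplasms (sensitivity analysis 1).
DEFAULT_MALIGNANCY_CODES = ("C",)

_CODE_RE = re.compile(r"^[A-Z0-9.]+$")


class CodeSetError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CodeSet:
    """The configurable ICD-10 prefix lists driving cohort construction."""

    ckd_codes: tuple[str, ...] = DEFAULT_CKD_CODES
    hk_codes: tuple[str, ...] = DEFAULT_HK_CODES
    malignancy_codes: tuple[str, ...] = DEFAULT_MALIGNANCY_CODES

    def __post_init__(self):
        for field in dataclasses.fields(self):
            codes = tuple(getattr(self, field.name))
            object.__setattr__(self, field.name, codes)
            if not codes:
                raise CodeSetError(f"{field.name} must be non-empty")
            for code in codes:
                if not _CODE_RE.match(code):
                    raise CodeSetError(
                        f"{field.name}: {code!r} is not an uppercase ICD-10 prefix"
                    )


def explode_codes(claims: pd.DataFrame) -> pd.DataFrame:
    """One row per (claim, diagnosis code) from the ';'-joined code column."""
    codes = claims["diagnosis_codes"].fillna("").str.split(";").explode()
    codes = codes[codes != ""]
    return pd.DataFrame(
        {"row": codes.index, "code": codes.values}
    )


def claims_matching(claims: pd.DataFrame, prefixes: tuple[str, ...]) -> pd.Series:
    """Boolean mask (aligned with ``claims``) of claims carrying any code
    that starts with one of ``prefixes``."""
    exploded = explode_codes(claims)
    hit = exploded.loc[
        exploded["code"].str.startswith(tuple(prefixes)), "row"
    ].unique()
    mask = pd.Series(False, index=claims.index)
    mask.loc[hit] = True
    return mask
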