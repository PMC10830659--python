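"""Reading and writing the plain-text interchange formats.

Cohort CSV schema: one row per patient with columns
{patient_id, age, sex, height_cm, weight_kg, heart_rate, hemoglobin_g_dl,
sao2, svo2, td_co_l_min, mpap_mmhg, mpawp_mmhg}; sex coded m/f; an empty
cell means missing. Input CSVs are written at full float precision so a
generate -> analyze round trip is exact; analysis result CSVs are rounded to
4 decimals at serialization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .hemo_core import FORMULAS, HemoDerived, PatientRecord, Sex

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "heart_rate",
    "hemoglobin_g_dl",
    "sao2",
    "svo2",
    "td_co_l_min",
    "mpap_mmhg",
    "mpawp_mmhg",
]

# Fields a record cannot be built without; rows lacking one are excluded
# (with a logged reason), not errors.
_CORE_FIELDS = [
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "hemoglobin_g_dl",
    "sao2",
    "svo2",
]

_SEX_CODES = {"m": Sex.MALE, "f": Sex.FEMALE}


class SchemaError(ValueError):
    """The cohort CSV violates the schema; ``rows`` lists (row, id, reason)."""

    def __init__(self, message: str, rows: Optional[list] = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass
class CohortReadResult:
    records: List[PatientRecord]
    exclusions: List[Tuple[str, str]]  # (patient_id, reason)


def _cell(row, column) -> Optional[float]:
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_cohort(path) -> CohortReadResult:
    """Parse a cohort CSV into validated records.

    Structural problems (missing columns, unparseable numbers, bad sex codes)
    raise :class:`SchemaError` carrying the offending rows. Rows missing a
    core field are excluded with a reason instead.
    """
    frame = pd.read_csv(
        path, dtype={"patient_id": str, "sex": str}, float_precision="round_trip"
    )
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort CSV is missing required columns: {missing}")

    records: List[PatientRecord] = []
    exclusions: List[Tuple[str, str]] = []
    bad_rows: List[Tuple[int, str, str]] = []
    for idx, row in frame.iterrows():
        pid = row["patient_id"]
        pid = f"row{idx}" if pd.isna(pid) else str(pid)
        missing_core = [
            c for c in _CORE_FIELDS if pd.isna(row[c]) or row[c] == ""
        ]
        if missing_core:
            exclusions.append((pid, f"missing core fields: {missing_core}"))
            continue
        try:
            sex_code = str(row["sex"]).strip().lower()
            if sex_code not in _SEX_CODES:
                raise ValueError(f"sex must be coded m/f, got {row['sex']!r}")
            record = PatientRecord(
                patient_id=pid,
                age=float(row["age"]),
                sex=_SEX_CODES[sex_code],
                height=float(row["height_cm"]),
                weight=float(row["weight_kg"]),
                hemoglobin=float(row["hemoglobin_g_dl"]),
                sao2=float(row["sao2"]),
                svo2=float(row["svo2"]),
                heart_rate=_cell(row, "heart_rate"),
                td_co=_cell(row, "td_co_l_min"),
                mpap=_cell(row, "mpap_mmhg"),
                mpawp=_cell(row, "mpawp_mmhg"),
            )
        except (TypeError, ValueError) as exc:
            bad_rows.append((int(idx), pid, str(exc)))
            continue
        records.append(record)
    if bad_rows:
        raise SchemaError(
            f"{len(bad_rows)} row(s) violate the cohort schema", rows=bad_rows
        )
    return CohortReadResult(records=records, exclusions=exclusions)


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": Sex(r.sex).value,
            "height_cm": r.height,
            "weight_kg": r.weight,
            "heart_rate": r.heart_rate,
            "hemoglobin_g_dl": r.hemoglobin,
            "sao2": r.sao2,
            "svo2": r.svo2,
            "td_co_l_min": r.td_co,
            "mpap_mmhg": r.mpap,
            "mpawp_mmhg": r.mpawp,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    """Full-precision cohort CSV (shortest round-tripping float repr)."""
    cohort_to_frame(records).to_csv(path, index=False)


def derived_to_frame(derived: Sequence[HemoDerived]) -> pd.DataFrame:
    """Wide table: one column per (formula, quantity)."""
    rows = []
    for d in derived:
        row = {
            "patient_id": d.patient_id,
            "bsa_m2": d.bsa,
            "avdo2_ml_dl": d.avdo2,
            "td_co_l_min": d.td_co,
            "td_ci_l_min_m2": d.td_ci,
            "pvr_dyn_s_cm5": d.pvr,
        }
        for f in FORMULAS:
            row[f"vo2_{f.value}_ml_min"] = d.vo2.get(f)
            row[f"ifm_co_{f.value}_l_min"] = d.ifm_co.get(f)
            row[f"ifm_ci_{f.value}_l_min_m2"] = d.ifm_ci.get(f)
        rows.append(row)
    return pd.DataFrame(rows)


def write_derived_csv(derived: Sequence[HemoDerived], path) -> None:
    derived_to_frame(derived).to_csv(path, index=False, float_format="%.4f")
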