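"""Per-patient hemodynamic computations.

Body surface area (Dubois power law), the four VO2 approximation formulas
(Krakau, LaFarge, Dehmer, Bergstra), arteriovenous oxygen content difference,
indirect-Fick cardiac output, and derived indices (cardiac index, pulmonary
vascular resistance).

Units are fixed throughout: height cm, weight kg, hemoglobin g/dL,
saturations as fractions of 1 (a percent mode converts 0-100 inputs),
VO2 mL/min, oxygen content mL/dL, cardiac output L/min, pressures mm Hg,
PVR dyn*s/cm^5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Optional

__all__ = [
    "DataError",
    "Sex",
    "Formula",
    "FORMULAS",
    "PatientRecord",
    "HemoDerived",
    "compute_bsa",
    "estimate_vo2",
    "compute_avdo2",
    "compute_fick_co",
    "compute_pvr",
    "derive_all",
    "derive_cohort",
    "normalize_saturation",
]

#: Oxygen-binding capacity of hemoglobin, mL O2 per gram (Huefner constant).
HUFNER_ML_PER_G = 1.34

# Dubois & Dubois (1916) body-surface-area power law constants.
_DUBOIS_COEF = 0.007184
_DUBOIS_H_EXP = 0.725
_DUBOIS_W_EXP = 0.425


class DataError(ValueError):
    """A measurement violates a physiological or unit precondition."""


class Sex(str, Enum):
    MALE = "m"
    FEMALE = "f"


class Formula(str, Enum):
    """The four VO2 approximation formulas; a closed set — every per-formula
    operation iterates exactly these members."""

    KRAKAU = "krakau"
    LAFARGE = "lafarge"
    DEHMER = "dehmer"
    BERGSTRA = "bergstra"


FORMULAS: tuple[Formula, ...] = tuple(Formula)


def compute_bsa(height: float, weight: float) -> float:
    """Body surface area in m^2 from height (cm) and weight (kg).

    Dubois power law: 0.007184 * height^0.725 * weight^0.425. Strictly
    increasing in both arguments.
    """
    if not height > 0:
        raise DataError(f"height must be > 0 cm, got {height!r}")
    if not weight > 0:
        raise DataError(f"weight must be > 0 kg, got {weight!r}")
    return _DUBOIS_COEF * height**_DUBOIS_H_EXP * weight**_DUBOIS_W_EXP


def estimate_vo2(
    formula: Formula,
    sex: Sex,
    age: float,
    bsa: float,
    heart_rate: Optional[float] = None,
) -> float:
    """Estimated oxygen consumption (mL/min) under one approximation formula.

    Sex-specific where the formula distinguishes sexes (Krakau, LaFarge slope
    on ln(age); Bergstra adds a constant 10 for men; Dehmer is sex-invariant).
    ``heart_rate`` (beats/min) is required only by LaFarge.
    """
    formula = Formula(formula)
    sex = Sex(sex)
    if not age > 0:
        raise DataError(f"age must be > 0 years, got {age!r}")
    if not bsa > 0:
        raise DataError(f"bsa must be > 0 m^2, got {bsa!r}")

    if formula is Formula.KRAKAU:
        if sex is Sex.MALE:
            return bsa * (161.0 - age * 0.54)
        return bsa * (147.5 - age * 0.47)
    if formula is Formula.LAFARGE:
        if heart_rate is None:
            raise DataError("LaFarge formula requires heart_rate (beats/min)")
        if not heart_rate > 0:
            raise DataError(f"heart_rate must be > 0, got {heart_rate!r}")
        slope = 11.49 if sex is Sex.MALE else 17.04
        return bsa * (138.1 - slope * math.log(age) + 0.378 * heart_rate)
    if formula is Formula.DEHMER:
        return bsa * 125.0
    # Bergstra: the male "+10" is additive, not multiplied by BSA.
    male_term = 10.0 if sex is Sex.MALE else 0.0
    return bsa * 157.3 + male_term - 10.5 * math.log(age) + 4.8


def normalize_saturation(value: float, saturation_mode: str = "fraction") -> float:
    """Coerce a saturation to a fraction in (0, 1].

    ``percent`` mode divides 0-100 inputs by 100. In fraction mode, values in
    (1, 1.5] are rejected as ambiguous and values > 1.5 are rejected with a
    hint that they look like the 0-100 scale.
    """
    if saturation_mode not in ("fraction", "percent"):
        raise ValueError(f"saturation_mode must be 'fraction' or 'percent', got {saturation_mode!r}")
    if saturation_mode == "percent":
        value = value / 100.0
    elif value > 1.5:
        raise DataError(
            f"saturation {value!r} looks like a 0-100 percentage; "
            "pass saturation_mode='percent' to convert"
        )
    elif value > 1.0:
        raise DataError(f"saturation {value!r} is ambiguous (neither fraction nor percent)")
    if not 0.0 < value <= 1.0:
        raise DataError(f"saturation must lie in (0, 1] after normalization, got {value!r}")
    return value


def compute_avdo2(
    hemoglobin: float,
    sao2: float,
    svo2: float,
    saturation_mode: str = "fraction",
) -> float:
    """Arteriovenous O2 content difference, mL O2 per dL blood.

    hemoglobin (g/dL) * 1.34 mL/g * (SaO2 - SvO2), saturations as fractions.
    """
    if not hemoglobin > 0:
        raise DataError(f"hemoglobin must be > 0 g/dL, got {hemoglobin!r}")
    sao2 = normalize_saturation(sao2, saturation_mode)
    svo2 = normalize_saturation(svo2, saturation_mode)
    if not sao2 > svo2:
        raise DataError(
            f"arterial saturation must exceed mixed-venous: sao2={sao2!r} <= svo2={svo2!r}"
        )
    return hemoglobin * HUFNER_ML_PER_G * (sao2 - svo2)


def compute_fick_co(vo2: float, avdo2: float) -> float:
    """Indirect-Fick cardiac output, L/min.

    CO = VO2 / (10 * avDO2). The factor 10 converts O2 content from per-dL to
    per-L so that mL/min divided by mL/L yields L/min.
    """
    if not vo2 > 0:
        raise DataError(f"vo2 must be > 0 mL/min, got {vo2!r}")
    if not avdo2 > 0:
        raise DataError(f"avdo2 must be > 0 mL/dL, got {avdo2!r}")
    return vo2 / (avdo2 * 10.0)


def compute_pvr(mpap: float, mpawp: float, co: float) -> float:
    """Pulmonary vascular resistance, dyn*s/cm^5: 80 * (mPAP - mPAWP) / CO."""
    if not co > 0:
        raise DataError(f"cardiac output must be > 0 L/min, got {co!r}")
    if mpap < mpawp:
        raise DataError(f"mPAP ({mpap!r}) must be >= mPAWP ({mpawp!r}) mm Hg")
    return 80.0 * (mpap - mpawp) / co


@dataclass(frozen=True)
class PatientRecord:
    """One catheterization patient's raw measurements.

    Optional fields (``heart_rate``, ``td_co``, ``mpap``, ``mpawp``) may be
    None; derived quantities depending on them are then simply absent, never
    imputed.
    """

    patient_id: str
    age: float
    sex: Sex
    height: float
    weight: float
    hemoglobin: float
    sao2: float
    svo2: float
    heart_rate: Optional[float] = None
    td_co: Optional[float] = None
    mpap: Optional[float] = None
    mpawp: Optional[float] = None

    def validate(self) -> None:
        """Raise :class:`DataError` if any invariant fails (saturations are
        assumed to already be fractions)."""
        for name in ("age", "height", "weight", "hemoglobin", "sao2", "svo2"):
            value = getattr(self, name)
            if not value > 0:
                raise DataError(f"{name} must be strictly positive, got {value!r}")
        for name in ("heart_rate", "td_co"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DataError(f"{name} must be strictly positive when present, got {value!r}")
        Sex(self.sex)
        if not self.sao2 > self.svo2:
            raise DataError(
                f"sao2 ({self.sao2!r}) must exceed svo2 ({self.svo2!r})"
            )
        if self.mpap is not None and self.mpawp is not None and self.mpap < self.mpawp:
            raise DataError(f"mpap ({self.mpap!r}) < mpawp ({self.mpawp!r})")


@dataclass(frozen=True)
class HemoDerived:
    """Every quantity computed for one patient.

    ``vo2`` / ``ifm_co`` / ``ifm_ci`` map formula -> value; formulas whose
    inputs were missing are absent from the maps.
    """

    patient_id: str
    bsa: float
    avdo2: float
    vo2: Dict[Formula, float] = field(default_factory=dict)
    ifm_co: Dict[Formula, float] = field(default_factory=dict)
    ifm_ci: Dict[Formula, float] = field(default_factory=dict)
    td_co: Optional[float] = None
    td_ci: Optional[float] = None
    pvr: Optional[float] = None


def derive_all(record: PatientRecord, saturation_mode: str = "fraction") -> HemoDerived:
    """Populate every derivable :class:`HemoDerived` field for one record.

    Deterministic; any constituent error propagates with the patient_id
    attached. Formulas whose required inputs are missing (LaFarge without
    heart rate) are skipped, as are TD index / PVR without their inputs.
    """
    try:
        record = replace(
            record,
            sao2=normalize_saturation(record.sao2, saturation_mode),
            svo2=normalize_saturation(record.svo2, saturation_mode),
        )
        record.validate()
        bsa = compute_bsa(record.height, record.weight)
        avdo2 = compute_avdo2(record.hemoglobin, record.sao2, record.svo2)
        vo2: Dict[Formula, float] = {}
        ifm_co: Dict[Formula, float] = {}
        ifm_ci: Dict[Formula, float] = {}
        for formula in FORMULAS:
            if formula is Formula.LAFARGE and record.heart_rate is None:
                continue
            v = estimate_vo2(formula, record.sex, record.age, bsa, record.heart_rate)
            co = compute_fick_co(v, avdo2)
            vo2[formula] = v
            ifm_co[formula] = co
            ifm_ci[formula] = co / bsa
        td_ci = record.td_co / bsa if record.td_co is not None else None
        pvr = None
        if record.td_co is not None and record.mpap is not None and record.mpawp is not None:
            pvr = compute_pvr(record.mpap, record.mpawp, record.td_co)
    except DataError as exc:
        raise DataError(f"patient {record.patient_id}: {exc}") from exc
    return HemoDerived(
        patient_id=record.patient_id,
        bsa=bsa,
        avdo2=avdo2,
        vo2=vo2,
        ifm_co=ifm_co,
        ifm_ci=ifm_ci,
        td_co=record.td_co,
        td_ci=td_ci,
        pvr=pvr,
    )


def derive_cohort(records, saturation_mode: str = "fraction") -> list[HemoDerived]:
    """Apply :func:`derive_all` to every record, preserving order."""
    return [derive_all(r, saturation_mode) for r in records]
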