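"""Synthetic right-heart-catheterization cohorts with known ground truth.

Demographics, oximetry and pressures are drawn from truncated normal
distributions (out-of-bound draws are redrawn, not clipped). A latent true
cardiac output is defined per patient as the indirect-Fick CO under a chosen
truth formula; the reference (thermodilution-style) CO is then

    td_co = true_co * exp(log_bias + eps),   eps ~ Normal(0, noise_sd^2),

a multiplicative log-normal disagreement model that keeps CO positive and
makes the comparator/reference ratio exp(-log_bias - eps), for which the
discordance probability has the closed form in :func:`expected_discordance`.

All randomness flows from one ``numpy.random.SeedSequence``: each variable
gets its own spawned child stream, so adding a variable never perturbs
previously generated columns.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .hemo_core import (
    Formula,
    PatientRecord,
    Sex,
    compute_avdo2,
    compute_bsa,
    compute_fick_co,
    estimate_vo2,
)

__all__ = ["ConfigError", "SynthConfig", "SynthCohort", "generate", "expected_discordance"]

# Spawn order is append-only: new variables take new trailing streams.
_STREAMS = (
    "sex",
    "age",
    "height",
    "weight",
    "hemoglobin",
    "heart_rate",
    "sao2",
    "svo2",
    "mpawp",
    "tpg",
    "noise",
)


class ConfigError(ValueError):
    """A generative parameter is invalid or its truncation support is empty."""


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters for one synthetic cohort.

    Marginal defaults approximate a contemporary catheterization population:
    age 63 +/- 14.4 y truncated to [18, 95], 30% women, hemoglobin
    13.7 +/- 1.8 g/dL, and saturations kept physiological (SaO2 in
    [0.85, 1.0], SvO2 in [0.30, 0.85], gap >= ``min_sat_gap``).
    """

    n: int = 200
    seed: int = 0
    prop_female: float = 0.30
    age_mean: float = 63.0
    age_sd: float = 14.4
    age_bounds: Tuple[float, float] = (18.0, 95.0)
    height_mean_male: float = 176.0
    height_mean_female: float = 163.0
    height_sd: float = 7.0
    height_bounds: Tuple[float, float] = (140.0, 210.0)
    weight_mean_male: float = 85.0
    weight_mean_female: float = 71.0
    weight_sd: float = 14.0
    weight_bounds: Tuple[float, float] = (40.0, 160.0)
    hb_mean: float = 13.7
    hb_sd: float = 1.8
    hb_bounds: Tuple[float, float] = (8.0, 19.0)
    hr_mean: float = 72.0
    hr_sd: float = 13.0
    hr_bounds: Tuple[float, float] = (40.0, 140.0)
    sao2_mean: float = 0.95
    sao2_sd: float = 0.02
    sao2_bounds: Tuple[float, float] = (0.85, 1.0)
    svo2_mean: float = 0.65
    svo2_sd: float = 0.07
    svo2_bounds: Tuple[float, float] = (0.30, 0.85)
    min_sat_gap: float = 0.02
    mpawp_mean: float = 13.0
    mpawp_sd: float = 6.0
    mpawp_bounds: Tuple[float, float] = (3.0, 35.0)
    tpg_mean: float = 9.0
    tpg_sd: float = 6.0
    tpg_bounds: Tuple[float, float] = (1.0, 60.0)
    truth_formula: Formula = Formula.KRAKAU
    log_bias: float = 0.0
    noise_sd: float = 0.15

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError(f"prop_female must lie in [0, 1], got {self.prop_female}")
        for name in (
            "age_sd", "height_sd", "weight_sd", "hb_sd", "hr_sd",
            "sao2_sd", "svo2_sd", "mpawp_sd", "tpg_sd", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "age_bounds", "height_bounds", "weight_bounds", "hb_bounds",
            "hr_bounds", "sao2_bounds", "svo2_bounds", "mpawp_bounds", "tpg_bounds",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} has empty support: ({lo}, {hi})")
        if self.min_sat_gap < 0:
            raise ConfigError(f"min_sat_gap must be >= 0, got {self.min_sat_gap}")
        if self.svo2_bounds[0] + self.min_sat_gap >= self.sao2_bounds[1]:
            raise ConfigError("saturation bounds leave no room for sao2 > svo2")
        Formula(self.truth_formula)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["truth_formula"] = Formula(self.truth_formula).value
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        if "truth_formula" in kwargs:
            try:
                kwargs["truth_formula"] = Formula(kwargs["truth_formula"])
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
        for key, value in kwargs.items():
            if key.endswith("_bounds"):
                kwargs[key] = tuple(value)
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_file(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


@dataclass
class SynthCohort:
    """Generated records plus the per-patient ground truth, aligned by
    patient_id."""

    records: list
    truth: pd.DataFrame
    config: SynthConfig


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws; mean/lo/hi may be scalars or per-element arrays.

    sd == 0 collapses to the (bounds-checked) point mass at the mean.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (size,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (size,))
    if np.any(lo >= hi):
        raise ConfigError("truncation support is empty for some draws")
    if sd == 0.0:
        if np.any((mean < lo) | (mean > hi)):
            raise ConfigError("degenerate distribution lies outside its truncation bounds")
        return mean.copy()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SynthConfig) -> SynthCohort:
    """Draw a cohort from ``config``; bitwise-deterministic given the seed.

    The latent true CO is computed with the same scalar routines the analysis
    pipeline uses, so a zero-noise, zero-bias cohort reproduces td_co exactly
    when re-derived.
    """
    config.validate()
    n = config.n
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    rng = {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}

    female = rng["sex"].random(n) < config.prop_female
    age = _truncnorm(rng["age"], config.age_mean, config.age_sd, *config.age_bounds, size=n)
    height_mean = np.where(female, config.height_mean_female, config.height_mean_male)
    height = _truncnorm(rng["height"], height_mean, config.height_sd,
                        *config.height_bounds, size=n)
    weight_mean = np.where(female, config.weight_mean_female, config.weight_mean_male)
    weight = _truncnorm(rng["weight"], weight_mean, config.weight_sd,
                        *config.weight_bounds, size=n)
    hb = _truncnorm(rng["hemoglobin"], config.hb_mean, config.hb_sd, *config.hb_bounds, size=n)
    hr = _truncnorm(rng["heart_rate"], config.hr_mean, config.hr_sd, *config.hr_bounds, size=n)
    sao2 = _truncnorm(rng["sao2"], config.sao2_mean, config.sao2_sd, *config.sao2_bounds, size=n)
    # SvO2 upper bound is per-patient: min(config bound, sao2 - gap).
    svo2_hi = np.minimum(config.svo2_bounds[1], sao2 - config.min_sat_gap)
    svo2 = _truncnorm(rng["svo2"], config.svo2_mean, config.svo2_sd,
                      config.svo2_bounds[0], svo2_hi, size=n)
    svo2 = np.minimum(svo2, svo2_hi)  # guard against fp edge at the bound
    mpawp = _truncnorm(rng["mpawp"], config.mpawp_mean, config.mpawp_sd,
                       *config.mpawp_bounds, size=n)
    tpg = _truncnorm(rng["tpg"], config.tpg_mean, config.tpg_sd, *config.tpg_bounds, size=n)
    mpap = mpawp + tpg
    eps = (
        rng["noise"].normal(0.0, config.noise_sd, size=n)
        if config.noise_sd > 0
        else np.zeros(n)
    )

    width = max(5, len(str(n)))
    records = []
    truth_rows = []
    truth_formula = Formula(config.truth_formula)
    for i in range(n):
        sex = Sex.FEMALE if female[i] else Sex.MALE
        bsa = compute_bsa(height[i], weight[i])
        vo2_truth = estimate_vo2(truth_formula, sex, age[i], bsa, hr[i])
        avdo2 = compute_avdo2(hb[i], sao2[i], svo2[i])
        true_co = compute_fick_co(vo2_truth, avdo2)
        td_co = true_co * math.exp(config.log_bias + eps[i])
        pid = f"S{i:0{width}d}"
        records.append(
            PatientRecord(
                patient_id=pid,
                age=float(age[i]),
                sex=sex,
                height=float(height[i]),
                weight=float(weight[i]),
                hemoglobin=float(hb[i]),
                sao2=float(sao2[i]),
                svo2=float(svo2[i]),
                heart_rate=float(hr[i]),
                td_co=float(td_co),
                mpap=float(mpap[i]),
                mpawp=float(mpawp[i]),
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_co": float(true_co),
                "epsilon": float(eps[i]),
                "vo2_truth": float(vo2_truth),
            }
        )
    return SynthCohort(records=records, truth=pd.DataFrame(truth_rows), config=config)


def expected_discordance(noise_sd: float, log_bias: float = 0.0) -> float:
    """Closed-form probability that the comparator/reference ratio leaves
    [0.8, 1.2] under the generative model.

    With ratio = exp(-log_bias - eps), eps ~ N(0, noise_sd^2):

        P = Phi((ln 0.8 + beta) / sigma) + 1 - Phi((ln 1.2 + beta) / sigma).

    For sigma = 0 the ratio is the point mass exp(-beta) and the function
    returns the indicator of it lying outside [0.8, 1.2] (bounds inclusive,
    matching the concordant class).
    """
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0.0:
        ratio = math.exp(-log_bias)
        return 0.0 if 0.8 <= ratio <= 1.2 else 1.0
    z_low = (math.log(0.8) + log_bias) / noise_sd
    z_high = (math.log(1.2) + log_bias) / noise_sd
    return float(stats.norm.cdf(z_low) + 1.0 - stats.norm.cdf(z_high))
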