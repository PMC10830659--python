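"""Pairwise method-comparison statistics for cardiac-output series.

Convention for every :class:`MethodPair`: ``values_a`` is the reference (or
first) method and ``values_b`` the comparator. Differences are a - b
(reference minus comparator); ratios are b / a (comparator over reference).
Each pair keeps only rows where both series are present and finite
(pairwise-complete handling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hemo_core import FORMULAS, Formula, HemoDerived

__all__ = [
    "AgreementError",
    "RatioClass",
    "MethodPair",
    "BlandAltmanResult",
    "AgreementReport",
    "KappaResult",
    "StudyReport",
    "classify_ratio",
    "ratio_classes",
    "deviation_table",
    "bland_altman",
    "percentage_error",
    "pearson_with_ci",
    "cohen_kappa",
    "compare_all",
]

#: Acceptability threshold for the percentage error, percent.
ACCEPTABLE_PE_PERCENT = 30.0


class AgreementError(ValueError):
    """A comparison's preconditions are not met (too few pairs, etc.)."""


class RatioClass(str, Enum):
    """Three-way classification of a comparator/reference CO ratio.

    ``under`` < 0.8, ``concordant`` in [0.8, 1.2] (boundaries inclusive),
    ``over`` > 1.2. The classes partition the positive reals.
    """

    UNDER = "under"
    CONCORDANT = "concordant"
    OVER = "over"


RATIO_CLASSES: tuple[RatioClass, ...] = tuple(RatioClass)


@dataclass(frozen=True)
class MethodPair:
    """Two paired CO series restricted to rows where both are present."""

    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    ids: tuple = ()

    @classmethod
    def from_series(cls, label_a, values_a, label_b, values_b, ids=None) -> "MethodPair":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.shape != b.shape:
            raise AgreementError(
                f"paired series must have equal length, got {a.shape} vs {b.shape}"
            )
        mask = np.isfinite(a) & np.isfinite(b)
        kept_ids: tuple = ()
        if ids is not None:
            ids = np.asarray(ids, dtype=object)
            kept_ids = tuple(ids[mask])
        return cls(label_a, label_b, a[mask], b[mask], kept_ids)

    @property
    def n(self) -> int:
        return int(self.values_a.size)

    def swapped(self) -> "MethodPair":
        return MethodPair(self.label_b, self.label_a, self.values_b, self.values_a, self.ids)


def classify_ratio(co_ifm: float, co_ref: float) -> RatioClass:
    """Classify the ratio co_ifm / co_ref; 0.8 and 1.2 are concordant."""
    if not co_ref > 0:
        raise AgreementError(f"reference CO must be > 0, got {co_ref!r}")
    if not co_ifm > 0:
        raise AgreementError(f"comparator CO must be > 0, got {co_ifm!r}")
    ratio = co_ifm / co_ref
    if ratio < 0.8:
        return RatioClass.UNDER
    if ratio > 1.2:
        return RatioClass.OVER
    return RatioClass.CONCORDANT


def ratio_classes(pair: MethodPair) -> List[RatioClass]:
    """Row-wise ratio classification of comparator vs reference."""
    return [classify_ratio(b, a) for a, b in zip(pair.values_a, pair.values_b)]


def deviation_table(pairs: Iterable[MethodPair]) -> pd.DataFrame:
    """Per-method counts and percentages of the three ratio classes.

    Percentages are computed on each pair's own complete-case n.
    """
    rows = []
    for pair in pairs:
        if pair.n == 0:
            raise AgreementError(f"empty pair {pair.label_b} vs {pair.label_a}")
        classes = ratio_classes(pair)
        row: Dict[str, object] = {"method": pair.label_b, "reference": pair.label_a, "n": pair.n}
        for cls in RATIO_CLASSES:
            count = sum(c is cls for c in classes)
            row[f"n_{cls.value}"] = count
            row[f"pct_{cls.value}"] = 100.0 * count / pair.n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(pair: MethodPair, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Mean difference and limits of agreement (mean_diff +/- 1.96 * SD).

    SD uses the n-1 denominator. The per-pair (mean, diff) coordinates are
    returned for plotting.
    """
    if pair.n < 2:
        raise AgreementError(f"need n >= 2 pairs for limits of agreement, got {pair.n}")
    diffs = pair.values_a - pair.values_b
    means = 0.5 * (pair.values_a + pair.values_b)
    mean_diff = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - loa_multiplier * sd,
        loa_high=mean_diff + loa_multiplier * sd,
        sd_diff=sd,
        means=means,
        diffs=diffs,
    )


def percentage_error(pair: MethodPair, multiplier: float = 1.96) -> float:
    """Percentage error: 100 * multiplier * SD(a-b) / (0.5 * (mean(a)+mean(b))).

    ``multiplier`` defaults to 1.96; 2.0 is accepted for sensitivity checks.
    Scale-invariant and symmetric under swapping the pair's roles.
    """
    if pair.n < 2:
        raise AgreementError(f"need n >= 2 pairs for percentage error, got {pair.n}")
    mean_of_means = 0.5 * (float(np.mean(pair.values_a)) + float(np.mean(pair.values_b)))
    if not mean_of_means > 0:
        raise AgreementError(f"combined mean must be > 0, got {mean_of_means!r}")
    sd = float(np.std(pair.values_a - pair.values_b, ddof=1))
    return 100.0 * multiplier * sd / mean_of_means


def pearson_with_ci(pair: MethodPair) -> tuple[float, float, float]:
    """Sample Pearson r with a 95% CI from the Fisher z-transform."""
    if pair.n < 4:
        raise AgreementError(f"need n >= 4 pairs for a correlation CI, got {pair.n}")
    a, b = pair.values_a, pair.values_b
    if np.std(a) == 0 or np.std(b) == 0:
        raise AgreementError("correlation undefined for a constant series")
    r = float(stats.pearsonr(a, b).statistic)
    if abs(r) >= 1.0:
        return r, r, r
    z = math.atanh(r)
    half = 1.959963984540054 / math.sqrt(pair.n - 3)
    return r, math.tanh(z - half), math.tanh(z + half)


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa between two 3-category classifications.

    ``degenerate`` is set (and kappa/CI are None) when expected agreement is
    1, i.e. both raters are constant and identical, leaving kappa undefined.
    """

    contingency: np.ndarray
    n: int
    kappa: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "kappa": self.kappa,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "degenerate": self.degenerate,
            "contingency": self.contingency.tolist(),
        }


def cohen_kappa(
    class_a: Sequence[RatioClass],
    class_b: Sequence[RatioClass],
    categories: Sequence[RatioClass] = RATIO_CLASSES,
) -> KappaResult:
    """Unweighted kappa (p_o - p_e) / (1 - p_e) with an asymptotic 95% CI.

    The CI uses the Fleiss-Cohen-Everitt large-sample standard error and a
    1.96 multiplier, truncated to [-1, 1].
    """
    if len(class_a) != len(class_b):
        raise AgreementError("classification series must have equal length")
    n = len(class_a)
    if n < 1:
        raise AgreementError("need at least one paired classification")
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((k, k), dtype=int)
    for ca, cb in zip(class_a, class_b):
        table[index[ca], index[cb]] += 1

    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(np.dot(row, col))
    if pe >= 1.0 - 1e-15:
        return KappaResult(contingency=table, n=n, kappa=None, ci_low=None, ci_high=None,
                           degenerate=True)
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt (1969) large-sample variance of kappa-hat.
    one_minus_k = 1.0 - kappa
    term1 = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * one_minus_k) ** 2 for i in range(k)
    )
    term2 = one_minus_k**2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    term3 = (kappa - pe * one_minus_k) ** 2
    var = (term1 + term2 - term3) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    return KappaResult(
        contingency=table,
        n=n,
        kappa=float(kappa),
        ci_low=max(-1.0, kappa - 1.96 * se),
        ci_high=min(1.0, kappa + 1.96 * se),
        degenerate=False,
    )


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one method pair (comparator vs reference)."""

    label_ref: str
    label_method: str
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    percentage_error: float
    acceptable: bool
    pearson_r: Optional[float]
    r_ci_low: Optional[float]
    r_ci_high: Optional[float]
    class_counts: Dict[RatioClass, int]
    class_proportions: Dict[RatioClass, float]

    def to_dict(self) -> dict:
        return {
            "reference": self.label_ref,
            "method": self.label_method,
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "percentage_error": self.percentage_error,
            "acceptable": self.acceptable,
            "pearson_r": self.pearson_r,
            "r_ci_low": self.r_ci_low,
            "r_ci_high": self.r_ci_high,
            "class_counts": {c.value: v for c, v in self.class_counts.items()},
            "class_proportions": {c.value: v for c, v in self.class_proportions.items()},
        }


def agreement_report(pair: MethodPair, pe_multiplier: float = 1.96) -> AgreementReport:
    """Assemble Bland-Altman, percentage error, correlation and ratio classes
    for one pair."""
    ba = bland_altman(pair)
    pe = percentage_error(pair, pe_multiplier)
    try:
        r, lo, hi = pearson_with_ci(pair)
    except AgreementError:
        r = lo = hi = None
    classes = ratio_classes(pair)
    counts = {c: sum(x is c for x in classes) for c in RATIO_CLASSES}
    props = {c: counts[c] / pair.n for c in RATIO_CLASSES}
    return AgreementReport(
        label_ref=pair.label_a,
        label_method=pair.label_b,
        n=pair.n,
        mean_diff=ba.mean_diff,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        percentage_error=pe,
        acceptable=pe < ACCEPTABLE_PE_PERCENT,
        pearson_r=r,
        r_ci_low=lo,
        r_ci_high=hi,
        class_counts=counts,
        class_proportions=props,
    )


def _quartile_row(values: np.ndarray) -> dict:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    return {
        "n": int(values.size),
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }


@dataclass
class StudyReport:
    """Everything the pipeline computes for one cohort.

    ``vs_reference`` holds one AgreementReport per formula against the
    reference CO; ``vs_krakau`` one per non-Krakau formula against the
    Krakau-Fick CO; ``kappa_vs_krakau`` compares each formula's ratio
    classification (vs reference) with Krakau's. Comparisons lacking two
    pair-complete patients are recorded as unavailable (None).
    """

    reference_label: str
    pe_multiplier: float
    n_patients: int
    vs_reference: Dict[Formula, Optional[AgreementReport]] = field(default_factory=dict)
    vs_krakau: Dict[Formula, Optional[AgreementReport]] = field(default_factory=dict)
    kappa_vs_krakau: Dict[Formula, Optional[KappaResult]] = field(default_factory=dict)
    method_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    bland_altman_data: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_label,
            "pe_multiplier": self.pe_multiplier,
            "n_patients": self.n_patients,
            "vs_reference": {
                f.value: (r.to_dict() if r is not None else None)
                for f, r in self.vs_reference.items()
            },
            "vs_krakau": {
                f.value: (r.to_dict() if r is not None else None)
                for f, r in self.vs_krakau.items()
            },
            "kappa_vs_krakau": {
                f.value: (k.to_dict() if k is not None else None)
                for f, k in self.kappa_vs_krakau.items()
            },
            "method_summary": self.method_summary.to_dict(orient="records"),
        }


def _column(derived: Sequence[HemoDerived], getter) -> np.ndarray:
    return np.array(
        [np.nan if (v := getter(d)) is None else v for d in derived], dtype=float
    )


def compare_all(
    derived: Sequence[HemoDerived],
    pe_multiplier: float = 1.96,
    formulas: Sequence[Formula] = FORMULAS,
    reference_label: str = "td",
) -> StudyReport:
    """Run the full comparison battery on a derived cohort.

    Produces, for each requested formula: an agreement report vs the
    reference CO; for each non-Krakau formula an agreement report vs the
    Krakau-Fick CO; kappa between the Krakau classification and each other
    formula's classification; and median/quartile summaries of CO, CI and
    VO2 per method.
    """
    formulas = [Formula(f) for f in formulas]
    ids = np.array([d.patient_id for d in derived], dtype=object)
    td = _column(derived, lambda d: d.td_co)
    co = {f: _column(derived, lambda d, f=f: d.ifm_co.get(f)) for f in formulas}

    report = StudyReport(
        reference_label=reference_label,
        pe_multiplier=pe_multiplier,
        n_patients=len(derived),
    )

    for f in formulas:
        pair = MethodPair.from_series(reference_label, td, f.value, co[f], ids=ids)
        if pair.n < 2:
            report.vs_reference[f] = None
            continue
        report.vs_reference[f] = agreement_report(pair, pe_multiplier)
        report.bland_altman_data[f"{reference_label}_vs_{f.value}"] = pd.DataFrame(
            {
                "patient_id": list(pair.ids),
                "mean": bland_altman(pair).means,
                "diff": bland_altman(pair).diffs,
            }
        )

    if Formula.KRAKAU in formulas:
        for f in formulas:
            if f is Formula.KRAKAU:
                continue
            pair = MethodPair.from_series(
                Formula.KRAKAU.value, co[Formula.KRAKAU], f.value, co[f], ids=ids
            )
            if pair.n < 2:
                report.vs_krakau[f] = None
                continue
            report.vs_krakau[f] = agreement_report(pair, pe_multiplier)
            ba = bland_altman(pair)
            report.bland_altman_data[f"krakau_vs_{f.value}"] = pd.DataFrame(
                {"patient_id": list(pair.ids), "mean": ba.means, "diff": ba.diffs}
            )

        # Kappa: each formula's ratio classification vs the reference against
        # Krakau's, restricted to rows where reference, Krakau and the other
        # formula are all present.
        for f in formulas:
            if f is Formula.KRAKAU:
                continue
            mask = np.isfinite(td) & np.isfinite(co[Formula.KRAKAU]) & np.isfinite(co[f])
            if mask.sum() < 1:
                report.kappa_vs_krakau[f] = None
                continue
            cls_k = [classify_ratio(x, r) for x, r in zip(co[Formula.KRAKAU][mask], td[mask])]
            cls_f = [classify_ratio(x, r) for x, r in zip(co[f][mask], td[mask])]
            report.kappa_vs_krakau[f] = cohen_kappa(cls_k, cls_f)

    rows = []
    td_ci = _column(derived, lambda d: d.td_ci)
    rows.append({"method": reference_label, "quantity": "co", **_quartile_row(td)})
    rows.append({"method": reference_label, "quantity": "ci", **_quartile_row(td_ci)})
    for f in formulas:
        rows.append({"method": f.value, "quantity": "co", **_quartile_row(co[f])})
        ci = _column(derived, lambda d, f=f: d.ifm_ci.get(f))
        vo2 = _column(derived, lambda d, f=f: d.vo2.get(f))
        rows.append({"method": f.value, "quantity": "ci", **_quartile_row(ci)})
        rows.append({"method": f.value, "quantity": "vo2", **_quartile_row(vo2)})
    report.method_summary = pd.DataFrame(rows)
    return report
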