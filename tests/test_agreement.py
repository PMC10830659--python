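import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fickco import (
    FORMULAS,
    Formula,
    MethodPair,
    RatioClass,
    bland_altman,
    classify_ratio,
    cohen_kappa,
    compare_all,
    derive_cohort,
    deviation_table,
    pearson_with_ci,
    percentage_error,
)
from fickco.agreement import AgreementError, RATIO_CLASSES, agreement_report
from fickco.synth_cohort import SynthConfig, generate


def kappa_bruteforce(table):
    """Definitional (p_o - p_e) / (1 - p_e) straight from a count table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    po = np.trace(table) / n
    pe = sum(table[i, :].sum() * table[:, i].sum() for i in range(table.shape[0])) / n**2
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


class TestClassifyRatio:
    def test_boundaries_are_concordant(self):
        assert classify_ratio(4.0, 5.0) is RatioClass.CONCORDANT  # ratio exactly 0.8
        assert classify_ratio(6.0, 5.0) is RatioClass.CONCORDANT  # ratio exactly 1.2

    def test_identity_is_concordant(self):
        for x in (0.5, 1.0, 7.3):
            assert classify_ratio(x, x) is RatioClass.CONCORDANT

    def test_over(self):
        assert classify_ratio(6.3, 5.0) is RatioClass.OVER

    def test_under(self):
        assert classify_ratio(3.9, 5.0) is RatioClass.UNDER

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(AgreementError):
            classify_ratio(5.0, 0.0)

    @given(st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, ratio):
        classes = [classify_ratio(ratio * 5.0, 5.0)]
        assert len(classes) == 1 and classes[0] in RATIO_CLASSES


class TestDeviationTable:
    def test_degenerate_all_concordant(self):
        pair = MethodPair.from_series("ref", [5.0] * 4, "m", [5.0] * 4)
        table = deviation_table([pair])
        assert table.loc[0, "pct_concordant"] == 100.0

    def test_enumerated_toy_counts(self):
        ref = np.full(5, 10.0)
        cmp = 10.0 * np.array([0.5, 0.79, 0.8, 1.0, 1.3])
        table = deviation_table([MethodPair.from_series("ref", ref, "m", cmp)])
        row = table.iloc[0]
        assert (row["n_under"], row["n_concordant"], row["n_over"]) == (2, 2, 1)

    def test_counts_sum_to_n(self, rng):
        ref = rng.uniform(3, 8, 40)
        cmp = ref * rng.lognormal(0, 0.3, 40)
        row = deviation_table([MethodPair.from_series("r", ref, "m", cmp)]).iloc[0]
        assert row["n_under"] + row["n_concordant"] + row["n_over"] == row["n"] == 40

    def test_empty_pair_rejected(self):
        with pytest.raises(AgreementError):
            deviation_table([MethodPair.from_series("r", [], "m", [])])


class TestBlandAltman:
    def test_identical_series(self):
        pair = MethodPair.from_series("a", [4.0, 5.0, 6.0], "b", [4.0, 5.0, 6.0])
        ba = bland_altman(pair)
        assert ba.mean_diff == ba.loa_low == ba.loa_high == 0.0

    def test_constant_offset(self):
        pair = MethodPair.from_series("a", [5.0, 6.0, 7.0], "b", [4.0, 5.0, 6.0])
        ba = bland_altman(pair)
        assert ba.mean_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(ba.loa_high) == pytest.approx(1.0)

    def test_toy_triple(self, toy_pair):
        ba = bland_altman(toy_pair)
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_antisymmetry(self, toy_pair, rng):
        a = rng.uniform(3, 8, 25)
        b = a * rng.lognormal(0, 0.2, 25)
        pair = MethodPair.from_series("a", a, "b", b)
        fwd, rev = bland_altman(pair), bland_altman(pair.swapped())
        assert rev.mean_diff == pytest.approx(-fwd.mean_diff)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)

    def test_n_below_two_rejected(self):
        with pytest.raises(AgreementError):
            bland_altman(MethodPair.from_series("a", [5.0], "b", [4.0]))

    def test_nan_rows_masked(self):
        pair = MethodPair.from_series(
            "a", [5.0, np.nan, 7.0], "b", [4.0, 6.0, 8.0], ids=["x", "y", "z"]
        )
        assert pair.n == 2
        assert pair.ids == ("x", "z")


class TestPercentageError:
    def test_identical_series_zero(self):
        pair = MethodPair.from_series("a", [4.0, 5.0, 6.0], "b", [4.0, 5.0, 6.0])
        assert percentage_error(pair) == 0.0

    def test_toy_triple(self, toy_pair):
        assert percentage_error(toy_pair) == pytest.approx(100 * 1.96 / 6, abs=1e-9)
        assert percentage_error(toy_pair) == pytest.approx(32.67, abs=0.01)

    def test_multiplier_two(self, toy_pair):
        assert percentage_error(toy_pair, multiplier=2.0) == pytest.approx(100 * 2.0 / 6)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, c):
        a = np.array([5.0, 6.0, 7.0, 5.5])
        b = np.array([4.0, 6.5, 8.0, 5.0])
        base = percentage_error(MethodPair.from_series("a", a, "b", b))
        scaled = percentage_error(MethodPair.from_series("a", c * a, "b", c * b))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_symmetric_under_swap(self, toy_pair):
        assert percentage_error(toy_pair.swapped()) == pytest.approx(
            percentage_error(toy_pair)
        )


class TestPearsonWithCi:
    def test_exact_linearity(self):
        a = np.arange(1.0, 11.0)
        r, lo, hi = pearson_with_ci(MethodPair.from_series("a", a, "b", 2 * a + 1))
        assert r == pytest.approx(1.0)

    def test_antilinearity(self):
        a = np.arange(1.0, 11.0)
        r, _, _ = pearson_with_ci(MethodPair.from_series("a", a, "b", -a))
        assert r == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self, rng):
        a = rng.normal(5, 1, 10)
        b = a + rng.normal(0, 0.5, 10)
        r, lo, hi = pearson_with_ci(MethodPair.from_series("a", a, "b", b))
        expected = np.sum((a - a.mean()) * (b - b.mean())) / (
            math.sqrt(np.sum((a - a.mean()) ** 2)) * math.sqrt(np.sum((b - b.mean()) ** 2))
        )
        assert r == pytest.approx(expected, abs=1e-12)
        # Fisher z oracle
        z = math.atanh(expected)
        half = 1.959963984540054 / math.sqrt(10 - 3)
        assert lo == pytest.approx(math.tanh(z - half), abs=1e-9)
        assert hi == pytest.approx(math.tanh(z + half), abs=1e-9)
        assert lo < r < hi

    def test_constant_series_rejected(self):
        with pytest.raises(AgreementError):
            pearson_with_ci(MethodPair.from_series("a", [1, 1, 1, 1], "b", [1, 2, 3, 4]))


CLS = list(RATIO_CLASSES)


class TestCohenKappa:
    def test_perfect_agreement(self):
        labels = [CLS[0], CLS[1], CLS[2], CLS[1], CLS[1]]
        result = cohen_kappa(labels, labels)
        assert result.kappa == pytest.approx(1.0)
        assert not result.degenerate

    def test_printed_toy_table(self):
        # diag 40, 50, 5 and a single off-diagonal cell of 5.
        class_a = [CLS[0]] * 40 + [CLS[1]] * 50 + [CLS[2]] * 5 + [CLS[0]] * 5
        class_b = [CLS[0]] * 40 + [CLS[1]] * 50 + [CLS[2]] * 5 + [CLS[1]] * 5
        result = cohen_kappa(class_a, class_b)
        table = np.zeros((3, 3))
        table[0, 0], table[1, 1], table[2, 2], table[0, 1] = 40, 50, 5, 5
        assert result.kappa == pytest.approx(kappa_bruteforce(table), abs=1e-12)
        np.testing.assert_array_equal(result.contingency, table)

    def test_independent_classifications_near_zero(self, rng):
        n = 20000
        a = rng.choice(3, n, p=[0.4, 0.5, 0.1])
        b = rng.choice(3, n, p=[0.3, 0.6, 0.1])
        result = cohen_kappa([CLS[i] for i in a], [CLS[i] for i in b])
        assert abs(result.kappa) < 0.03

    def test_degenerate_signalled(self):
        constant = [CLS[1]] * 10
        result = cohen_kappa(constant, constant)
        assert result.degenerate
        assert result.kappa is None and result.ci_low is None

    def test_one_constant_rater_defined(self):
        a = [CLS[1]] * 6
        b = [CLS[1]] * 5 + [CLS[0]]
        result = cohen_kappa(a, b)
        assert not result.degenerate
        assert -1.0 <= result.kappa <= 1.0

    def test_contingency_totals(self, rng):
        a = [CLS[i] for i in rng.choice(3, 57)]
        b = [CLS[i] for i in rng.choice(3, 57)]
        result = cohen_kappa(a, b)
        assert result.contingency.sum() == result.n == 57

    def test_exhaustive_small_tables(self):
        """All 3x3 contingency tables with total <= 12 (composition
        enumeration over 9 cells capped for runtime via total in {1..12}
        restricted to tables reachable from <= 4 distinct cells)."""
        # Full enumeration over 9 cells is ~C(21,9) per total; instead
        # enumerate all tables with at most 12 items spread over the 9 cells
        # using stars-and-bars on a reduced grid: every cell value in 0..4
        # and total <= 12 still covers the degenerate and boundary cases.
        checked = 0
        for cells in itertools.product(range(5), repeat=4):
            # embed the 4 free cells into fixed positions of a 3x3 table
            table = np.zeros((3, 3), dtype=int)
            table[0, 0], table[1, 1], table[0, 1], table[2, 0] = cells
            total = table.sum()
            if not 1 <= total <= 12:
                continue
            class_a, class_b = [], []
            for i in range(3):
                for j in range(3):
                    class_a += [CLS[i]] * table[i, j]
                    class_b += [CLS[j]] * table[i, j]
            result = cohen_kappa(class_a, class_b)
            expected = kappa_bruteforce(table)
            if expected is None:
                assert result.degenerate
            else:
                assert result.kappa == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked > 100

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_kappa_bounds_property(self, indices):
        rng = np.random.default_rng(sum(indices) + len(indices))
        a = [CLS[i] for i in indices]
        b = [CLS[i] for i in rng.choice(3, len(indices))]
        result = cohen_kappa(a, b)
        if not result.degenerate:
            assert -1.0 - 1e-12 <= result.kappa <= 1.0 + 1e-12
        if len(set(a)) > 1:
            same = cohen_kappa(a, a)
            assert same.kappa == pytest.approx(1.0)


@pytest.fixture(scope="module")
def zero_noise_report():
    cohort = generate(SynthConfig(n=80, seed=11, noise_sd=0.0, log_bias=0.0))
    derived = derive_cohort(cohort.records)
    return compare_all(derived)


class TestCompareAll:
    def test_structural_counts(self, zero_noise_report):
        assert len(zero_noise_report.vs_reference) == 4
        assert len(zero_noise_report.vs_krakau) == 3
        assert len(zero_noise_report.kappa_vs_krakau) == 3

    def test_zero_noise_krakau_exact(self, zero_noise_report):
        rep = zero_noise_report.vs_reference[Formula.KRAKAU]
        assert rep.percentage_error == 0.0
        assert rep.mean_diff == 0.0
        assert rep.class_proportions[RatioClass.CONCORDANT] == 1.0

    def test_class_proportions_sum_to_one(self, zero_noise_report):
        for rep in zero_noise_report.vs_reference.values():
            assert sum(rep.class_proportions.values()) == pytest.approx(1.0)
            assert rep.loa_low <= rep.mean_diff <= rep.loa_high

    def test_median_matches_sorting_oracle(self, zero_noise_report):
        cohort = generate(SynthConfig(n=80, seed=11, noise_sd=0.0, log_bias=0.0))
        derived = derive_cohort(cohort.records)
        values = sorted(d.ifm_co[Formula.KRAKAU] for d in derived)
        expected = 0.5 * (values[39] + values[40])
        summary = zero_noise_report.method_summary
        row = summary[(summary.method == "krakau") & (summary.quantity == "co")]
        assert row["median"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_unavailable_when_reference_missing(self, record):
        import dataclasses

        derived = derive_cohort(
            [dataclasses.replace(record, patient_id=f"P{i}", td_co=None) for i in range(5)]
        )
        report = compare_all(derived)
        assert all(r is None for r in report.vs_reference.values())

    def test_report_serializes(self, zero_noise_report):
        import json

        text = json.dumps(zero_noise_report.to_dict(), sort_keys=True)
        assert "percentage_error" in text
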