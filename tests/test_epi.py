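"""Incidence arithmetic, population inference, rates and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from neoscreen.epi import (
    CannotInferError,
    CaseRow,
    class_incidence,
    compare_groups,
    group_incidence,
    incidence_denominator,
    infer_population,
    minority_implied_population,
    per_disorder_incidence,
    rate_percent,
    share_within_class,
    yearly_frequencies,
)
from neoscreen.rounding import format_one_in_n, round_half_up


class TestIncidenceDenominator:
    @pytest.mark.parametrize("population, n_cases, expected", [
        (206_977, 69, 3_000),
        (206_977, 2, 103_489),   # 103,488.5 rounds half-up
        (206_977, 29, 7_137),
        (206_977, 9, 22_997),
        (100, 100, 1),
    ])
    def test_examples(self, population, n_cases, expected):
        assert incidence_denominator(population, n_cases) == expected

    def test_zero_cases_is_undefined(self):
        assert incidence_denominator(206_977, 0) is None

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.integers(1, 10_000_000), st.data())
    def test_against_integer_oracle(self, pop, data):
        """Half-up rounding cross-checked against an exact integer-arithmetic
        oracle: N = (2*population + cases) // (2*cases)."""
        n_cases = data.draw(st.integers(1, pop))
        assert incidence_denominator(pop, n_cases) == (2 * pop + n_cases) // (2 * n_cases)

    def test_formatting(self):
        assert format_one_in_n(3_000) == "1:3,000"
        assert format_one_in_n(103_489) == "1:103,489"


class TestFixtureRegression:
    def test_every_printed_per_disorder_denominator(self, cases):
        expected = {
            "PAHD": 22_997, "BH4D": 103_489, "MSUD": 206_977, "MET": 206_977,
            "2MBG": 7_137, "MMA": 103_489, "3MCC": 206_977, "HCSD": 206_977,
            "IVA": 206_977, "GA-I": 206_977, "IBDD": 206_977,
            "PCD": 34_496, "SCADD": 51_744, "VLCADD": 103_489, "BKD": 206_977,
            "MCADD": 206_977, "CD": 34_496,
        }
        assert per_disorder_incidence(cases) == expected
        assert incidence_denominator(206_977, cases.total_cases) == 3_000

    def test_class_incidences(self, cases):
        assert class_incidence(cases) == {
            "AAMD": 15_921, "OAMD": 5_749, "FAOD": 14_784, "UCD": 34_496}

    def test_class_totals(self, cases):
        assert cases.class_cases("AAMD") == 13
        assert cases.class_cases("OAMD") == 36
        assert cases.class_cases("FAOD") == 14
        assert cases.class_cases("UCD") == 6

    @pytest.mark.parametrize("disorder, expected", [
        ("2MBG", 80.56), ("PAHD", 69.23), ("PCD", 42.86)])
    def test_share_within_class(self, cases, disorder, expected):
        assert share_within_class(cases, disorder) == expected

    def test_yearly_frequencies(self, yearly):
        assert yearly_frequencies(yearly) == {
            2015: 7_473, 2016: 4_003, 2017: 2_949, 2018: 6_028,
            2019: 2_170, 2020: 3_038, 2021: 1_710}


class TestPopulationInference:
    def test_han_via_mcadd_anchor(self, cases):
        assert infer_population(cases, "Han") == 128_004

    def test_miao_via_bkd_anchor(self, cases):
        assert infer_population(cases, "Miao") == 32_237

    def test_dong_has_no_anchor(self, cases):
        with pytest.raises(CannotInferError):
            infer_population(cases, "Dong")

    @pytest.mark.parametrize("group, expected", [
        ("Han", 4_741), ("Miao", 1_612), ("Tujia", 2_005), ("Yao", 1_769)])
    def test_group_incidences(self, cases, group, expected):
        assert group_incidence(cases, group) == expected

    def test_group_cases_sums(self, cases):
        assert cases.group_cases("Han") == 27
        assert cases.group_cases("Miao") == 20
        assert cases.total_cases == 69

    def test_inferred_populations_internally_consistent(self, cases):
        """Inferred sub-populations fit inside the screened total, and the
        minority total implied by the printed 1:1,852 leaves a positive
        residual for the Dong group."""
        inferable = {g: infer_population(cases, g) for g in ("Han", "Miao", "Tujia", "Yao")}
        assert sum(inferable.values()) <= 206_977
        minority_total = minority_implied_population(cases)
        assert minority_total == 42 * 1_852
        dong_residual = minority_total - inferable["Miao"] - inferable["Tujia"] - inferable["Yao"]
        assert dong_residual > 0

    def test_degenerate_equal_population_and_cases(self):
        row = CaseRow("X", "AAMD", {"Han": 5, "Miao": 0, "Dong": 0, "Tujia": 0, "Yao": 0}, 5)
        from neoscreen.epi import CaseCountTable
        table = CaseCountTable((row,))
        assert group_incidence(table, "Han", population=5) == 1


class TestRates:
    @pytest.mark.parametrize("num, den, expected", [
        (5_578, 206_977, 2.69),
        (4_085, 5_578, 73.23),
        (203_708, 206_977, 98.42),
        (69, 297, 23.23),
    ])
    def test_printed_rates(self, num, den, expected):
        assert rate_percent(num, den) == expected

    def test_half_up_at_final_step(self):
        assert round_half_up(80.555, 2) == 80.56
        assert round_half_up(103_488.5) == 103_489.0


class TestCompareGroups:
    def test_perfect_independence(self):
        res = compare_groups([[50, 50], [50, 50]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_margin_is_undefined(self):
        res = compare_groups([[0, 0], [10, 20]])
        assert res.statistic is None and res.p_value is None

    def test_chi_square_matches_permutation_oracle(self):
        """Asymptotic chi-square p agrees with a conditional permutation oracle
        (hypergeometric resampling of the 2x2 table, 10^5 resamples)."""
        table = np.array([[120, 80], [90, 110]])
        res = compare_groups(table)

        n = table.sum()
        row1, col1 = table[0].sum(), table[:, 0].sum()
        rng = np.random.default_rng(2024)
        a = rng.hypergeometric(col1, n - col1, row1, size=100_000)

        def stat(a_cells):
            b = row1 - a_cells
            c = col1 - a_cells
            d = n - row1 - c
            num = n * (a_cells * d - b * c) ** 2
            den = row1 * (n - row1) * col1 * (n - col1)
            return num / den

        p_perm = np.mean(stat(a.astype(float)) >= stat(float(table[0, 0])) - 1e-12)
        assert res.p_value == pytest.approx(p_perm, abs=0.01)

    def test_identical_samples_give_zero_f(self):
        res = compare_groups([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]], kind="samples")
        assert res.method == "one-way ANOVA"
        assert res.statistic == pytest.approx(0.0)

    def test_anova_matches_scipy_on_unequal_groups(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 1, 25), rng.normal(0, 1, 40)]
        res = compare_groups(groups, kind="samples")
        f, p = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)
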