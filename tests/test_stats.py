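import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy import stats as scipy_stats

from psirr.stats import (
    ContingencyTable,
    SMRInput,
    UndefinedStatisticError,
    chi_square_uncorrected,
    chi_square_yates,
    critical_value,
    expected_deaths,
    odds_ratio,
    poisson_tail_p,
    relative_risk,
    smr,
    smr_z,
    stratified_rr,
    z_statistic,
)
from conftest import MEN_CELLS, MEN_EXPECTED, WOMEN_CELLS, WOMEN_EXPECTED

MEN_T = ContingencyTable(25, 7865, 79, 13915)

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def yates_cell_sum_oracle(t: ContingencyTable) -> float:
    """Independent four-cell sum of (|O_i - E_i| - 1/2)^2 / E_i."""
    total = 0.0
    observed = [[t.a, t.b], [t.c, t.d]]
    rows, cols = [t.n1, t.n2], [t.m1, t.m2]
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / t.N
            total += max(abs(observed[i][j] - e) - 0.5, 0.0) ** 2 / e
    return total


class TestContingencyTable:
    def test_margins(self):
        assert (MEN_T.n1, MEN_T.n2, MEN_T.m1, MEN_T.m2) == (7890, 13994, 104, 21780)
        assert MEN_T.N == 21884

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestRelativeRisk:
    def test_mens_third_class(self):
        assert round(relative_risk(MEN_T), 2) == 0.56

    def test_womens_third_class(self):
        assert round(relative_risk(ContingencyTable(32, 10283, 40, 14347)), 2) == 1.12

    def test_equal_risks_give_one(self):
        assert relative_risk(ContingencyTable(10, 90, 20, 180)) == pytest.approx(1.0)

    def test_undefined_cases(self):
        with pytest.raises(UndefinedStatisticError):
            relative_risk(ContingencyTable(1, 1, 0, 5))
        with pytest.raises(UndefinedStatisticError):
            relative_risk(ContingencyTable(0, 0, 3, 5))


class TestOddsRatio:
    def test_unit_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_hand_arithmetic(self):
        assert odds_ratio(ContingencyTable(2, 3, 5, 7)) == pytest.approx(14 / 15)

    def test_rare_disease_agreement_with_rr(self):
        assert abs(odds_ratio(MEN_T) - relative_risk(MEN_T)) < 0.01

    def test_zero_denominator(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(ContingencyTable(1, 0, 1, 1))

    @settings(max_examples=200, deadline=None)
    @given(tables)
    def test_rarity_implies_agreement(self, t):
        if t.a < 0.01 * t.n1 and t.c < 0.01 * t.n2:
            rr, orr = relative_risk(t), odds_ratio(t)
            assert abs(orr - rr) / rr < 0.01


class TestChiSquare:
    def test_mens_third_class_uncorrected(self):
        assert round(chi_square_uncorrected(MEN_T), 2) == 6.54

    def test_mens_second_class_uncorrected(self):
        assert round(chi_square_uncorrected(ContingencyTable(36, 8229, 79, 13915)), 2) == 1.68

    def test_independence_gives_zero(self):
        t = ContingencyTable(10, 20, 30, 60)  # ad == bc
        assert chi_square_uncorrected(t) == 0.0
        assert chi_square_yates(t) == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            chi_square_uncorrected(ContingencyTable(0, 5, 0, 5))

    def test_yates_floor_rule(self):
        # |ad - bc| = 1 < N/2 = 2.5 -> floored to zero
        assert chi_square_yates(ContingencyTable(1, 1, 1, 2)) == 0.0

    def test_yates_closed_form_equals_cell_sum_on_fixed_cells(self):
        assert chi_square_yates(MEN_T) == pytest.approx(
            yates_cell_sum_oracle(MEN_T), rel=1e-9
        )

    @settings(max_examples=1000, deadline=None)
    @given(tables)
    def test_yates_closed_form_equals_cell_sum(self, t):
        closed = chi_square_yates(t)
        oracle = yates_cell_sum_oracle(t)
        assert closed == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(tables)
    def test_non_negative(self, t):
        assert chi_square_uncorrected(t) >= 0.0
        assert chi_square_yates(t) >= 0.0

    def test_type_one_error_rate_under_null(self):
        # equal class risks; uncorrected statistic at 3.84 rejects ~5%
        rng = np.random.default_rng(2024)
        reps, n1, n2, p = 10_000, 2000, 3000, 0.1
        a = rng.binomial(n1, p, size=reps).astype(np.int64)
        c = rng.binomial(n2, p, size=reps).astype(np.int64)
        b, d = n1 - a, n2 - c
        N = n1 + n2
        chi2 = N * (a * d - b * c) ** 2.0 / (n1 * n2 * (a + c) * (b + d))
        rate = float((chi2 > 3.84).mean())
        assert 0.04 <= rate <= 0.06


class TestZStatistic:
    def test_literal_minus_sign_cancels(self):
        # ad - bc = +N/2 with the minus sign applied literally -> 0
        t = ContingencyTable(2, 1, 1, 2)  # ad - bc = 3 = N/2
        assert z_statistic(t, correction_sign=-1) == 0.0

    def test_mens_third_class_exceeds_normal_critical(self):
        assert abs(z_statistic(MEN_T)) > 1.960

    def test_identity_with_yates_chi_square(self):
        for t in (MEN_T, ContingencyTable(7, 11, 13, 17)):
            z = z_statistic(t)
            expected = chi_square_yates(t) * (t.N - 1) / t.N
            assert z * z == pytest.approx(expected, rel=1e-9)

    def test_invalid_sign(self):
        with pytest.raises(ValueError):
            z_statistic(MEN_T, correction_sign=2)


class TestCriticalValue:
    def test_chi2_upper_five_percent(self):
        assert round(critical_value("chi2_1df", 0.05), 2) == 3.84

    def test_normal_two_sided_five_percent(self):
        assert round(critical_value("normal_two_sided", 0.05), 3) == 1.960

    def test_numeric_inversion_oracle(self):
        # brute-force root of CDF(x) - 0.5 = 0, independent of .ppf
        got = critical_value("chi2_1df", 0.5)
        oracle = optimize.brentq(
            lambda x: scipy_stats.chi2.cdf(x, df=1) - 0.5, 1e-9, 100.0, xtol=1e-10
        )
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_alpha_domain(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                critical_value("chi2_1df", bad)


class TestStratified:
    def test_mens_table(self):
        counts = [(label, *MEN_CELLS[label]) for label in ("L", "S", "T", "H")]
        result = stratified_rr(counts, "L")
        for label, (rr, chi2) in MEN_EXPECTED.items():
            row = result.row(label)
            assert round(row.rr, 2) == rr
            if chi2 is None:
                assert row.chi2 is None and row.is_reference
            else:
                assert round(row.chi2, 2) == chi2

    def test_womens_table(self):
        counts = [(label, *WOMEN_CELLS[label]) for label in ("L", "S", "T", "H")]
        result = stratified_rr(counts, "L")
        for label, (rr, _) in WOMEN_EXPECTED.items():
            assert round(result.row(label).rr, 2) == rr

    def test_womens_chi2(self):
        counts = [(label, *WOMEN_CELLS[label]) for label in ("L", "S", "T", "H")]
        result = stratified_rr(counts, "L")
        for label, (_, chi2) in WOMEN_EXPECTED.items():
            if chi2 is not None:
                assert round(result.row(label).chi2, 2) == chi2

    def test_single_reference_class(self):
        result = stratified_rr([("L", 5, 95)], "L")
        assert len(result.rows) == 1
        assert result.rows[0].rr == 1.0

    def test_missing_reference(self):
        with pytest.raises(ValueError):
            stratified_rr([("A", 1, 2)], "Z")

    def test_reference_without_cases(self):
        with pytest.raises(UndefinedStatisticError):
            stratified_rr([("L", 0, 10), ("S", 1, 9)], "L")


class TestSMR:
    def test_expected_deaths(self):
        assert expected_deaths([(0, 0.01, 1000)]) == pytest.approx(10.0)
        assert expected_deaths([(0, 0.01, 1000), (0, 0.02, 500)]) == pytest.approx(20.0)
        assert expected_deaths([(0, 0.0, 1000), (0, 0.0, 50)]) == 0.0

    def test_smr_input_aggregates(self):
        smr_in = SMRInput([(3, 0.01, 1000), (7, 0.02, 500)])
        assert smr_in.observed == 10
        assert smr_in.expected == pytest.approx(20.0)

    def test_smr_values(self):
        assert smr(10, 10) == 1.0
        assert smr(15, 10) == 1.5
        with pytest.raises(UndefinedStatisticError):
            smr(1, 0)

    def test_smr_mean_one_under_null(self):
        rng = np.random.default_rng(11)
        E = 25.0
        O = rng.poisson(E, size=10_000)
        assert np.mean(O / E) == pytest.approx(1.0, abs=0.02)


class TestPoissonTail:
    def test_zero_observed(self):
        assert poisson_tail_p(0, 3.0) == 1.0

    def test_hand_evaluated_sum(self):
        expected = 1 - math.exp(-1) * (1 + 1 + 0.5)
        assert poisson_tail_p(3, 1.0) == pytest.approx(expected, abs=1e-12)
        assert round(poisson_tail_p(3, 1.0), 4) == 0.0803

    def test_brute_force_summation_oracle(self):
        for O in range(0, 51, 5):
            for E in (0.5, 1.0, 5.0, 12.5, 30.0):
                brute = 1.0 - sum(
                    math.exp(-E) * E**j / math.factorial(j) for j in range(O)
                )
                assert poisson_tail_p(O, E) == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_observed(self):
        ps = [poisson_tail_p(O, 7.0) for O in range(0, 40)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))
        assert ps[-1] < 1e-12

    def test_domain(self):
        with pytest.raises(ValueError):
            poisson_tail_p(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_tail_p(3, 0.0)


class TestSMRZ:
    def test_zero_statistic_one_sided(self):
        res = smr_z(21, 20.5, sided="one")
        assert res.statistic == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        res = smr_z(30, 20.0, sided="two")
        assert round(res.statistic, 3) == 2.124
        assert res.reject  # 2.124 > 1.960

    def test_warning_below_validity(self):
        assert smr_z(3, 2.0).warning is not None
        assert smr_z(30, 20.0).warning is None

    def test_invalid_expected(self):
        with pytest.raises(UndefinedStatisticError):
            smr_z(3, 0.0)

    def test_normal_approximation_close_to_exact_poisson(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for E in np.linspace(20, 100, 30):
            O = int(rng.poisson(E))
            exact = poisson_tail_p(O, float(E))
            approx = smr_z(O, float(E), sided="one").p_value
            worst = max(worst, abs(exact - approx))
        assert worst < 0.02
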