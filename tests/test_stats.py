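"""Validation statistics: recoveries, Dixon Q, regression, EJCR, t/F tests,
critical values and the titration utility."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from mixcal.stats import (compare_with_official, critical_value, dixon_q_test,
                          ejcr, molar_mass, one_sample_t_vs_reference,
                          recovery_percent, regression_diagnostics,
                          summarize_recoveries, titration_equivalent)

# published validation column (PLS, first drug): recoveries in %
PLS_BUP_RECOVERIES = [99.87, 101.26, 100.36, 99.98, 99.5, 101.66, 99.29, 100.77]
# published MCR-ALS column for the second drug, containing a flagged outlier
MCR_DEX_RECOVERIES = [114.44, 102.71, 98.87, 101.43, 104.44, 101.55, 103.28, 102.46]


class TestRecovery:
    def test_worked_cell(self):
        assert recovery_percent(14.98, 15.00) == pytest.approx(99.87, abs=0.005)

    def test_exact_is_hundred(self):
        assert recovery_percent(7.31, 7.31) == pytest.approx(100.0)

    def test_zero_prediction(self):
        assert recovery_percent(0.0, 10.0) == 0.0

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            recovery_percent(5.0, 0.0)


class TestSummaries:
    def test_published_column_mean_and_rsd(self):
        # the printed summary was computed from unrounded recoveries; the
        # 2-dp column reproduces it to one unit in the last digit
        s = summarize_recoveries(PLS_BUP_RECOVERIES, apply_q=False)
        assert s.mean_percent == pytest.approx(100.33, abs=0.01)
        assert s.rsd_percent == pytest.approx(0.83, abs=0.01)

    def test_constant_list_zero_rsd(self):
        s = summarize_recoveries([100.0] * 5)
        assert s.rsd_percent == 0.0

    def test_q_rejection_reflected_in_summary(self):
        s = summarize_recoveries(MCR_DEX_RECOVERIES, apply_q=True)
        assert s.rejected_indices == [0]
        assert s.n_used == 7

    def test_duplicate_extremes_gap_range_arithmetic(self):
        # gap/range oracle: (110-100)/(110-100) = 1.0, above any critical
        q = dixon_q_test([100.0, 100.0, 110.0])
        assert q.q_statistic == pytest.approx(1.0)
        assert q.rejected_value == 110.0

    def test_ordering_invariance(self):
        a = summarize_recoveries(MCR_DEX_RECOVERIES, apply_q=True)
        b = summarize_recoveries(MCR_DEX_RECOVERIES[::-1], apply_q=True)
        assert a.mean_percent == pytest.approx(b.mean_percent, abs=1e-12)
        assert a.rsd_percent == pytest.approx(b.rsd_percent, abs=1e-12)


class TestDixonQ:
    def test_published_outlier_rejected(self):
        res = dixon_q_test(MCR_DEX_RECOVERIES)
        # gap/range arithmetic on the printed values
        assert res.q_statistic == pytest.approx((114.44 - 104.44) / (114.44 - 98.87), abs=1e-12)
        assert res.q_statistic == pytest.approx(0.642, abs=5e-4)
        assert res.q_critical == 0.468
        assert res.rejected_value == 114.44

    def test_symmetric_small_sample_kept(self):
        res = dixon_q_test([1.0, 2.0, 3.0])
        assert res.q_statistic == pytest.approx(0.5)
        assert res.rejected_value is None

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            dixon_q_test([1.0, 2.0])
        with pytest.raises(ValueError):
            dixon_q_test(list(range(11)))


class TestRegressionDiagnostics:
    def test_identity_line(self):
        x = [5.0, 10, 15, 20, 25]
        d = regression_diagnostics(x, x)
        assert (d.slope, d.intercept, d.r, d.rmsec) == pytest.approx((1, 0, 1, 0), abs=1e-12)

    def test_affine_case(self):
        x = np.array([2.0, 4, 6, 8])
        d = regression_diagnostics(2 * x + 1, x)
        assert (d.slope, d.intercept, d.r) == pytest.approx((2, 1, 1), abs=1e-12)

    def test_against_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 25, size=10)
        y = 0.98 * x + 0.1 + rng.normal(0, 0.1, size=10)
        d = regression_diagnostics(y, x)
        X = np.column_stack([np.ones(10), x])
        b = np.linalg.solve(X.T @ X, X.T @ y)
        assert d.intercept == pytest.approx(b[0], abs=1e-10)
        assert d.slope == pytest.approx(b[1], abs=1e-10)

    def test_degenerate_nominals_rejected(self):
        with pytest.raises(ValueError):
            regression_diagnostics([1.0, 2, 3], [5.0, 5, 5])


class TestEjcr:
    def test_ideal_fit_contains_ideal_point(self):
        rng = np.random.default_rng(1)
        x = np.array([5.0, 8, 12, 15, 18, 21, 24, 25])
        y = x + 1e-9 * rng.normal(size=8)
        res = ejcr(y, x)
        assert res.contains_ideal
        assert res.slope == pytest.approx(1.0, abs=1e-6)
        assert res.intercept == pytest.approx(0.0, abs=1e-6)

    def test_biased_slope_excluded(self):
        rng = np.random.default_rng(2)
        x = np.array([5.0, 8, 12, 15, 18, 21, 24, 25])
        y = 1.1 * x + rng.normal(0, 0.01, size=8)
        assert not ejcr(y, x).contains_ideal

    def test_boundary_points_satisfy_quadratic_form(self):
        rng = np.random.default_rng(3)
        x = np.linspace(5, 25, 8)
        y = x + rng.normal(0, 0.1, size=8)
        res = ejcr(y, x)
        X = np.column_stack([np.ones(8), x])
        b = np.array([res.intercept, res.slope])
        c = 2 * res.s2 * res.f_crit
        for pt in res.ellipse_boundary[::60]:
            d = pt - b
            assert float(d @ (X.T @ X) @ d) == pytest.approx(c, rel=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ejcr([1.0, 2.0], [1.0, 2.0])


class TestTTests:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t_vs_reference([101, 101, 101, 99, 99, 99, 101, 99])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 7
        assert not res.significant

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        v = rng.normal(100.4, 1.2, size=8)
        res = one_sample_t_vs_reference(v)
        t = (v.mean() - 100) / (v.std(ddof=1) / np.sqrt(8))
        assert res.statistic == pytest.approx(t, abs=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_vs_reference([100.0] * 4)


class TestOfficialComparison:
    def test_identical_samples(self):
        a = [99.5, 100.2, 100.8, 99.9]
        t, f = compare_with_official(a, list(a))
        assert t.statistic == pytest.approx(0.0)
        assert f.statistic == pytest.approx(1.0)

    def test_df_pattern_of_published_comparison(self):
        # model n=8 vs official n=3: pooled t df 9 -> critical 2.262
        rng = np.random.default_rng(5)
        t, f = compare_with_official(rng.normal(100, 1, 8), rng.normal(100, 1.4, 3))
        assert t.df == 9
        assert t.critical == pytest.approx(2.262, abs=5e-4)
        assert f.df in [(7, 2), (2, 7)]

    def test_pooled_t_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(100, 1, 8), rng.normal(99.8, 1.5, 3)
        t, _ = compare_with_official(a, b)
        sp2 = (7 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 9
        expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 8 + 1 / 3))
        assert t.statistic == pytest.approx(expect, abs=1e-12)

    def test_larger_variance_in_numerator(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(100, 0.5, 8), rng.normal(100, 3.0, 3)
        _, f = compare_with_official(a, b)
        assert f.statistic >= 1.0
        assert f.df == (2, 7)


class TestCriticalValues:
    @pytest.mark.parametrize("alpha,df,expect", [
        (0.05, 7, 2.365), (0.01, 7, 3.499), (0.05, 9, 2.262),
    ])
    def test_t_two_sided_tabulated(self, alpha, df, expect):
        assert critical_value("t_two_sided", alpha, df) == pytest.approx(expect, abs=5e-4)

    def test_f_upper_tabulated(self):
        assert critical_value("F_upper", 0.05, (2, 7)) == pytest.approx(4.737, abs=5e-4)

    def test_t_normal_limit(self):
        assert critical_value("t_two_sided", 0.05, 10**6) == pytest.approx(1.960, abs=1e-3)

    def test_t_matches_density_integration(self):
        # brute-force numerical integration of the t density at small df
        crit = critical_value("t_two_sided", 0.05, 5)
        mass, _ = integrate.quad(lambda u: sps.t.pdf(u, 5), -crit, crit)
        assert mass == pytest.approx(0.95, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            critical_value("t_two_sided", 0.05, 0)
        with pytest.raises(ValueError):
            critical_value("t_two_sided", 1.5, 5)
        with pytest.raises(ValueError):
            critical_value("chi2", 0.05, 5)


class TestMolarMass:
    def test_single_carbon(self):
        assert molar_mass("C") == pytest.approx(12.011)

    def test_water(self):
        assert molar_mass("H2O") == pytest.approx(18.015, abs=5e-4)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            molar_mass("Xx2")

    def test_titration_equivalence_constant(self):
        # 1.0 mL of 0.1 M NaOH ~ 35.23 mg dextromethorphan hydrobromide
        assert titration_equivalent("C18H26BrNO", 0.1, 1.0) == pytest.approx(35.23, abs=0.005)
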