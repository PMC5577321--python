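"""Regression, power-law, Welch-test and pre/post analyses against
closed-form oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import stromap as sm


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        reg = sm.linear_regression(x, 3.0 * x + 1.0)
        assert reg.slope == pytest.approx(3.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.n == 4

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 30)
        y = 2.0 * x + rng.normal(0, 1.5, 30)
        reg = sm.linear_regression(x, y)
        # textbook normal equations + slope t-test
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(x) - 2)
        se = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
        t = beta[0] / se
        p = 2 * sps.t.sf(abs(t), len(x) - 2)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
        assert reg.slope == pytest.approx(beta[0], abs=1e-10)
        assert reg.intercept == pytest.approx(beta[1], abs=1e-10)
        assert reg.r2 == pytest.approx(r2, abs=1e-10)
        assert reg.p_value == pytest.approx(p, abs=1e-10)

    def test_null_p_values_uniform(self):
        """Under no correlation the slope p-value is U(0,1): KS over 500
        simulated datasets of n = 100."""
        gen = np.random.default_rng(42)
        pvals = [
            sm.linear_regression(gen.normal(size=100), gen.normal(size=100)).p_value
            for _ in range(500)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize(
        "x,y",
        [([1.0, 2.0], [1.0, 2.0]), ([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])],
    )
    def test_degenerate_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            sm.linear_regression(x, y)


class TestPowerLaw:
    def test_exact_power_law_recovered(self):
        x = np.geomspace(0.5, 20.0, 24)
        fit = sm.power_law_fit(x, 5.0 * x**-0.31)
        assert fit.exponent == pytest.approx(-0.31, abs=1e-9)
        assert fit.prefactor == pytest.approx(5.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y_gives_zero_exponent(self):
        fit = sm.power_law_fit([1.0, 2.0, 4.0, 8.0], [3.0, 3.0, 3.0, 3.0])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_identity_gives_unit_exponent(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        fit = sm.power_law_fit(x, x)
        assert fit.exponent == pytest.approx(1.0)
        assert fit.prefactor == pytest.approx(1.0)

    def test_nonpositive_values_reported_by_index(self):
        with pytest.raises(ValueError, match=r"\[1, 3\]"):
            sm.power_law_fit([1.0, -2.0, 3.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_agrees_with_regression_on_logs(self, rng):
        x = rng.uniform(0.5, 20, 24)
        y = 3.0 * x**-0.5 * np.exp(rng.normal(0, 0.1, 24))
        fit = sm.power_law_fit(x, y)
        reg = sm.linear_regression(np.log(x), np.log(y))
        assert fit.exponent == reg.slope
        assert fit.prefactor == pytest.approx(np.exp(reg.intercept))
        assert fit.r2 == reg.r2 and fit.p_value == reg.p_value


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        res = sm.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        res = sm.welch_t_test(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_symmetry_under_sample_swap(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 20)
        r1, r2 = sm.welch_t_test(a, b), sm.welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.df == pytest.approx(r2.df)

    def test_detects_two_sd_shift(self):
        gen = np.random.default_rng(9)
        a = gen.normal(0.0, 1.0, 30)
        b = gen.normal(2.0, 1.0, 30)
        assert sm.welch_t_test(a, b).p_value < 0.001

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            sm.welch_t_test([1.0], [1.0, 2.0])


class TestCollagenase:
    def test_thirty_percent_reduction(self):
        s = sm.collagenase_effect([sm.PrePostRecord("t1", 50.0, 35.0)])
        assert s.percent_changes == (-30.0,)
        assert s.n_decreased == 1

    def test_no_change_is_zero_percent(self):
        s = sm.collagenase_effect([sm.PrePostRecord("t1", 40.0, 40.0)])
        assert s.mean_percent_change == 0.0
        assert s.n_decreased == 0

    def test_mean_of_three_reductions(self):
        recs = [
            sm.PrePostRecord("a", 100.0, 80.0),
            sm.PrePostRecord("b", 100.0, 70.0),
            sm.PrePostRecord("c", 100.0, 60.0),
        ]
        s = sm.collagenase_effect(recs)
        assert s.mean_percent_change == pytest.approx(-30.0)
        assert s.n_decreased == 3 and s.n == 3

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            sm.collagenase_effect([sm.PrePostRecord("t", 0.0, 5.0)])


class TestResidualComparison:
    def test_uniform_offset_appears_in_residuals(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 2.0 * x + 1.0
        fit = sm.linear_regression(x, y)
        res_u, res_t, _ = sm.residual_comparison(fit, (x, y), (x, y + 3.0))
        assert np.allclose(res_u, 0.0)
        assert np.allclose(res_t, 3.0)  # positive = above the untreated trend

    def test_same_distribution_not_flagged(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2.0 * x + rng.normal(0, 1, 40)
        fit = sm.linear_regression(x, y)
        xt = rng.uniform(0, 10, 25)
        yt = fit.predict(xt) + rng.normal(0, 1, 25)  # treated follow the trend
        res_u, res_t, welch = sm.residual_comparison(fit, (x, y), (xt, yt))
        assert abs(res_u.mean()) < 1e-9  # OLS residuals average to zero
        assert welch.p_value > 0.05

    def test_simulated_uplift_detected(self):
        gen = np.random.default_rng(3)
        x = gen.uniform(0, 10, 30)
        y = 2.0 * x + gen.normal(0, 1, 30)
        fit = sm.linear_regression(x, y)
        xt = gen.uniform(0, 10, 20)
        yt = 2.0 * xt + 2.5 + gen.normal(0, 1, 20)  # uplifted group
        _, res_t, welch = sm.residual_comparison(fit, (x, y), (xt, yt))
        assert res_t.mean() > 0
        assert welch.p_value < 0.05


def test_per_group_means_collapse():
    g = ["a", "a", "b", "b", "c"]
    x = [1.0, 3.0, 10.0, 20.0, 5.0]
    y = [2.0, 4.0, 8.0, 12.0, 7.0]
    gx, gy = sm.stats_analysis.per_group_means(g, x, y)
    assert np.allclose(gx, [2.0, 15.0, 5.0])
    assert np.allclose(gy, [3.0, 10.0, 7.0])
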