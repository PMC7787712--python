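"""OLS and sequential ANCOVA against closed-form and external oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burrowtherm.linmod import Transform, ancova, fit_ols


class TestFitOls:
    def test_exact_line(self):
        fit = fit_ols([0, 1, 2, 3], [1, 3, 5, 7])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_solved_normal_equations(self):
        # x=(0,1,2), y=(0,1,0): Sxy = 0 so slope 0, intercept = ȳ = 1/3
        fit = fit_ols([0, 1, 2], [0, 1, 0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_constant_y_explains_nothing(self):
        fit = fit_ols([0, 1, 2, 3], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    @pytest.mark.parametrize("x,y,msg", [
        ([1, 1, 1], [1, 2, 3], "constant"),
        ([1, 2], [1, 2], "at least 3"),
        ([1, 2, 3], [1, 2], "equal length"),
    ])
    def test_degenerate_inputs(self, x, y, msg):
        with pytest.raises(ValueError, match=msg):
            fit_ols(x, y)

    def test_matches_statsmodels_on_random_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n) * rng.uniform(0.5, 10)
            y = rng.normal(2, 1) * x + rng.normal(size=n)
            fit = fit_ols(x, y)
            ref = sm.OLS(y, sm.add_constant(x)).fit()
            assert fit.intercept == pytest.approx(ref.params[0], rel=1e-9)
            assert fit.slope == pytest.approx(ref.params[1], rel=1e-9)
            assert fit.intercept_se == pytest.approx(ref.bse[0], rel=1e-8)
            assert fit.slope_se == pytest.approx(ref.bse[1], rel=1e-8)
            assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
            cov = np.asarray(ref.cov_params())
            assert fit.slope_intercept_cov == pytest.approx(cov[0, 1],
                                                            rel=1e-8)

    def test_beats_any_nearby_line_by_grid_search(self, rng):
        """Brute-force oracle: no line on a grid around the OLS solution
        achieves a smaller sum of squared errors."""
        x = rng.uniform(-3, 3, size=12)
        y = 1.7 * x - 0.4 + rng.normal(0, 0.6, size=12)
        fit = fit_ols(x, y)
        best = fit.sse
        for ds in np.linspace(-0.5, 0.5, 21):
            for di in np.linspace(-0.5, 0.5, 21):
                sse = float(np.sum((y - ((fit.slope + ds) * x
                                         + fit.intercept + di)) ** 2))
                assert sse >= best - 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_normal_equations_hold(self, seed):
        """Residuals are orthogonal to the design: Σe = 0 and Σe·x = 0."""
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 40))
        x = r.normal(size=n)
        if np.ptp(x) == 0:
            x = x + np.arange(n)
        y = r.normal(size=n)
        fit = fit_ols(x, y)
        assert abs(fit.residuals.sum()) < 1e-8
        assert abs((fit.residuals * x).sum()) < 1e-8


class TestAncova:
    def test_parallel_groups_offset(self):
        x = np.tile(np.arange(8.0), 2)
        y = np.concatenate([2 * np.arange(8.0),
                            2 * np.arange(8.0) + 0.7])
        g = np.repeat(["a", "b"], 8)
        res = ancova(y, g, x)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-9)
        assert res.p_factor < 1e-6  # exact offset, zero noise

    def test_identical_groups_have_zero_factor_f(self, rng):
        x = np.tile(rng.uniform(0, 10, 10), 2)
        y_half = 1.5 * x[:10] + rng.normal(0, 0.5, 10)
        y = np.concatenate([y_half, y_half])
        g = np.repeat(["a", "b"], 10)
        res = ancova(y, g, x)
        assert res.f_factor == pytest.approx(0.0, abs=1e-9)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-9)

    def test_twelve_point_fixture_matches_hand_table(self):
        """Frozen sequential ANOVA table for a balanced 12-point design
        (identical covariate values in both groups, so covariate and
        group sums of squares are orthogonal and order-free)."""
        x = np.array([1, 2, 3, 4, 5, 6] * 2, dtype=float)
        y = np.array([2.0, 2.9, 4.1, 5.0, 6.2, 6.8,
                      3.1, 4.0, 4.9, 6.1, 7.0, 8.1])
        g = np.repeat(["A", "B"], 6)
        res = ancova(y, g, x)
        assert res.ss_covariate == pytest.approx(35.0, rel=1e-9)
        assert res.ss_factor == pytest.approx(3.2033333333333, rel=1e-9)
        assert res.ss_interaction == pytest.approx(0.001142857142857, rel=1e-8)
        assert res.ss_residual == pytest.approx(0.132190476190476, rel=1e-9)
        assert res.f_covariate == pytest.approx(2118.1556195965, rel=1e-8)
        assert res.f_factor == pytest.approx(193.86167146974, rel=1e-8)
        assert res.f_interaction == pytest.approx(0.06916426512969, rel=1e-8)
        assert res.df_covariate == (1, 8)

    def test_matches_statsmodels_type1_anova(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm
        import pandas as pd
        n = 30
        x = rng.uniform(15, 40, n)
        g = rng.choice(["small", "large"], n)
        y = 0.5 * x + (g == "large") * 0.8 + rng.normal(0, 1, n)
        res = ancova(y, g, x)
        df = pd.DataFrame({"x": x, "g": g, "y": y})
        # force the same sequential order: covariate first
        m0 = smf.ols("y ~ x", df).fit()
        m1 = smf.ols("y ~ x + C(g)", df).fit()
        m2 = smf.ols("y ~ x + C(g) + x:C(g)", df).fit()
        tab = anova_lm(m0, m1, m2)
        ms_res = m2.ssr / m2.df_resid
        assert res.ss_factor == pytest.approx(tab.ss_diff[1], rel=1e-8)
        assert res.ss_interaction == pytest.approx(tab.ss_diff[2], rel=1e-8)
        assert res.f_factor == pytest.approx(tab.ss_diff[1] / ms_res, rel=1e-8)
        assert res.f_interaction == pytest.approx(tab.ss_diff[2] / ms_res,
                                                  rel=1e-8)

    def test_interaction_never_increases_residual_ss(self, rng):
        for _ in range(10):
            n = 24
            x = rng.uniform(0, 10, n)
            g = rng.choice(["a", "b"], n)
            y = rng.normal(size=n)
            with_int = ancova(y, g, x, include_interaction=True)
            without = ancova(y, g, x, include_interaction=False)
            assert with_int.ss_residual <= without.ss_residual + 1e-10

    def test_single_level_reduces_to_simple_regression(self, rng):
        x = rng.uniform(0, 10, 12)
        y = 2.0 * x + rng.normal(0, 0.3, 12)
        res = ancova(y, np.repeat("only", 12), x)
        fit = fit_ols(x, y)
        assert res.ss_residual == pytest.approx(fit.sse, rel=1e-10)
        assert res.f_factor == pytest.approx(0.0, abs=1e-9)

    def test_offset_sqrt_transform_applies_to_test_only(self, rng):
        x = rng.uniform(15, 40, 30)
        g = rng.choice(["a", "b"], 30)
        y = -0.3 * x + 8 + rng.normal(0, 0.8, 30)  # includes negatives
        res = ancova(y, g, x, transform=Transform.offset_sqrt)
        assert res.transform_applied is Transform.offset_sqrt
        assert np.isfinite(res.f_covariate)

    @pytest.mark.parametrize("bad", ["empty_level", "constant_cov"])
    def test_preconditions(self, bad, rng):
        x = rng.uniform(0, 10, 10)
        g = np.repeat(["a", "b"], 5)
        if bad == "empty_level":
            g = np.array(["a"] * 9 + ["b"])  # one obs in level b
        else:
            x[g == "b"] = 3.0
        with pytest.raises(ValueError):
            ancova(rng.normal(size=10), g, x)
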