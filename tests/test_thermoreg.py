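"""Burrow use efficiency, no-refuge offset, and onset-temperature algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burrowtherm.linmod import LinearFit, fit_ols
from burrowtherm.thermoreg import (OnsetUndefined, estimate_eb, estimate_treg,
                                   estimates_from_fits, group_contrast,
                                   implied_tb_sensitivity, treg_se)


def _fit(m, c, n=50):
    """A LinearFit with prescribed line and nominal uncertainty."""
    return LinearFit(slope=m, intercept=c, r_squared=0.7, n=n,
                     slope_se=0.02, intercept_se=0.5,
                     slope_intercept_cov=-0.008,
                     residuals=np.zeros(n))


class TestEstimateEb:
    @pytest.mark.parametrize("slope,intercept", [
        (0.42, 1.31),  # efficient burrow user, warm offset
        (0.0, 2.0),    # burrow ignored: horizontal line
        (1.0, 1.0),    # complete regulation: body tracks the burrow
    ])
    def test_exact_lines_recovered(self, slope, intercept):
        x = np.linspace(-18, 2, 25)
        fit = estimate_eb(zip(x, slope * x + intercept))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_cooling_capacity_is_informative_error(self):
        with pytest.raises(ValueError, match="[bB]urrow temperatures did not vary"):
            estimate_eb([(0.0, 1.0), (0.0, 2.0), (0.0, 3.0)])

    def test_noisy_recovery_with_ci_coverage(self, rng):
        """At n=150 and 0.8 °C noise, the 95% CIs for the slope and
        intercept cover the generating values in at least 90% of 200
        replicates, and the slope is essentially unbiased."""
        e_b, b = 0.42, 1.31
        cover_s = cover_i = 0
        errs = []
        for _ in range(200):
            x = rng.uniform(-18, 0, 150)
            y = b + e_b * x + rng.normal(0, 0.8, 150)
            fit = estimate_eb(zip(x, y))
            errs.append(fit.slope - e_b)
            if abs(fit.slope - e_b) <= 1.96 * fit.slope_se:
                cover_s += 1
            if abs(fit.intercept - b) <= 1.96 * fit.intercept_se:
                cover_i += 1
        assert cover_s >= 180
        assert cover_i >= 180
        assert abs(float(np.mean(errs))) < 0.02

    def test_no_false_burrow_use_signal(self, rng):
        """Data generated with E_B = 0 gives a slope CI containing 0."""
        x = rng.uniform(-15, 0, 120)
        y = 1.5 + rng.normal(0, 0.8, 120)
        fit = estimate_eb(zip(x, y))
        assert abs(fit.slope) <= 1.96 * fit.slope_se + 1e-12


class TestEstimateTreg:
    def test_unit_slope_case(self):
        s_star, t_reg, t_upper = estimate_treg(_fit(-1.0, 10.0), 2.0)
        assert (s_star, t_reg, t_upper) == (8.0, 10.0, 10.0)

    def test_reconstructed_small_female_case(self):
        # m = -0.30, c = 8.784, b = 2.04: S* = 22.48 and T_reg = 24.52
        s_star, t_reg, t_upper = estimate_treg(_fit(-0.30, 8.784), 2.04)
        assert s_star == pytest.approx(22.48, abs=1e-9)
        assert round(t_reg, 2) == 24.52
        # substituting S* back into the line returns exactly b
        assert -0.30 * s_star + 8.784 == pytest.approx(2.04, abs=1e-10)

    def test_positive_slope_onset_undefined(self):
        with pytest.raises(OnsetUndefined):
            estimate_treg(_fit(0.1, 1.0), 2.0)

    @given(st.floats(-2.0, -0.05), st.floats(3.0, 15.0), st.floats(0.1, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_algebraic_closure(self, m, c, b):
        """m·S* + c == b to 1e-10 for any admissible (m, c, b)."""
        s_star, t_reg, t_upper = estimate_treg(_fit(m, c), b)
        assert m * s_star + c == pytest.approx(b, abs=1e-10)
        assert t_reg == pytest.approx(s_star + b, abs=1e-10)
        if 0 < b and -1 < m < 0:
            assert t_reg <= t_upper + 1e-9

    def test_monotone_in_slope_and_offset(self):
        """Onset rises as the capacity declines more slowly with surface
        temperature (m less negative, c > b), and rises with b."""
        c, b = 9.0, 1.5
        t_regs = [estimate_treg(_fit(m, c), b)[1]
                  for m in np.linspace(-2.0, -0.1, 25)]
        assert all(a < bb for a, bb in zip(t_regs, t_regs[1:]))
        # dT_reg/db = 1 + 1/m, positive only for m < -1
        t_regs_b = [estimate_treg(_fit(-1.5, c), bi)[1]
                    for bi in np.linspace(0.2, 3.0, 15)]
        assert all(a < bb for a, bb in zip(t_regs_b, t_regs_b[1:]))
        t_regs_shallow = [estimate_treg(_fit(-0.5, c), bi)[1]
                          for bi in np.linspace(0.2, 3.0, 15)]
        assert all(a > bb for a, bb in zip(t_regs_shallow, t_regs_shallow[1:]))

    def test_delta_method_se_positive_and_scales(self):
        se = treg_se(_fit(-0.30, 8.784), 2.04, 0.2)
        assert se > 0
        # more uncertain offset -> more uncertain onset
        assert treg_se(_fit(-0.30, 8.784), 2.04, 0.4) > se


class TestImpliedSensitivity:
    @pytest.mark.parametrize("m,expected", [
        (-0.30, 0.70),  # female capacity slope
        (-0.25, 0.75),  # male capacity slope
        (0.0, 1.0),     # body tracks the surface one-to-one
    ])
    def test_identity(self, m, expected):
        assert implied_tb_sensitivity(m) == pytest.approx(expected, abs=1e-12)
        assert implied_tb_sensitivity(_fit(m, 5.0)) == pytest.approx(
            expected, abs=1e-12)


class TestGroupContrast:
    def _estimates(self, e_b, b, name):
        x = np.linspace(-18, 0, 40)
        axes = fit_ols(x, e_b * x + b + np.sin(np.arange(40)) * 0.1)
        cap = fit_ols(np.linspace(18, 40, 40),
                      -0.3 * np.linspace(18, 40, 40) + 8.8
                      + np.cos(np.arange(40)) * 0.1)
        return estimates_from_fits(name, axes, cap)

    def test_offset_contrast_rounds_to_printed_value(self):
        a = self._estimates(0.50, 2.04, "small_female")
        b = self._estimates(0.42, 1.31, "large_female")
        contrast = group_contrast(a, b)
        assert contrast.d_b_offset == pytest.approx(0.73, abs=0.02)
        assert round(contrast.d_b_offset, 1) == 0.7
        assert contrast.d_e_b == pytest.approx(0.08, abs=0.01)
        assert contrast.d_e_b_se > 0

    def test_identical_groups_contrast_zero(self):
        a = self._estimates(0.42, 1.31, "g")
        contrast = group_contrast(a, a)
        assert contrast.d_e_b == 0.0
        assert contrast.d_b_offset == 0.0
        assert contrast.d_t_reg == 0.0

    def test_onset_undefined_propagates_as_absent(self):
        x = np.linspace(-18, 0, 30)
        axes = fit_ols(x, 0.4 * x + 1.0 + np.sin(np.arange(30)) * 0.05)
        rising = fit_ols(np.linspace(18, 40, 30),
                         0.2 * np.linspace(18, 40, 30)
                         + np.cos(np.arange(30)) * 0.05)
        est = estimates_from_fits("odd", axes, rising)
        assert est.t_reg is None
        assert "non-negative" in est.onset_reason
        other = self._estimates(0.42, 1.31, "g")
        assert group_contrast(est, other).d_t_reg is None
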