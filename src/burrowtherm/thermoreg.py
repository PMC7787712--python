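"""Estimators for burrow-based behavioral thermoregulation parameters.

Three quantities characterise how an intertidal burrowing ectotherm uses
its burrow against surface heat:

* **E_B**, the burrow use efficiency: the slope of the thermoregulation
  capacity y = Tb - S on the burrow cooling capacity x = B - S.  0 means
  the burrow is ignored, 1 means the body tracks the burrow completely.
* **b = T̂e - S**, the intercept of that line: how much warmer than the
  surface the body sits when the burrow offers no refuge (B = S), set by
  passive thermal properties of the body.  T̂e is the operative body
  temperature under no refuge.
* **T_reg**, the onset body temperature at which the animal begins using
  burrows to thermoregulate.  With the regression of y = Tb - S on the
  surface temperature S written y = m·S + c (m < 0: capacity declines as
  the surface warms), the onset surface temperature S* solves
  m·S* + c = b, so S* = (b - c)/m, and T_reg = S* + b.  The x-intercept
  -c/m of the same line gives an upper bound for T_reg.

All estimators consume :class:`~burrowtherm.linmod.LinearFit` objects, so
uncertainty can be propagated by the delta method.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .data import SizeClass, ThermoPoint
from .linmod import LinearFit, fit_ols

__all__ = [
    "ThermoregEstimates",
    "GroupContrast",
    "OnsetUndefined",
    "estimate_eb",
    "estimate_treg",
    "implied_tb_sensitivity",
    "group_contrast",
]


class OnsetUndefined(ValueError):
    """The thermoregulation onset does not exist for this fit.

    Raised when the Tb - S versus S slope is non-negative: the capacity
    line never descends to the no-thermoregulation level b, so no onset
    surface temperature exists.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ThermoregEstimates:
    """Per-group thermoregulation parameters with provenance fits."""

    group: SizeClass | str
    e_b: float
    e_b_se: float
    b_offset: float
    b_offset_se: float
    #: slope / intercept of the Tb - S vs S regression
    m: float
    c: float
    surface_at_onset: float | None
    t_reg: float | None
    t_reg_se: float | None
    t_reg_upper: float | None
    onset_reason: str | None  # set when the onset is undefined
    axes_fit: LinearFit
    capacity_fit: LinearFit

    @property
    def n_axes(self) -> int:
        return self.axes_fit.n

    def to_dict(self) -> dict:
        g = self.group.value if isinstance(self.group, SizeClass) else self.group
        return {
            "group": g,
            "n_axes": self.axes_fit.n,
            "n_capacity": self.capacity_fit.n,
            "e_b": self.e_b,
            "e_b_se": self.e_b_se,
            "b_offset": self.b_offset,
            "b_offset_se": self.b_offset_se,
            "m": self.m,
            "c": self.c,
            "surface_at_onset": self.surface_at_onset,
            "t_reg": self.t_reg,
            "t_reg_se": self.t_reg_se,
            "t_reg_upper": self.t_reg_upper,
            "onset_reason": self.onset_reason,
            "r_squared_axes": self.axes_fit.r_squared,
            "r_squared_capacity": self.capacity_fit.r_squared,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def estimate_eb(points) -> LinearFit:
    """Fit the thermoregulation-axes line y = E_B·x + b.

    ``points`` is an iterable of :class:`ThermoPoint` (or (x, y) pairs).
    The returned fit's slope is the burrow use efficiency E_B and its
    intercept the no-refuge offset b = T̂e - S.
    """
    xs, ys = [], []
    for p in points:
        if isinstance(p, ThermoPoint):
            xs.append(p.cooling_capacity_c)
            ys.append(p.thermoreg_capacity_c)
        else:
            x, y = p
            xs.append(float(x))
            ys.append(float(y))
    if len(xs) < 3:
        raise ValueError("need at least 3 thermoregulation-axes points")
    try:
        return fit_ols(xs, ys)
    except ValueError as e:
        if "constant" in str(e):
            raise ValueError(
                "burrow temperatures did not vary relative to the surface: "
                "the cooling capacity is constant, so the burrow use "
                "efficiency is not identifiable"
            ) from e
        raise


def estimate_treg(fit_tbs_vs_s: LinearFit,
                  b_offset: float) -> tuple[float, float, float]:
    """Onset of burrow thermoregulation from the capacity-vs-surface fit.

    Returns ``(surface_at_onset, t_reg, t_reg_upper)`` where
    S* = (b - c)/m, T_reg = S* + b, and T_reg_upper = -c/m is the
    x-intercept bound.

    Raises
    ------
    OnsetUndefined
        if the fitted slope m is non-negative — the capacity never falls
        to the no-thermoregulation level, so no onset exists.
    """
    m, c = fit_tbs_vs_s.slope, fit_tbs_vs_s.intercept
    if not math.isfinite(b_offset):
        raise ValueError("b_offset must be finite")
    if m >= 0:
        raise OnsetUndefined(
            f"capacity-vs-surface slope m = {m:.4g} is non-negative; the "
            "thermoregulation capacity never declines to the no-refuge "
            "level, so the onset temperature is undefined"
        )
    s_star = (b_offset - c) / m
    return s_star, s_star + b_offset, -c / m


def treg_se(fit_tbs_vs_s: LinearFit, b_offset: float,
            b_offset_se: float) -> float:
    """Delta-method standard error of T_reg = (b - c)/m + b.

    Treats the capacity-vs-surface fit (m, c) and the axes-fit intercept
    b as independent, using the within-fit (m, c) covariance.
    """
    m, c = fit_tbs_vs_s.slope, fit_tbs_vs_s.intercept
    db = 1.0 / m + 1.0
    dc = -1.0 / m
    dm = -(b_offset - c) / m ** 2
    var = (db ** 2 * b_offset_se ** 2
           + dc ** 2 * fit_tbs_vs_s.intercept_se ** 2
           + dm ** 2 * fit_tbs_vs_s.slope_se ** 2
           + 2.0 * dm * dc * fit_tbs_vs_s.slope_intercept_cov)
    return math.sqrt(max(var, 0.0))


def implied_tb_sensitivity(fit_tbs_vs_s: LinearFit | float) -> float:
    """Marginal change of body temperature per 1 °C of surface warming.

    From Tb - S = m·S + c, the body temperature satisfies
    Tb = (1 + m)·S + c, so dTb/dS = 1 + m.  Accepts a fit or a bare
    slope.  A slope of -0.30 therefore implies the body warms 0.70 °C
    per 1 °C of surface warming; m = 0 means the body tracks the surface
    one-to-one plus a constant offset.
    """
    m = fit_tbs_vs_s.slope if isinstance(fit_tbs_vs_s, LinearFit) \
        else float(fit_tbs_vs_s)
    return 1.0 + m


def estimates_from_fits(group, axes_fit: LinearFit,
                        capacity_fit: LinearFit) -> ThermoregEstimates:
    """Assemble the full per-group estimate record from the two fits."""
    b, b_se = axes_fit.intercept, axes_fit.intercept_se
    try:
        s_star, t_reg, t_upper = estimate_treg(capacity_fit, b)
        t_se = treg_se(capacity_fit, b, b_se)
        reason = None
    except OnsetUndefined as e:
        s_star = t_reg = t_upper = t_se = None
        reason = e.reason
    return ThermoregEstimates(
        group=group,
        e_b=axes_fit.slope, e_b_se=axes_fit.slope_se,
        b_offset=b, b_offset_se=b_se,
        m=capacity_fit.slope, c=capacity_fit.intercept,
        surface_at_onset=s_star, t_reg=t_reg, t_reg_se=t_se,
        t_reg_upper=t_upper, onset_reason=reason,
        axes_fit=axes_fit, capacity_fit=capacity_fit,
    )


@dataclass(frozen=True)
class GroupContrast:
    """Differences in (E_B, b, T_reg) between two groups, a - b.

    Standard errors combine the two groups' independent fits in
    quadrature (delta method on independent estimates).
    """

    group_a: str
    group_b: str
    d_e_b: float
    d_e_b_se: float
    d_b_offset: float
    d_b_offset_se: float
    d_t_reg: float | None
    d_t_reg_se: float | None

    def to_dict(self) -> dict:
        return {
            "groups": [self.group_a, self.group_b],
            "d_e_b": self.d_e_b, "d_e_b_se": self.d_e_b_se,
            "d_b_offset": self.d_b_offset,
            "d_b_offset_se": self.d_b_offset_se,
            "d_t_reg": self.d_t_reg, "d_t_reg_se": self.d_t_reg_se,
        }


def group_contrast(a: ThermoregEstimates,
                   b: ThermoregEstimates) -> GroupContrast:
    """Contrast two groups' thermoregulation estimates (a minus b)."""
    def _name(g):
        return g.value if isinstance(g, SizeClass) else str(g)

    if a.t_reg is not None and b.t_reg is not None:
        d_t = a.t_reg - b.t_reg
        d_t_se = math.hypot(a.t_reg_se, b.t_reg_se)
    else:
        d_t = d_t_se = None
    return GroupContrast(
        group_a=_name(a.group), group_b=_name(b.group),
        d_e_b=a.e_b - b.e_b,
        d_e_b_se=math.hypot(a.e_b_se, b.e_b_se),
        d_b_offset=a.b_offset - b.b_offset,
        d_b_offset_se=math.hypot(a.b_offset_se, b.b_offset_se),
        d_t_reg=d_t, d_t_reg_se=d_t_se,
    )
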