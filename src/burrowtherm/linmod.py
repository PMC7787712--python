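"""Ordinary least squares and ANCOVA built directly on the normal equations.

These serve two roles: the per-group regressions of thermoregulation
capacity (Tb - S) on surface temperature or on burrow cooling capacity
(B - S), and the homogeneity-of-slopes ANCOVA (size factor x continuous
covariate, with interaction) used to test whether crab size changes the
response.  Sums of squares are sequential (Type I): the covariate enters
first, then the size term, then the interaction — the same sequential
convention as the permutational analogue in :mod:`burrowtherm.nonparam`,
so parametric and permutational tables partition the identical total SS.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["LinearFit", "AncovaResult", "Transform", "fit_ols", "ancova"]


class Transform(str, enum.Enum):
    """Dependent-variable transform for the ANCOVA hypothesis test.

    ``offset_sqrt`` shifts y to positivity then takes the square root,
    sqrt(y - min(y) + 0.01): a variance-stabilising device for the test
    only.  Parameter estimation (slopes in °C/°C, intercepts in °C) is
    always done untransformed.
    """

    none = "none"
    offset_sqrt = "offset_sqrt"


@dataclass(frozen=True)
class LinearFit:
    """A simple linear regression y = slope * x + intercept.

    When fitted on the thermoregulation axes (y = Tb - S against
    x = B - S) the slope is the burrow use efficiency E_B and the
    intercept is the no-refuge operative offset b = T̂e - S.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float
    intercept_se: float
    #: cov(slope, intercept) under the homoscedastic OLS model; needed to
    #: propagate uncertainty into derived onset temperatures.
    slope_intercept_cov: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    @property
    def sse(self) -> float:
        return float(self.residuals @ self.residuals)

    def to_dict(self, group: str | None = None) -> dict:
        d = {
            "n": self.n,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
        }
        if group is not None:
            d = {"group": group, **d}
        return d

    def to_json(self, group: str | None = None) -> str:
        return json.dumps(self.to_dict(group))


def fit_ols(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Least-squares line through (x, y) via the closed-form normal equations.

    slope = Sxy / Sxx, intercept = ȳ - slope·x̄, with the usual
    residual-variance based standard errors.  R² is 1 - SSE/SST, defined
    as 0 when y has no variance.

    Raises
    ------
    ValueError
        on length mismatch, n < 3, or constant x (degenerate design).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a fit with standard errors")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("degenerate design: x is constant")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(((y - ybar) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    # guard tiny negative round-off
    r2 = min(1.0, max(0.0, r2))
    sigma2 = sse / (n - 2)
    slope_se = math.sqrt(sigma2 / sxx)
    intercept_se = math.sqrt(sigma2 * (1.0 / n + xbar ** 2 / sxx))
    cov = -xbar * sigma2 / sxx
    return LinearFit(slope=slope, intercept=intercept, r_squared=r2, n=n,
                     slope_se=slope_se, intercept_se=intercept_se,
                     slope_intercept_cov=cov, residuals=resid)


@dataclass(frozen=True)
class AncovaResult:
    """Sequential (Type I) ANCOVA table for covariate, factor, interaction."""

    f_covariate: float
    f_factor: float
    f_interaction: float | None
    p_covariate: float
    p_factor: float
    p_interaction: float | None
    df_covariate: tuple[int, int]
    df_factor: tuple[int, int]
    df_interaction: tuple[int, int] | None
    ss_covariate: float
    ss_factor: float
    ss_interaction: float | None
    ss_residual: float
    ss_total: float
    n: int
    transform_applied: Transform

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "transform": self.transform_applied.value,
            "covariate": {"f": self.f_covariate, "p": self.p_covariate,
                          "df": list(self.df_covariate),
                          "ss": self.ss_covariate},
            "factor": {"f": self.f_factor, "p": self.p_factor,
                       "df": list(self.df_factor), "ss": self.ss_factor},
            "residual_ss": self.ss_residual,
            "total_ss": self.ss_total,
        }
        if self.f_interaction is not None:
            d["interaction"] = {"f": self.f_interaction,
                                "p": self.p_interaction,
                                "df": list(self.df_interaction),
                                "ss": self.ss_interaction}
        return d


def _lstsq_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def design_matrices(factor: np.ndarray, covariate: np.ndarray,
                    include_interaction: bool) -> list[np.ndarray]:
    """Nested design matrices: intercept; +covariate; +factor; [+interaction].

    ``factor`` may be a two-level categorical (any dtype) or a continuous
    size measure; a two-level factor is dummy-coded, anything else is
    entered as a centred numeric column.
    """
    n = covariate.size
    ones = np.ones(n)
    levels = np.unique(factor)
    if levels.size == 2:
        fcol = (factor == levels[1]).astype(float)
    elif levels.size == 1:
        # degenerate single-level factor: the model collapses onto the
        # covariate-only regression
        fcol = np.zeros(n)
    else:
        fcol = np.asarray(factor, dtype=float)
        fcol = fcol - fcol.mean()
    mats = [
        np.column_stack([ones]),
        np.column_stack([ones, covariate]),
        np.column_stack([ones, covariate, fcol]),
    ]
    if include_interaction:
        mats.append(np.column_stack([ones, covariate, fcol, covariate * fcol]))
    return mats


def ancova(
    y: Sequence[float],
    factor: Sequence,
    covariate: Sequence[float],
    include_interaction: bool = True,
    transform: Transform | str = Transform.none,
) -> AncovaResult:
    """Sequential ANCOVA of y on a covariate, a size term, and optionally
    their interaction (the homogeneity-of-slopes test).

    Each term's F is its sequential mean square over the residual mean
    square of the largest model, with the F distribution providing
    p-values.  ``factor`` may be a dichotomous size class or a continuous
    carapace width; both forms of the analysis are supported.
    """
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    factor = np.asarray(factor)
    transform = Transform(transform)
    if not (y.size == covariate.size == factor.size):
        raise ValueError("y, factor and covariate must have equal length")
    n = y.size
    levels = np.unique(factor)
    if levels.size == 2:
        for lev in levels:
            sub = covariate[factor == lev]
            if sub.size < 2:
                raise ValueError(f"factor level {lev!r} has fewer than 2 observations")
            if np.ptp(sub) == 0:
                raise ValueError(f"covariate is constant within level {lev!r}")
    elif np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")

    if transform is Transform.offset_sqrt:
        y = np.sqrt(y - y.min() + 0.01)

    mats = design_matrices(factor, covariate, include_interaction)
    sses = [_lstsq_sse(X, y) for X in mats]
    df_model = [X.shape[1] for X in mats]
    df_res = n - df_model[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    ms_res = sses[-1] / df_res
    ss_total = sses[0]

    def term(i: int) -> tuple[float, float, float, tuple[int, int]]:
        ss = max(sses[i - 1] - sses[i], 0.0)
        df1 = df_model[i] - df_model[i - 1]
        if ms_res > 0:
            f = (ss / df1) / ms_res
        else:  # exact fit: any explained SS is infinitely significant
            f = math.inf if ss > 1e-12 * max(ss_total, 1.0) else 0.0
        p = float(stats.f.sf(f, df1, df_res))
        return ss, f, p, (df1, df_res)

    ss_c, f_c, p_c, df_c = term(1)
    ss_f, f_f, p_f, df_f = term(2)
    if include_interaction:
        ss_i, f_i, p_i, df_i = term(3)
    else:
        ss_i = f_i = p_i = df_i = None
    return AncovaResult(
        f_covariate=f_c, f_factor=f_f, f_interaction=f_i,
        p_covariate=p_c, p_factor=p_f, p_interaction=p_i,
        df_covariate=df_c, df_factor=df_f, df_interaction=df_i,
        ss_covariate=ss_c, ss_factor=ss_f, ss_interaction=ss_i,
        ss_residual=sses[-1], ss_total=ss_total, n=n,
        transform_applied=transform,
    )
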