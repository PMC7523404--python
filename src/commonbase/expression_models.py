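"""Regression-to-expression transforms with confidence bands.

A fitted line relating dCq(w) to another quantity is only a point estimate on
the log scale.  These functions turn a :class:`~commonbase.linreg.LinearFit`
plus a baseline x0 into relative-expression or response predictions, in the
five functional configurations the method covers:

===== ============================== ==============================
case  fitted relationship            back-transformed prediction
===== ============================== ==============================
A     dCq(w) = m*x + b               R(x)   = 10**(m*(x0 - x))
B     y = m*dCq(w) + b               y(R)   = y0 - m*log10(R)
C     dCq_B(w) = m*dCq_A(w) + b      R_B    = R_A**m
D     dCq(w) = m*log10(x) + b        R(x)   = (x0/x)**m
E     log10(y) = m*dCq(w) + b        y(R)   = y0 * R**(-m)
===== ============================== ==============================

All confidence bands are propagated from the slope CI (L, U) alone — the
baseline x0 is a fixed choice, not a random quantity, so slope uncertainty is
the only random element in a predicted ddCq(w).  The two candidate band
endpoints swap order on either side of the baseline; the builders order them
pointwise, which also makes the band collapse to the point estimate exactly
at the baseline.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import ExtrapolationError, ExtrapolationWarning, ValidationError
from .linreg import LinearFit, slope_is_null

__all__ = [
    "BaselinePolicy",
    "Baseline",
    "ExpressionCurve",
    "ResponseCurve",
    "choose_baseline",
    "case_a_curve",
    "case_b_predict",
    "case_c_curve",
    "case_d_curve",
    "case_e_predict",
]

#: Relative slack on range checks so the observed endpoints themselves never
#: trip the extrapolation guard through float round-off.
_RANGE_RTOL = 1e-9


class BaselinePolicy(str, enum.Enum):
    MEAN = "mean"
    MIN = "min"
    MAX = "max"
    CUSTOM = "custom"


@dataclass(frozen=True)
class Baseline:
    """The fixed comparison point x0 on the independent axis.

    Everything is expressed relative to it: the predicted ratio at x0 is 1 by
    construction.  The mean of the observed x is the recommended default —
    it yields the smallest and most symmetric confidence bands, because band
    width grows with |x - x0|.
    """

    x0: float
    policy: BaselinePolicy


def choose_baseline(
    fit: LinearFit,
    policy: "BaselinePolicy | str" = BaselinePolicy.MEAN,
    custom_value: Optional[float] = None,
    x_values: Optional[Sequence[float]] = None,
) -> Baseline:
    """Pick the baseline x0 from the fitted data or a custom value.

    With ``x_values`` given, statistics are taken from those numbers instead
    of the fit — required for case D, where the fit saw log10(x) but the
    baseline lives on the raw scale.  A custom value must lie inside the
    observed range; comparisons to a point never measured are extrapolation.
    """
    policy = BaselinePolicy(policy)
    if x_values is not None:
        xv = np.asarray(x_values, dtype=float)
        if xv.size == 0:
            raise ValidationError("x_values must be non-empty")
        lo, mid, hi = float(xv.min()), float(xv.mean()), float(xv.max())
    else:
        lo, mid, hi = fit.x_min, fit.x_mean, fit.x_max

    if policy is BaselinePolicy.CUSTOM:
        if custom_value is None:
            raise ValidationError("policy 'custom' requires custom_value")
        x0 = float(custom_value)
        if not (lo <= x0 <= hi):
            raise ExtrapolationError(
                f"custom baseline {x0!r} lies outside the observed range"
                f" [{lo}, {hi}]; relative expression is only defined within"
                " the range of the study"
            )
    elif policy is BaselinePolicy.MEAN:
        x0 = mid
    elif policy is BaselinePolicy.MIN:
        x0 = lo
    else:
        x0 = hi
    return Baseline(x0=x0, policy=policy)


@dataclass(frozen=True)
class ExpressionCurve:
    """Predicted relative expression over a grid of inputs, with CI band.

    ``inputs`` are x values (cases A and D) or gene-A ratios R_A (case C);
    ``r_hat`` the point predictions; the band is ordered pointwise so
    ``ci_low <= r_hat <= ci_high`` everywhere and all three equal 1 at the
    baseline.  ``null_slope`` records that the slope test failed to reject
    m = 0 at 1 - conf_level, in which case the flat curve R = 1 is the
    defensible summary.
    """

    mode: str
    inputs: np.ndarray
    r_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline: Baseline
    null_slope: bool


@dataclass(frozen=True)
class ResponseCurve:
    """Predicted response y over a grid of expression ratios, with CI band.

    ``y0_hat`` is the response predicted at the baseline dCq(w); predictions
    satisfy y_hat = y0_hat at R = 1.
    """

    mode: str
    ratios: np.ndarray
    y_hat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    y0_hat: float
    baseline: Baseline
    null_slope: bool


def _check_range(
    values: np.ndarray,
    lo: float,
    hi: float,
    allow_extrapolation: bool,
    what: str,
) -> None:
    slack = _RANGE_RTOL * max(abs(lo), abs(hi), 1.0)
    bad = values[(values < lo - slack) | (values > hi + slack)]
    if bad.size:
        msg = (
            f"{what} {bad[0]!r} lies outside the observed range"
            f" [{lo}, {hi}]; predictions there are extrapolation"
        )
        if allow_extrapolation:
            warnings.warn(msg, ExtrapolationWarning, stacklevel=3)
        else:
            raise ExtrapolationError(
                msg + " (pass allow_extrapolation=True to override)"
            )


def _band(end1: np.ndarray, end2: np.ndarray):
    """Order two candidate band endpoints pointwise."""
    return np.minimum(end1, end2), np.maximum(end1, end2)


def _positive(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(arr) & (arr > 0)):
        raise ValidationError(f"{what} must be positive and finite")
    return arr


def case_a_curve(
    fit: LinearFit,
    baseline: Baseline,
    grid,
    allow_extrapolation: bool = False,
    null_as_unity: bool = False,
    alpha: Optional[float] = None,
) -> ExpressionCurve:
    """Case A: dCq(w) regressed on a linear x; R(x) = 10**(m*(x0 - x)).

    The band endpoints are 10**(L*(x0-x)) and 10**(U*(x0-x)); which is lower
    depends on the sign of x - x0, so they are ordered per point.  With
    ``null_as_unity`` and a non-significant slope, the point prediction is
    reported as the constant 1 (the band, which necessarily contains 1,
    is kept).
    """
    x = np.atleast_1d(np.asarray(grid, dtype=float))
    _check_range(x, fit.x_min, fit.x_max, allow_extrapolation, "x value")
    shift = baseline.x0 - x
    r_hat = 10.0 ** (fit.m * shift)
    lo, hi = _band(10.0 ** (fit.ci_low * shift), 10.0 ** (fit.ci_high * shift))
    null = slope_is_null(fit, alpha if alpha is not None else 1 - fit.conf_level)
    if null_as_unity and null:
        r_hat = np.ones_like(r_hat)
    return ExpressionCurve(
        mode="A_linear",
        inputs=x,
        r_hat=r_hat,
        ci_low=lo,
        ci_high=hi,
        baseline=baseline,
        null_slope=null,
    )


def case_b_predict(
    fit: LinearFit,
    baseline: Baseline,
    ratios,
    alpha: Optional[float] = None,
) -> ResponseCurve:
    """Case B: a response regressed on dCq(w); y(R) = y0 - m*log10(R).

    ``baseline.x0`` is a dCq(w) value here, and y0 = m*x0 + b.  Because the
    multiplier on log10(R) is -m, the slope CI endpoints swap: the band is
    (y0 - U*log10R, y0 - L*log10R), reordered when log10(R) < 0.
    """
    r = _positive(ratios, "expression ratio R")
    logr = np.log10(r)
    y0 = fit.m * baseline.x0 + fit.b
    y_hat = y0 - fit.m * logr
    lo, hi = _band(y0 - fit.ci_high * logr, y0 - fit.ci_low * logr)
    null = slope_is_null(fit, alpha if alpha is not None else 1 - fit.conf_level)
    return ResponseCurve(
        mode="B_log",
        ratios=r,
        y_hat=y_hat,
        ci_low=lo,
        ci_high=hi,
        y0_hat=float(y0),
        baseline=baseline,
        null_slope=null,
    )


def case_c_curve(
    fit: LinearFit,
    baseline: Baseline,
    ratios_a,
    null_as_unity: bool = False,
    alpha: Optional[float] = None,
) -> ExpressionCurve:
    """Case C: gene B's dCq(w) regressed on gene A's; R_B = R_A**m.

    This is case A composed with the ratio transform on the input axis: a
    ratio R_A relative to the gene-A baseline maps to the m-th power.  The
    band is (R_A**L, R_A**U), ordered per point — which endpoint is lower
    flips as R_A crosses 1.
    """
    ra = _positive(ratios_a, "gene-A expression ratio R_A")
    r_hat = ra**fit.m
    lo, hi = _band(ra**fit.ci_low, ra**fit.ci_high)
    null = slope_is_null(fit, alpha if alpha is not None else 1 - fit.conf_level)
    if null_as_unity and null:
        r_hat = np.ones_like(r_hat)
    return ExpressionCurve(
        mode="C_gene_gene",
        inputs=ra,
        r_hat=r_hat,
        ci_low=lo,
        ci_high=hi,
        baseline=baseline,
        null_slope=null,
    )


def case_d_curve(
    fit_on_logx: LinearFit,
    baseline: Baseline,
    grid,
    allow_extrapolation: bool = False,
    null_as_unity: bool = False,
    alpha: Optional[float] = None,
) -> ExpressionCurve:
    """Case D: dCq(w) regressed on log10(x); R(x) = (x0/x)**m.

    ``fit_on_logx`` was computed on (log10 x, dCq(w)), but ``grid`` and the
    baseline stay on the raw scale — log-transform bookkeeping is internal.
    The band is ((x0/x)**L, (x0/x)**U), ordered by whether x0/x exceeds 1.
    """
    x = _positive(grid, "x value")
    _check_range(
        np.log10(x),
        fit_on_logx.x_min,
        fit_on_logx.x_max,
        allow_extrapolation,
        "log10(x) value",
    )
    if baseline.x0 <= 0:
        raise ValidationError("baseline x0 must be positive in case D")
    ratio = baseline.x0 / x
    r_hat = ratio**fit_on_logx.m
    lo, hi = _band(ratio**fit_on_logx.ci_low, ratio**fit_on_logx.ci_high)
    null = slope_is_null(
        fit_on_logx, alpha if alpha is not None else 1 - fit_on_logx.conf_level
    )
    if null_as_unity and null:
        r_hat = np.ones_like(r_hat)
    return ExpressionCurve(
        mode="D_power",
        inputs=x,
        r_hat=r_hat,
        ci_low=lo,
        ci_high=hi,
        baseline=baseline,
        null_slope=null,
    )


def case_e_predict(
    fit_on_logy: LinearFit,
    baseline: Baseline,
    ratios,
    alpha: Optional[float] = None,
) -> ResponseCurve:
    """Case E: log10(y) regressed on dCq(w); y(R) = y0 * R**(-m).

    y0 = 10**(m*x0 + b) is the back-transformed response at the baseline
    dCq(w).  The band endpoints y0*R**(-L) and y0*R**(-U) are ordered per
    point.
    """
    r = _positive(ratios, "expression ratio R")
    m, b = fit_on_logy.m, fit_on_logy.b
    y0 = 10.0 ** (m * baseline.x0 + b)
    y_hat = y0 * r ** (-m)
    lo, hi = _band(y0 * r ** (-fit_on_logy.ci_low), y0 * r ** (-fit_on_logy.ci_high))
    null = slope_is_null(
        fit_on_logy, alpha if alpha is not None else 1 - fit_on_logy.conf_level
    )
    return ResponseCurve(
        mode="E_power",
        ratios=r,
        y_hat=y_hat,
        ci_low=lo,
        ci_high=hi,
        y0_hat=float(y0),
        baseline=baseline,
        null_slope=null,
    )
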