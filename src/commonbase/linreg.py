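"""Ordinary least squares with closed-form slope inference.

Every confidence interval downstream of a regression in this package is
propagated from exactly one random quantity: the fitted slope m.  This module
therefore exposes a single fit routine returning the slope, its standard
error (unbiased residual variance, divisor n - 2), the t-based confidence
interval (L, U), and the two-sided p-value for H0: m = 0, plus the observed
x-range so extrapolation guards never need to re-read the raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = ["LinearFit", "fit_ols", "slope_is_null"]


@dataclass(frozen=True)
class LinearFit:
    """Result of a simple linear regression y = m*x + b.

    ``ci_low``/``ci_high`` bound the slope at ``conf_level``; ``p_slope`` is
    the two-sided p-value of the t test of m = 0 on ``df`` = n - 2 residual
    degrees of freedom.  ``x_min``/``x_mean``/``x_max`` describe the observed
    predictor so downstream code can pick baselines and refuse extrapolation
    without access to the original points.
    """

    m: float
    b: float
    r2: float
    se_m: float
    df: int
    conf_level: float
    ci_low: float
    ci_high: float
    p_slope: float
    x_min: float
    x_mean: float
    x_max: float
    n: int


def _as_xy(
    points: "Iterable[Tuple[float, float]] | Sequence[float] | np.ndarray",
    y: "Sequence[float] | np.ndarray | None",
) -> Tuple[np.ndarray, np.ndarray]:
    if y is None:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(
                "points must be an iterable of (x, y) pairs"
            )
        return arr[:, 0], arr[:, 1]
    x = np.asarray(points, dtype=float)
    yy = np.asarray(y, dtype=float)
    if x.shape != yy.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d sequences")
    return x, yy


def fit_ols(
    points,
    y=None,
    conf_level: float = 0.95,
) -> LinearFit:
    """Fit y = m*x + b by ordinary least squares with slope inference.

    Accepts either an iterable of (x, y) pairs or two separate sequences.
    Requires n >= 3 points and at least two distinct x values.  The slope CI
    is m -/+ t_{df, 1-alpha/2} * se_m with se_m built from the unbiased
    residual variance (divisor n - 2).
    """
    if not 0.0 < conf_level < 1.0:
        raise ValidationError(
            f"conf_level must be in (0, 1), got {conf_level!r}"
        )
    x, yy = _as_xy(points, y)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(yy))):
        raise ValidationError("regression inputs must be finite")
    n = x.size
    if n < 3:
        raise ValidationError(
            f"insufficient points: need at least 3, got {n}"
        )
    if np.ptp(x) == 0.0:
        raise ValidationError(
            "degenerate predictor: all x values are identical"
        )

    res = stats.linregress(x, yy)
    m = float(res.slope)
    b = float(res.intercept)
    df = n - 2

    # Residual-based slope SE (unbiased variance, divisor n-2).  Computed
    # directly so that exactly collinear or constant responses give se = 0
    # rather than the NaN linregress produces for zero response variance.
    resid = yy - (m * x + b)
    rss = float(resid @ resid)
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_m = math.sqrt(rss / df / sxx)

    sst = float(np.sum((yy - yy.mean()) ** 2))
    if sst == 0.0:
        # Constant response: the fit is flat and explains nothing.
        r2 = 0.0
    else:
        r2 = 1.0 - rss / sst
        r2 = min(max(r2, 0.0), 1.0)

    if se_m == 0.0:
        # Exact collinearity: slope is known without uncertainty.
        p_slope = 1.0 if m == 0.0 else 0.0
        ci_low = ci_high = m
    else:
        tcrit = float(stats.t.ppf(0.5 + conf_level / 2.0, df))
        ci_low = m - tcrit * se_m
        ci_high = m + tcrit * se_m
        p_slope = float(2.0 * stats.t.sf(abs(m / se_m), df))

    return LinearFit(
        m=m,
        b=b,
        r2=r2,
        se_m=se_m,
        df=df,
        conf_level=conf_level,
        ci_low=ci_low,
        ci_high=ci_high,
        p_slope=p_slope,
        x_min=float(x.min()),
        x_mean=float(x.mean()),
        x_max=float(x.max()),
        n=int(n),
    )


def slope_is_null(fit: LinearFit, alpha: float = 0.05) -> bool:
    """True when the slope test fails to reject m = 0 at level ``alpha``.

    When this holds, the fitted line carries no evidence that x affects
    expression, and the method's convention is then to report a relative expression
    ratio of 1.  Curve builders attach this flag rather than silently
    flattening the curve; see ``null_as_unity`` in the expression models.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha!r}")
    return fit.p_slope >= alpha
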