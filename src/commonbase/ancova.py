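"""One-way ANCOVA on dCq(w) with pairwise expression contrasts.

Compares expression between treatment groups while controlling for a
quantitative covariate (temperature, age, dose ...).  The workflow mirrors
standard general-linear-model practice:

1. fit a separate regression per group and check that at least one slope
   differs from zero (otherwise plain ANOVA suffices);
2. test homogeneity of slopes via the treatment-by-covariate interaction —
   an extra-sum-of-squares F test between the separate-slopes model and the
   common-slope model;
3. if the lines can be treated as parallel, refit with an enforced common
   slope; the vertical offsets between lines are then constant in x and
   equal intercept differences b_i - b_j, which live on the dCq(w) scale and
   so map directly to expression ratios R = 10**(-(b_i - b_j)).

Contrasts default to unadjusted (Fisher-LSD-style) t intervals; Bonferroni
and Sidak corrections are available.  Tukey HSD is out of scope.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import HeterogeneousSlopesError, ValidationError
from .linreg import LinearFit, fit_ols

__all__ = [
    "GroupedData",
    "InteractionTest",
    "AncovaFit",
    "Contrast",
    "Adjustment",
    "SeparateSlopes",
    "fit_separate_slopes",
    "test_homogeneity",
    "fit_common_slope",
    "contrast",
    "all_contrasts",
]


class Adjustment(str, enum.Enum):
    NONE = "none"
    BONFERRONI = "bonferroni"
    SIDAK = "sidak"


@dataclass(frozen=True)
class GroupedData:
    """Per-group (covariate x, dCq(w) y) points for a one-way ANCOVA.

    Requires at least two groups, each with >= 3 points and >= 2 distinct
    covariate values.
    """

    groups: Mapping[str, Tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError(
                f"ANCOVA needs at least 2 groups, got {len(self.groups)}"
            )
        clean: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for name, (x, y) in self.groups.items():
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            if x.shape != y.shape or x.ndim != 1:
                raise ValidationError(
                    f"group {name!r}: x and y must be equal-length 1-d arrays"
                )
            if x.size < 3:
                raise ValidationError(
                    f"group {name!r} has {x.size} points; need >= 3"
                )
            if np.unique(x).size < 2:
                raise ValidationError(
                    f"group {name!r} has a constant covariate"
                )
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
                raise ValidationError(f"group {name!r} contains non-finite values")
            clean[str(name)] = (x, y)
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        x_col: str = "x",
        y_col: str = "delta_cq",
    ) -> "GroupedData":
        for col in (group_col, x_col, y_col):
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r}")
        groups = {
            str(name): (
                sub[x_col].to_numpy(dtype=float),
                sub[y_col].to_numpy(dtype=float),
            )
            for name, sub in df.groupby(group_col, sort=False)
        }
        return cls(groups=groups)

    @property
    def n_total(self) -> int:
        return sum(x.size for x, _ in self.groups.values())

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class InteractionTest:
    """F test of the treatment-by-covariate interaction (slope homogeneity).

    ``p_value`` >= alpha means the separate-slopes model fits no better than
    parallel lines, so ANCOVA may proceed.
    """

    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class SeparateSlopes:
    """Per-group OLS fits plus the step-1 screen on the covariate.

    ``any_slope_nonzero`` is False when no group rejects m = 0, in which case
    the covariate can be dropped and a plain ANOVA used instead.
    """

    fits: Mapping[str, LinearFit]
    any_slope_nonzero: bool
    note: str


@dataclass(frozen=True)
class AncovaFit:
    """Common-slope model: y = m_common * x + b_g for each group g."""

    m_common: float
    intercepts: Mapping[str, float]
    mse: float
    df_resid: int
    group_ns: Mapping[str, int]
    homogeneity: InteractionTest
    group_x_means: Mapping[str, float]
    sxx_pooled: float
    forced: bool = False

    def predict(self, group: str, x) -> np.ndarray:
        if group not in self.intercepts:
            raise ValidationError(f"unknown group {group!r}")
        return self.m_common * np.asarray(x, dtype=float) + self.intercepts[group]


@dataclass(frozen=True)
class Contrast:
    """One pairwise comparison between group intercepts.

    ``diff`` = b_i - b_j is a ddCq(w); ``r_hat`` = 10**(-diff) is the
    expression of group i relative to group j, with ``r_ci`` the
    back-transformed interval (10**(-U), 10**(-L)) — the endpoint order
    flips under the negative exponent.
    """

    group_i: str
    group_j: str
    diff: float
    ci: Tuple[float, float]
    p_value: float
    r_hat: float
    r_ci: Tuple[float, float]
    adjustment: Adjustment
    conf_level: float


def _centered_sums(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean()))), float(np.sum(xc * xc))


def fit_separate_slopes(
    data: GroupedData, alpha: float = 0.05, conf_level: float = 0.95
) -> SeparateSlopes:
    """Step 1: independent OLS per group, screening the covariate.

    Reports whether at least one group slope differs from zero at ``alpha``;
    if none does, the attached note recommends dropping the covariate in
    favor of plain ANOVA.
    """
    fits = {}
    for name, (x, y) in data.groups.items():
        try:
            fits[name] = fit_ols(x, y, conf_level=conf_level)
        except ValidationError as exc:
            raise ValidationError(f"group {name!r}: {exc}") from exc
    any_nonzero = any(f.p_slope < alpha for f in fits.values())
    note = (
        "at least one group slope differs from zero; the covariate matters"
        if any_nonzero
        else "no group slope differs from zero at alpha="
        f"{alpha}; the covariate may be ignored and ordinary ANOVA used"
    )
    return SeparateSlopes(fits=fits, any_slope_nonzero=any_nonzero, note=note)


def _rss_full(data: GroupedData) -> float:
    rss = 0.0
    for x, y in data.groups.values():
        sxy, sxx = _centered_sums(x, y)
        m = sxy / sxx
        b = y.mean() - m * x.mean()
        rss += float(np.sum((y - m * x - b) ** 2))
    return rss


def _common_slope_parts(data: GroupedData):
    sxy_tot = 0.0
    sxx_tot = 0.0
    for x, y in data.groups.values():
        sxy, sxx = _centered_sums(x, y)
        sxy_tot += sxy
        sxx_tot += sxx
    m = sxy_tot / sxx_tot
    intercepts = {
        name: float(y.mean() - m * x.mean())
        for name, (x, y) in data.groups.items()
    }
    rss = sum(
        float(np.sum((y - m * x - intercepts[name]) ** 2))
        for name, (x, y) in data.groups.items()
    )
    return m, intercepts, rss, sxx_tot


def test_homogeneity(data: GroupedData) -> InteractionTest:
    """Step 2: extra-sum-of-squares F test of slope homogeneity.

    Full model: one slope per group (2k parameters).  Reduced model: common
    slope, per-group intercepts (k + 1 parameters).  F on (k-1, n-2k)
    degrees of freedom; a small p means the lines are not parallel and
    ANCOVA is inappropriate.
    """
    n, k = data.n_total, data.k
    df_num = k - 1
    df_den = n - 2 * k
    if df_den < 1:
        raise ValidationError(
            f"too few points for the interaction test: n - 2k = {df_den}"
        )
    rss_full = _rss_full(data)
    _, _, rss_red, _ = _common_slope_parts(data)
    scale = sum(float(np.sum(y**2)) for _, y in data.groups.values())
    if rss_full <= 1e-20 * max(scale, 1e-300):
        # Saturated full model: noise-free per-group lines (up to float
        # round-off).  Any lack of parallelism is then infinitely
        # significant; perfect parallelism leaves nothing to test.
        extra = rss_red - rss_full
        f = 0.0 if extra <= 1e-20 * max(scale, 1e-300) else math.inf
        p = 1.0 if f == 0.0 else 0.0
        return InteractionTest(f_stat=f, df_num=df_num, df_den=df_den, p_value=p)
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_num, df_den))
    return InteractionTest(f_stat=float(f), df_num=df_num, df_den=df_den, p_value=p)


def fit_common_slope(
    data: GroupedData,
    alpha_homogeneity: float = 0.05,
    force: bool = False,
) -> AncovaFit:
    """Step 3: refit with an enforced common slope.

    The pooled slope is sum_g Sxy_g / sum_g Sxx_g; each intercept is
    b_g = mean(y_g) - m * mean(x_g).  Refuses (raising
    :class:`HeterogeneousSlopesError`) when the homogeneity test rejects at
    ``alpha_homogeneity``, unless ``force`` is set — then a warning is
    emitted and ``forced`` is recorded on the fit.
    """
    homogeneity = test_homogeneity(data)
    forced = False
    if homogeneity.p_value < alpha_homogeneity:
        if not force:
            raise HeterogeneousSlopesError(
                "slopes are heterogeneous (interaction p="
                f"{homogeneity.p_value:.4g} < {alpha_homogeneity}); parallel"
                " lines cannot be assumed and ANCOVA is not appropriate."
                " Pass force=True to fit anyway.",
                homogeneity,
            )
        warnings.warn(
            "fitting a common slope despite heterogeneous slopes"
            f" (interaction p={homogeneity.p_value:.4g}); interpret"
            " contrasts with caution",
            UserWarning,
            stacklevel=2,
        )
        forced = True

    n, k = data.n_total, data.k
    m, intercepts, rss, sxx_tot = _common_slope_parts(data)
    df_resid = n - (k + 1)
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    return AncovaFit(
        m_common=m,
        intercepts=intercepts,
        mse=rss / df_resid,
        df_resid=df_resid,
        group_ns={g: x.size for g, (x, _) in data.groups.items()},
        homogeneity=homogeneity,
        group_x_means={g: float(x.mean()) for g, (x, _) in data.groups.items()},
        sxx_pooled=sxx_tot,
        forced=forced,
    )


def _n_comparisons(fit: AncovaFit) -> int:
    k = len(fit.intercepts)
    return k * (k - 1) // 2


def contrast(
    fit: AncovaFit,
    group_i: str,
    group_j: str,
    conf_level: float = 0.95,
    adjustment: "Adjustment | str" = Adjustment.NONE,
) -> Contrast:
    """Pairwise expression contrast between two groups.

    diff = b_i - b_j with the standard adjusted-means standard error

        SE^2 = MSE * (1/n_i + 1/n_j + (x̄_i - x̄_j)^2 / Sxx_pooled)

    which collapses to MSE*(1/n_i + 1/n_j) when the groups share the same
    covariate mean.  The t interval on the residual df back-transforms to a
    ratio interval via R = 10**(-diff).  Bonferroni/Sidak adjust both the
    interval level and the p-value for k(k-1)/2 comparisons.
    """
    adjustment = Adjustment(adjustment)
    if not 0.0 < conf_level < 1.0:
        raise ValidationError(f"conf_level must be in (0, 1), got {conf_level!r}")
    for g in (group_i, group_j):
        if g not in fit.intercepts:
            raise ValidationError(f"unknown group label {g!r}")

    diff = fit.intercepts[group_i] - fit.intercepts[group_j]
    ni, nj = fit.group_ns[group_i], fit.group_ns[group_j]
    dx = fit.group_x_means[group_i] - fit.group_x_means[group_j]
    se = math.sqrt(fit.mse * (1.0 / ni + 1.0 / nj + dx * dx / fit.sxx_pooled))

    alpha = 1.0 - conf_level
    m_comp = _n_comparisons(fit)
    if adjustment is Adjustment.BONFERRONI and m_comp > 1:
        alpha_eff = alpha / m_comp
    elif adjustment is Adjustment.SIDAK and m_comp > 1:
        alpha_eff = 1.0 - (1.0 - alpha) ** (1.0 / m_comp)
    else:
        alpha_eff = alpha

    if se == 0.0:
        lo = hi = diff
        p_raw = 1.0 if diff == 0.0 else 0.0
    else:
        tcrit = float(stats.t.ppf(1.0 - alpha_eff / 2.0, fit.df_resid))
        lo, hi = diff - tcrit * se, diff + tcrit * se
        p_raw = float(2.0 * stats.t.sf(abs(diff / se), fit.df_resid))

    if adjustment is Adjustment.BONFERRONI and m_comp > 1:
        p = min(1.0, p_raw * m_comp)
    elif adjustment is Adjustment.SIDAK and m_comp > 1:
        p = 1.0 - (1.0 - p_raw) ** m_comp
    else:
        p = p_raw

    return Contrast(
        group_i=group_i,
        group_j=group_j,
        diff=diff,
        ci=(lo, hi),
        p_value=p,
        r_hat=10.0 ** (-diff),
        r_ci=(10.0 ** (-hi), 10.0 ** (-lo)),
        adjustment=adjustment,
        conf_level=conf_level,
    )


def all_contrasts(
    fit: AncovaFit,
    conf_level: float = 0.95,
    adjustment: "Adjustment | str" = Adjustment.NONE,
) -> list:
    """Every ordered-by-appearance pair (i before j in the fit) once."""
    names = list(fit.intercepts)
    return [
        contrast(fit, names[i], names[j], conf_level, adjustment)
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
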