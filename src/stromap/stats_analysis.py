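"""Statistical procedures of the analysis: ordinary least squares with a
no-correlation slope test, log-log power-law fits, the Welch t-test for
unequal-variance samples, and the collagenase pre/post and residual
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RegressionResult",
    "PowerLawFit",
    "WelchResult",
    "PrePostRecord",
    "CollagenaseSummary",
    "linear_regression",
    "power_law_fit",
    "welch_t_test",
    "collagenase_effect",
    "residual_comparison",
    "per_group_means",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit y = slope*x + intercept with the two-sided p-value for the
    slope under the null of no correlation."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=np.float64) + self.intercept


@dataclass(frozen=True)
class PowerLawFit:
    """Fit y = prefactor * x**exponent obtained by OLS on natural logs."""

    exponent: float
    prefactor: float
    r2: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError(f"prefactor must be > 0, got {self.prefactor}")

    def predict(self, x) -> np.ndarray:
        return self.prefactor * np.asarray(x, dtype=np.float64) ** self.exponent


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float


@dataclass(frozen=True)
class PrePostRecord:
    """TTP at one tumor before and after collagenase administration."""

    tumor_id: str
    ttp_pre_mmHg: float
    ttp_post_mmHg: float


@dataclass(frozen=True)
class CollagenaseSummary:
    percent_changes: tuple[float, ...]
    mean_percent_change: float
    n_decreased: int
    n: int


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return x, y


def linear_regression(x, y) -> RegressionResult:
    """OLS regression of y on x with R^2 and the slope's two-sided t-test.

    Requires at least 3 points and nonzero variance in x.
    """
    x, y = _as_xy(x, y)
    if len(x) < 3:
        raise ValueError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression is degenerate")
    res = _stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )


def power_law_fit(x, y) -> PowerLawFit:
    """Fit y = a * x^b by linear regression on the natural logarithms.

    The exponent is the slope of ln y on ln x; the prefactor is
    exp(intercept); R^2 and p come from that log-log regression.
    """
    x, y = _as_xy(x, y)
    bad = np.flatnonzero((x <= 0) | (y <= 0))
    if bad.size:
        raise ValueError(
            f"power-law fit requires positive data; offending indices: {bad.tolist()}"
        )
    reg = linear_regression(np.log(x), np.log(y))
    return PowerLawFit(
        exponent=reg.slope,
        prefactor=float(np.exp(reg.intercept)),
        r2=reg.r2,
        p_value=reg.p_value,
        n=reg.n,
    )


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom
    and a two-sided p-value."""
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = _stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p_value=float(res.pvalue))


def collagenase_effect(records: list[PrePostRecord]) -> CollagenaseSummary:
    """Per-tumor percent TTP change 100*(post - pre)/pre and its mean."""
    if not records:
        raise ValueError("no pre/post records supplied")
    changes = []
    for r in records:
        if r.ttp_pre_mmHg <= 0:
            raise ValueError(
                f"tumor {r.tumor_id!r}: pre-treatment TTP must be > 0"
            )
        changes.append(100.0 * (r.ttp_post_mmHg - r.ttp_pre_mmHg) / r.ttp_pre_mmHg)
    return CollagenaseSummary(
        percent_changes=tuple(changes),
        mean_percent_change=float(np.mean(changes)),
        n_decreased=int(sum(c < 0 for c in changes)),
        n=len(changes),
    )


def residual_comparison(
    reference_fit: RegressionResult | PowerLawFit,
    untreated_points: tuple,
    treated_points: tuple,
) -> tuple[np.ndarray, np.ndarray, WelchResult]:
    """Residuals of both groups against a fit calibrated on the untreated
    group, plus a Welch t-test between the residual sets.

    Each points argument is ``(x, y)``.  Residual = observed - predicted,
    so a positive residual means uptake above the untreated trend.
    """
    xu, yu = _as_xy(*untreated_points)
    xt, yt = _as_xy(*treated_points)
    res_u = yu - reference_fit.predict(xu)
    res_t = yt - reference_fit.predict(xt)
    return res_u, res_t, welch_t_test(res_u, res_t)


def per_group_means(groups, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-site values to per-group (per-tumor) means, preserving
    first-appearance group order.  Used when regressions are run on tumor
    means rather than pooled sites."""
    groups = np.asarray(groups)
    x, y = _as_xy(x, y)
    order = {g: i for i, g in enumerate(dict.fromkeys(groups.tolist()))}
    gx, gy = np.zeros(len(order)), np.zeros(len(order))
    for g, i in order.items():
        sel = groups == g
        gx[i], gy[i] = x[sel].mean(), y[sel].mean()
    return gx, gy
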