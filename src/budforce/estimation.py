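"""Apparent base temperature and thermal time from constant-temperature forcing.

The development rate of a floral bud population at a constant forcing
temperature ``T`` is taken as the reciprocal of the hours needed to reach a
0.5 bud-break fraction.  Over the sub-optimal temperature range the rate is
linear in temperature,

    D = (T - Tb) / theta,

so an ordinary least-squares fit of rate on temperature, ``D = m*T + b``,
yields the apparent base temperature as the x-intercept, ``Tb = -b/m``, and
the thermal-time requirement as the reciprocal slope, ``theta = 1/m`` (units
degree-Celsius-hours).  "Apparent" because Tb lies below the lowest forcing
temperature and is reached only by extrapolation.

Across accessions, Tb and theta are negatively related; the cross-accession
trend is summarized by the logarithmic curve ``Tb = a + c*ln(theta)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ForcingTimeCourse",
    "RatePoint",
    "ThermalTimeFit",
    "TbThetaCurve",
    "AccessionExclusion",
    "InsufficientTemperaturesError",
    "bud_break_fraction",
    "hours_to_half",
    "fit_rate_response",
    "estimate_accession",
    "fit_tb_theta_curve",
    "correlate",
]

HALF_BREAK_FRACTION = 0.5
MIN_POINTS = 3  # leaves one residual degree of freedom for R^2 and CIs


class InsufficientTemperaturesError(ValueError):
    """Fewer included rate points than the minimum needed for a fit."""


@dataclasses.dataclass(frozen=True)
class ForcingTimeCourse:
    """One accession x constant-forcing-temperature observation series.

    ``cum_open`` is cumulative because opened buds are removed at each
    observation, so the running count can only grow.
    """

    accession_id: str
    forcing_temp_c: float
    obs_hours: np.ndarray
    cum_open: np.ndarray
    n_initial: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "obs_hours", np.asarray(self.obs_hours, dtype=float))
        object.__setattr__(self, "cum_open", np.asarray(self.cum_open, dtype=float))
        if self.obs_hours.ndim != 1 or self.obs_hours.shape != self.cum_open.shape:
            raise ValueError("obs_hours and cum_open must be 1-d and equal length")
        if len(self.obs_hours) == 0:
            raise ValueError("empty time course")
        if np.any(np.diff(self.obs_hours) <= 0):
            raise ValueError("obs_hours must be strictly increasing")
        if np.any(np.diff(self.cum_open) < 0):
            raise ValueError("cum_open must be non-decreasing")
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if np.any(self.cum_open < 0) or np.any(self.cum_open > self.n_initial):
            raise ValueError("cum_open must lie in [0, n_initial]")


@dataclasses.dataclass(frozen=True)
class RatePoint:
    """Development rate at one forcing temperature.

    ``hours_to_half`` is None when the time course never reached a 0.5
    bud-break fraction; such points are excluded from the regression.
    """

    forcing_temp_c: float
    hours_to_half: float | None

    @property
    def included(self) -> bool:
        return self.hours_to_half is not None

    @property
    def rate(self) -> float | None:
        """Development rate D = 1/hours_to_half (h^-1)."""
        if self.hours_to_half is None:
            return None
        return 1.0 / self.hours_to_half


@dataclasses.dataclass(frozen=True)
class ThermalTimeFit:
    """Rate-temperature regression results for one accession.

    ``status`` is ``"ok"`` for a valid fit and ``"invalid_slope"`` when the
    slope is non-positive (no positive thermal time exists); in that case
    the derived quantities are NaN and the intervals are None.
    """

    accession_id: str
    m: float
    b: float
    apparent_tb_c: float
    thermal_time_ch: float
    r_squared: float
    n_points: int
    ci95_tb: tuple[float, float] | None
    ci95_theta: tuple[float, float] | None
    status: str = "ok"

    @property
    def valid(self) -> bool:
        return self.status == "ok"


@dataclasses.dataclass(frozen=True)
class AccessionExclusion:
    """Record of an accession dropped before fitting, with the reason."""

    accession_id: str
    reason: str
    n_reached: int
    n_courses: int


@dataclasses.dataclass(frozen=True)
class TbThetaCurve:
    """Cross-accession trend Tb = a + c * ln(theta)."""

    a: float
    c: float
    r_squared: float
    n: int

    def predict_tb(self, theta_ch: float | np.ndarray) -> float | np.ndarray:
        theta_ch = np.asarray(theta_ch, dtype=float)
        if np.any(theta_ch <= 0):
            raise ValueError("thermal time must be positive")
        out = self.a + self.c * np.log(theta_ch)
        return float(out) if out.ndim == 0 else out


def bud_break_fraction(tc: ForcingTimeCourse) -> np.ndarray:
    """Cumulative opened buds divided by the initial floral bud count."""
    if tc.n_initial == 0:
        raise ValueError("n_initial must be positive")
    return tc.cum_open / tc.n_initial


def hours_to_half(tc: ForcingTimeCourse) -> float | None:
    """Hours of forcing to reach a 0.5 bud-break fraction, or None.

    Linear interpolation between the first pair of observations bracketing
    0.5 (fraction = 0 at hour 0 is the implicit origin when the first
    observation already exceeds 0.5).  An observation exactly at 0.5
    returns its own time.  None signals that the combination never reached
    0.5 and must be excluded from the rate regression.
    """
    f = bud_break_fraction(tc)
    above = np.flatnonzero(f >= HALF_BREAK_FRACTION)
    if len(above) == 0:
        return None
    i = int(above[0])
    if f[i] == HALF_BREAK_FRACTION:
        return float(tc.obs_hours[i])
    if i == 0:
        t_lo, f_lo = 0.0, 0.0
    else:
        t_lo, f_lo = float(tc.obs_hours[i - 1]), float(f[i - 1])
    t_hi, f_hi = float(tc.obs_hours[i]), float(f[i])
    return t_lo + (HALF_BREAK_FRACTION - f_lo) * (t_hi - t_lo) / (f_hi - f_lo)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form simple OLS: slope, intercept, r^2, sxx, residual variance."""
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    m = float(dx @ (y - ybar)) / sxx
    b = float(ybar - m * xbar)
    resid = y - (m * x + b)
    rss = float(resid @ resid)
    tss = float((y - ybar) @ (y - ybar))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    sigma2 = rss / (n - 2) if n > 2 else float("nan")
    return m, b, r2, sxx, sigma2


def _bootstrap_cis(
    x: np.ndarray,
    m: float,
    b: float,
    sigma2: float,
    n_boot: int,
    seed: int,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Parametric residual bootstrap for Tb = -b/m and theta = 1/m.

    Both quantities are nonlinear in the regression coefficients, so
    percentile intervals from refitted synthetic data sets are used rather
    than a normal approximation.  Resamples whose slope is non-positive
    carry no positive thermal time and are discarded.
    """
    rng = np.random.default_rng(seed)
    yhat = m * x + b
    noise = rng.normal(0.0, math.sqrt(sigma2), size=(n_boot, len(x)))
    yb = yhat + noise
    xbar = x.mean()
    dx = x - xbar
    sxx = float(dx @ dx)
    mb = (yb - yb.mean(axis=1, keepdims=True)) @ dx / sxx
    bb = yb.mean(axis=1) - mb * xbar
    keep = mb > 0
    if keep.sum() < max(20, n_boot // 20):
        nan = (float("nan"), float("nan"))
        return nan, nan
    tb = -bb[keep] / mb[keep]
    theta = 1.0 / mb[keep]
    lo, hi = 2.5, 97.5
    return (
        tuple(np.percentile(tb, [lo, hi])),
        tuple(np.percentile(theta, [lo, hi])),
    )


def delta_method_cis(
    x: np.ndarray, m: float, b: float, sigma2: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """First-order (delta-method) 95% intervals for Tb and theta.

    Provided as a cross-check on the bootstrap; uses the t distribution
    with n-2 degrees of freedom.
    """
    n = len(x)
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    var_m = sigma2 / sxx
    var_b = sigma2 * (1.0 / n + xbar**2 / sxx)
    cov_mb = -sigma2 * xbar / sxx
    # Tb = -b/m: gradient (d/db, d/dm) = (-1/m, b/m^2)
    var_tb = var_b / m**2 + (b**2 / m**4) * var_m - 2.0 * (b / m**3) * cov_mb
    var_theta = var_m / m**4
    tcrit = stats.t.ppf(0.975, n - 2)
    tb = -b / m
    theta = 1.0 / m
    return (
        (tb - tcrit * math.sqrt(max(var_tb, 0.0)), tb + tcrit * math.sqrt(max(var_tb, 0.0))),
        (
            theta - tcrit * math.sqrt(max(var_theta, 0.0)),
            theta + tcrit * math.sqrt(max(var_theta, 0.0)),
        ),
    )


def fit_rate_response(
    points: Sequence[RatePoint],
    *,
    accession_id: str = "",
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ThermalTimeFit:
    """OLS of development rate on measured forcing temperature.

    Only included points enter; at least :data:`MIN_POINTS` are required.
    The regressors must be the measured chamber means, not the set points.
    A non-positive slope yields a fit marked ``invalid_slope`` (an
    extrapolated Tb below the lowest forcing temperature is expected and
    allowed; a negative slope is not interpretable as thermal time).
    """
    used = [p for p in points if p.included]
    if len(used) < MIN_POINTS:
        raise InsufficientTemperaturesError(
            f"need >= {MIN_POINTS} temperatures with rates, got {len(used)}"
        )
    x = np.array([p.forcing_temp_c for p in used], dtype=float)
    y = np.array([p.rate for p in used], dtype=float)
    m, b, r2, _, sigma2 = _ols(x, y)
    if m <= 0:
        return ThermalTimeFit(
            accession_id=accession_id,
            m=m,
            b=b,
            apparent_tb_c=float("nan"),
            thermal_time_ch=float("nan"),
            r_squared=r2,
            n_points=len(used),
            ci95_tb=None,
            ci95_theta=None,
            status="invalid_slope",
        )
    if ci_method == "bootstrap":
        ci_tb, ci_theta = _bootstrap_cis(x, m, b, sigma2, n_boot, seed)
    elif ci_method == "delta":
        ci_tb, ci_theta = delta_method_cis(x, m, b, sigma2)
    elif ci_method is None or ci_method == "none":
        ci_tb = ci_theta = None
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ThermalTimeFit(
        accession_id=accession_id,
        m=m,
        b=b,
        apparent_tb_c=-b / m,
        thermal_time_ch=1.0 / m,
        r_squared=r2,
        n_points=len(used),
        ci95_tb=ci_tb,
        ci95_theta=ci_theta,
    )


def estimate_accession(
    tcs: Sequence[ForcingTimeCourse],
    *,
    min_points: int = MIN_POINTS,
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ThermalTimeFit | AccessionExclusion:
    """Estimate (Tb, theta) for one accession from its per-temperature courses.

    Temperature treatments whose bud-break fraction never reached 0.5 are
    dropped; if fewer than ``min_points`` treatments remain the accession
    is excluded with a reason instead of fitted.
    """
    if not tcs:
        raise ValueError("no time courses supplied")
    ids = {tc.accession_id for tc in tcs}
    if len(ids) != 1:
        raise ValueError(f"time courses mix accessions: {sorted(ids)}")
    accession_id = ids.pop()
    points = [RatePoint(tc.forcing_temp_c, hours_to_half(tc)) for tc in tcs]
    n_reached = sum(p.included for p in points)
    if n_reached < min_points:
        return AccessionExclusion(
            accession_id=accession_id,
            reason=(
                f"insufficient temperatures: reached 0.5 bud break in "
                f"{n_reached} of {len(points)} treatments (minimum {min_points})"
            ),
            n_reached=n_reached,
            n_courses=len(points),
        )
    return fit_rate_response(
        points, accession_id=accession_id, n_boot=n_boot, seed=seed, ci_method=ci_method
    )


def fit_tb_theta_curve(
    tb_c: Iterable[float], theta_ch: Iterable[float]
) -> TbThetaCurve:
    """Fit the cross-accession trend Tb = a + c * ln(theta) by OLS.

    Used to place hypothetical heat-requirement trait combinations on the
    observed Tb-theta line for simulation scenarios.
    """
    tb = np.asarray(list(tb_c), dtype=float)
    theta = np.asarray(list(theta_ch), dtype=float)
    if tb.shape != theta.shape or tb.ndim != 1:
        raise ValueError("tb_c and theta_ch must be 1-d and equal length")
    if len(tb) < 3:
        raise ValueError("need at least 3 accessions to fit the Tb-theta curve")
    if np.any(theta <= 0):
        raise ValueError("all thermal times must be positive")
    c, a, r2, _, _ = _ols(np.log(theta), tb)
    return TbThetaCurve(a=a, c=c, r_squared=r2, n=len(tb))


def correlate(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-test p-value."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)
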