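"""Seeded generators for forcing experiments and hourly winter weather.

Both generators exist so that estimation and simulation can be exercised,
calibrated and validated without any external data.  They encode the study
conditions of the forcing-experiment design they emulate: 100-150 floral
buds per accession x temperature combination (default 125), five constant
forcing temperatures at the measured chamber means 11.8, 13.6, 15.9, 17.8
and 20.1 C, and observations a few times per week.

Forcing model
-------------
Bud ``i`` at constant temperature ``T`` opens when its elapsed heat units
``(T - Tb) * t`` reach a personal threshold ``theta_i``.  Thresholds are
drawn log-normal with median equal to the accession's true thermal time and
a configurable coefficient of variation — any smooth positive threshold
distribution produces the sigmoidal cumulative bud-break curves seen in
forcing experiments, and the log-normal keeps every threshold positive.
Counts are cumulative by construction (opened buds are removed from the
stems at each observation in the protocol being emulated).

Weather model
-------------
Hourly temperature is an annual sinusoid (minimum in mid-January) plus a
diurnal sinusoid (minimum pre-dawn, about 05:00) plus stationary AR(1)
Gaussian noise, emitted for each dormancy season 01 October - 30 June.
The defaults approximate a humid-subtropical winter of the southeastern
United States piedmont: annual mean 15.5 C with 9 C annual and 5 C diurnal
amplitude gives January nights near 1.5 C and days near 11.5 C, producing
seasonal chill-hour totals in the 1000-1500 h range typical of that region.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .estimation import ForcingTimeCourse
from .weather import HourlyWeatherSeries, season_window

__all__ = [
    "MEASURED_CHAMBER_TEMPS_C",
    "ForcingSimConfig",
    "WeatherSimConfig",
    "gen_forcing_experiment",
    "gen_weather",
    "forcing_to_frame",
]

#: measured chamber means of the five warm-forcing treatments (C)
MEASURED_CHAMBER_TEMPS_C = (11.8, 13.6, 15.9, 17.8, 20.1)


@dataclasses.dataclass(frozen=True)
class ForcingSimConfig:
    """Configuration for one synthetic accession's forcing experiment.

    ``obs_pattern`` is the repeating cycle of hours between observations;
    the default single 48-h interval approximates observation three times a
    week, and ``(48, 48, 72)`` reproduces a strict Mon/Wed/Fri visit
    pattern.  The first observation falls 24 h after setup.  Observations
    continue until three consecutive visits show no change (the stopping
    rule of the emulated protocol), up to ``max_obs`` visits.
    """

    true_tb_c: float
    true_theta_ch: float
    theta_cv: float = 0.15
    n_buds: int = 125
    temps_c: tuple[float, ...] = MEASURED_CHAMBER_TEMPS_C
    obs_pattern: tuple[float, ...] = (48.0,)
    first_obs_h: float = 24.0
    max_obs: int = 120
    seed: int = 0
    accession_id: str = "SYN001"

    def __post_init__(self) -> None:
        if self.theta_cv < 0:
            raise ValueError("theta_cv must be >= 0")
        if self.n_buds < 1:
            raise ValueError("n_buds must be >= 1")
        if self.true_theta_ch <= 0:
            raise ValueError("true_theta_ch must be positive")
        if not self.obs_pattern or any(dt <= 0 for dt in self.obs_pattern):
            raise ValueError("obs_pattern must be positive intervals")


@dataclasses.dataclass(frozen=True)
class WeatherSimConfig:
    """Synthetic hourly winter weather configuration (units: C, hours)."""

    annual_mean_c: float = 15.5
    annual_amplitude_c: float = 9.0
    diurnal_amplitude_c: float = 5.0
    ar1_coef: float = 0.8
    noise_sd_c: float = 3.0
    n_seasons: int = 1
    start_year: int = 1990
    seed: int = 0
    station_id: str = "SYN"

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if self.n_seasons < 1:
            raise ValueError("n_seasons must be >= 1")


def _observation_grid(cfg: ForcingSimConfig, horizon_h: float) -> np.ndarray:
    """Observation times from first visit until just past ``horizon_h``."""
    times = [cfg.first_obs_h]
    k = 0
    while times[-1] < horizon_h and len(times) < cfg.max_obs:
        times.append(times[-1] + cfg.obs_pattern[k % len(cfg.obs_pattern)])
        k += 1
    return np.asarray(times)


def gen_forcing_experiment(cfg: ForcingSimConfig) -> list[ForcingTimeCourse]:
    """Simulate one accession's bud-break time courses, one per temperature.

    Per-bud thresholds theta_i are log-normal with median
    ``true_theta_ch`` and coefficient of variation ``theta_cv``; bud i at
    temperature T opens at t_i = theta_i / (T - true_tb_c).  Cumulative
    open counts are read off the observation grid, which extends three
    observation intervals past the last opening (emulating the
    no-change-for-three-visits stopping rule).  A treatment at or below
    the true base temperature never opens any bud and yields an all-zero
    course over a fixed long horizon, exercising exclusion paths
    downstream.  Identical configuration (including seed) gives identical
    output.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cfg.theta_cv**2))
    courses: list[ForcingTimeCourse] = []
    tail_h = 3 * max(cfg.obs_pattern)
    for temp in cfg.temps_c:
        thresholds = cfg.true_theta_ch * np.exp(rng.normal(0.0, sigma, cfg.n_buds))
        if temp <= cfg.true_tb_c:
            grid = _observation_grid(cfg, 1500.0)
            counts = np.zeros_like(grid)
        else:
            open_at = np.sort(thresholds / (temp - cfg.true_tb_c))
            grid = _observation_grid(cfg, open_at[-1] + tail_h)
            counts = np.searchsorted(open_at, grid, side="right").astype(float)
        courses.append(
            ForcingTimeCourse(
                accession_id=cfg.accession_id,
                forcing_temp_c=temp,
                obs_hours=grid,
                cum_open=counts,
                n_initial=cfg.n_buds,
            )
        )
    return courses


def forcing_to_frame(courses: list[ForcingTimeCourse]) -> pd.DataFrame:
    """Long-format table `accession,temp_c,obs_hour,cum_open,n_initial`."""
    parts = []
    for tc in courses:
        parts.append(
            pd.DataFrame(
                {
                    "accession": tc.accession_id,
                    "temp_c": tc.forcing_temp_c,
                    "obs_hour": tc.obs_hours,
                    "cum_open": tc.cum_open.astype(int),
                    "n_initial": tc.n_initial,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def gen_weather(cfg: WeatherSimConfig) -> HourlyWeatherSeries:
    """Generate regular hourly temperatures for ``n_seasons`` dormancy seasons.

    T(t) = annual sinusoid + diurnal sinusoid + AR(1) noise.  The annual
    component reaches its minimum on 15 January and the diurnal component
    at 05:00; the AR(1) noise is stationary with marginal standard
    deviation ``noise_sd_c`` and is drawn independently per season (seasons
    are separated by an unmodelled summer anyway).  Output is already
    regular: exactly one finite value per hour, no imputation.
    """
    rng = np.random.default_rng(cfg.seed)
    idx_parts: list[pd.DatetimeIndex] = []
    temp_parts: list[np.ndarray] = []
    for k in range(cfg.n_seasons):
        year = cfg.start_year + k
        start, end = season_window(year)
        idx = pd.date_range(start, end, freq="h")
        doy = idx.dayofyear.to_numpy()
        hod = idx.hour.to_numpy()
        annual = cfg.annual_mean_c - cfg.annual_amplitude_c * np.cos(
            2.0 * np.pi * (doy - 15) / 365.25
        )
        diurnal = -cfg.diurnal_amplitude_c * np.cos(2.0 * np.pi * (hod - 5) / 24.0)
        noise = _ar1_noise(rng, len(idx), cfg.ar1_coef, cfg.noise_sd_c)
        idx_parts.append(idx)
        temp_parts.append(annual + diurnal + noise)
    timestamps = idx_parts[0].append(idx_parts[1:]) if len(idx_parts) > 1 else idx_parts[0]
    temps = np.concatenate(temp_parts)
    return HourlyWeatherSeries(
        station_id=cfg.station_id,
        timestamps=timestamps,
        temp_c=temps,
        imputed=np.zeros(len(temps), dtype=bool),
        regular=True,
    )


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, n - 1)
    # lfilter-equivalent recursion; explicit loop avoided for speed
    if phi == 0.0:
        e[1:] = shocks
        return e
    from scipy.signal import lfilter

    e[1:] = lfilter([1.0], [1.0, -phi], shocks, zi=np.array([phi * e[0]]))[0]
    return e
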