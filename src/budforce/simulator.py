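"""Weather-driven bud-break phenology: chill hours, then growing degree hours.

The model is strictly sequential.  From the 01 October season start,
chilling accumulates as whole hours with air temperature strictly below
7.2 degrees C (the classic chill-hour model).  Once a stated chilling total
(500, 750 or 1000 h) is reached, heat accumulates as growing degree hours
(GDH): each hour contributes max(T - Tb, 0) degree-hours above the
trait-specific base temperature Tb.  Bud break is predicted at the first
hour at which the GDH running total reaches the thermal-time requirement
theta.  Warmth before chilling satisfaction contributes nothing, and chill
after it is ignored.

Each hourly value is credited at the end of its hour, so with a constant
temperature T > Tb the predicted interval from heat-accumulation start to
bud break is ceil(theta / (T - Tb)) hours — within one hour of the
continuous closed form theta / (T - Tb).

Scenario comparison expresses each trait combination's bud-break time as a
signed delay in fractional days relative to a reference combination,
per season and per chilling threshold; seasons in which the threshold is
never reached, or in which the reference does not complete by 30 June, are
omitted rather than extrapolated.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .weather import HourlyWeatherSeries

__all__ = [
    "CHILL_THRESHOLD_C",
    "HRTraits",
    "chill_hours",
    "chill_threshold_time",
    "accumulate_gdh",
    "budbreak_time",
    "compare_traits",
]

logger = logging.getLogger(__name__)

#: chill-hour model boundary: hours strictly below this count as chilling
CHILL_THRESHOLD_C = 7.2

_HOUR = pd.Timedelta(hours=1)


@dataclasses.dataclass(frozen=True)
class HRTraits:
    """Heat-requirement trait combination: base temperature and thermal time."""

    tb_c: float
    theta_ch: float

    def __post_init__(self) -> None:
        if not self.theta_ch > 0:
            raise ValueError("theta_ch must be positive")

    def label(self) -> str:
        return f"Tb={self.tb_c:g}C, theta={self.theta_ch:g}C.h"


def _season_arrays(
    w: HourlyWeatherSeries, season_year: int
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    if not w.regular:
        raise ValueError("weather series must be regularized before simulation")
    if season_year in w.invalid_seasons:
        raise ValueError(f"season {season_year} is flagged invalid (gappy record)")
    return w.season_slice(season_year)


def chill_hours(w: HourlyWeatherSeries, season_year: int) -> pd.Series:
    """Running chill-hour total for one season.

    Indexed by hour start; the value at index t counts hours strictly below
    7.2 C among hours [season start, t], i.e. the total credited at the end
    of hour t.  Non-decreasing with per-hour increments of 0 or 1.
    """
    idx, temps = _season_arrays(w, season_year)
    return pd.Series(np.cumsum(temps < CHILL_THRESHOLD_C), index=idx, name="chill_h")


def chill_threshold_time(
    w: HourlyWeatherSeries, season_year: int, threshold_h: int
) -> pd.Timestamp | None:
    """Instant at which the chill total first reaches ``threshold_h``.

    The returned instant is the end of the hour completing the count (with
    a constant 5 C season the 500-hour threshold is reached exactly 500
    hours after season start).  None when the season never accumulates the
    threshold — expected in warm winters, and such seasons are skipped.
    """
    cum = chill_hours(w, season_year)
    total = cum.to_numpy()
    if total[-1] < threshold_h:
        return None
    pos = int(np.searchsorted(total, threshold_h, side="left"))
    return cum.index[pos] + _HOUR


def accumulate_gdh(
    w: HourlyWeatherSeries,
    season_year: int,
    start: pd.Timestamp,
    tb_c: float,
) -> pd.Series:
    """Running GDH total from ``start`` to the season end.

    Each hour with timestamp >= start contributes max(T - tb_c, 0)
    degree-hours, credited at the end of that hour.
    """
    idx, temps = _season_arrays(w, season_year)
    sel = idx >= pd.Timestamp(start)
    gdh = np.maximum(temps[sel] - tb_c, 0.0)
    return pd.Series(np.cumsum(gdh), index=idx[sel], name="gdh_ch")


def budbreak_time(
    w: HourlyWeatherSeries,
    season_year: int,
    start: pd.Timestamp,
    traits: HRTraits,
) -> pd.Timestamp | None:
    """First instant at which accumulated GDH reaches the requirement.

    None when the season ends (30 June) before theta is reached.
    """
    cum = accumulate_gdh(w, season_year, start, traits.tb_c)
    if len(cum) == 0:
        return None
    total = cum.to_numpy()
    if total[-1] < traits.theta_ch:
        return None
    pos = int(np.searchsorted(total, traits.theta_ch, side="left"))
    return cum.index[pos] + _HOUR


def _gdh_start(chill_time: pd.Timestamp, dialect: str) -> pd.Timestamp:
    if dialect == "hour":
        return chill_time
    if dialect == "midnight":
        return chill_time.normalize()
    raise ValueError(f"unknown gdh_start dialect {dialect!r}")


def compare_traits(
    w: HourlyWeatherSeries,
    thresholds: Iterable[int],
    scenarios: Sequence[HRTraits],
    reference: HRTraits,
    *,
    gdh_start: str = "hour",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bud-break delay of each trait combination relative to a reference.

    For every valid season x chilling threshold x scenario the delay is
    (scenario bud break - reference bud break) in signed fractional days;
    positive means later bud break.  Seasons where the chilling threshold
    is not reached, or where the reference does not complete, are omitted
    (with a log notice).

    Returns
    -------
    results : DataFrame
        One row per season x threshold x scenario with chilling and
        bud-break instants and the delay (NaN when the scenario itself
        does not complete).
    summary : DataFrame
        Per station x threshold x scenario: median/min/max delay, the
        number of completing seasons, and a two-sided Wilcoxon signed-rank
        p-value for the paired per-season delays against zero (reported as
        an assumption-laden convenience; NaN when degenerate).
    """
    rows: list[dict] = []
    for year in w.seasons():
        if year in w.invalid_seasons:
            logger.info("season %s at %s skipped: invalid record", year, w.station_id)
            continue
        for thr in thresholds:
            chill_at = chill_threshold_time(w, year, thr)
            if chill_at is None:
                logger.info(
                    "season %s at %s skipped for %d CH: threshold never reached",
                    year, w.station_id, thr,
                )
                continue
            start = _gdh_start(chill_at, gdh_start)
            ref_bb = budbreak_time(w, year, start, reference)
            if ref_bb is None:
                logger.warning(
                    "season %s at %s, %d CH skipped: reference %s did not complete",
                    year, w.station_id, thr, reference.label(),
                )
                continue
            for sc in scenarios:
                bb = budbreak_time(w, year, start, sc)
                delay = (bb - ref_bb) / pd.Timedelta(days=1) if bb is not None else np.nan
                rows.append(
                    {
                        "station_id": w.station_id,
                        "season_year": year,
                        "chill_threshold_h": int(thr),
                        "tb_c": sc.tb_c,
                        "theta_ch": sc.theta_ch,
                        "chill_reached_at": chill_at,
                        "budbreak_at": bb,
                        "delay_days": delay,
                    }
                )
    results = pd.DataFrame(
        rows,
        columns=[
            "station_id", "season_year", "chill_threshold_h", "tb_c", "theta_ch",
            "chill_reached_at", "budbreak_at", "delay_days",
        ],
    )
    summary = _summarize(results)
    return results, summary


def _summarize(results: pd.DataFrame) -> pd.DataFrame:
    if results.empty:
        return pd.DataFrame(
            columns=[
                "station_id", "chill_threshold_h", "tb_c", "theta_ch",
                "n_seasons", "median_delay_days", "min_delay_days",
                "max_delay_days", "wilcoxon_p",
            ]
        )
    out = []
    keys = ["station_id", "chill_threshold_h", "tb_c", "theta_ch"]
    for key, grp in results.groupby(keys, sort=True):
        delays = grp["delay_days"].dropna().to_numpy()
        rec = dict(zip(keys, key))
        rec["n_seasons"] = len(delays)
        if len(delays):
            rec["median_delay_days"] = float(np.median(delays))
            rec["min_delay_days"] = float(delays.min())
            rec["max_delay_days"] = float(delays.max())
            rec["wilcoxon_p"] = _wilcoxon_p(delays)
        else:
            rec["median_delay_days"] = np.nan
            rec["min_delay_days"] = np.nan
            rec["max_delay_days"] = np.nan
            rec["wilcoxon_p"] = np.nan
        out.append(rec)
    return pd.DataFrame(out)


def _wilcoxon_p(delays: np.ndarray) -> float:
    """Two-sided signed-rank p for paired delays vs zero; NaN when degenerate."""
    if len(delays) < 2 or np.all(delays == 0):
        return float("nan")
    try:
        return float(stats.wilcoxon(delays, zero_method="zsplit").pvalue)
    except ValueError:
        return float("nan")
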