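"""Hourly air-temperature series: reading, validation, and regularization.

A *season* is the dormancy-to-bloom window running from 01 October of year
``y`` through 30 June of year ``y+1``; chilling accumulation is anchored at
the 01 October season start.  All timestamps are interpreted as local
standard time with no daylight-saving shifts: phenological accumulations
are sums over hours, so a fixed one-hour offset is immaterial, but mixed
conventions would corrupt season boundaries.

Two on-disk dialects are supported:

``simple_csv``
    Header ``timestamp,temp_c`` with ISO-8601 timestamps and air
    temperature in degrees Celsius.

``isd_lite``
    The NOAA ISD-Lite whitespace-delimited layout: year, month, day, hour,
    then air temperature in tenths of a degree Celsius with ``-9999`` as
    the missing-value sentinel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HourlyWeatherSeries",
    "read_hourly_table",
    "regularize_hourly",
    "season_year",
    "season_window",
]

#: months that belong to no season (the July-September off-season)
_OFF_SEASON_MONTHS = (7, 8, 9)


def season_year(ts: pd.Timestamp) -> int | None:
    """Season label for a timestamp: the calendar year of its 01 October start.

    Hours in July-September fall outside every season and map to ``None``.
    """
    if ts.month in _OFF_SEASON_MONTHS:
        return None
    return ts.year if ts.month >= 10 else ts.year - 1


def season_window(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive hourly bounds of the season starting 01 October of ``year``."""
    return pd.Timestamp(year, 10, 1, 0), pd.Timestamp(year + 1, 6, 30, 23)


def _season_years_of(index: pd.DatetimeIndex) -> np.ndarray:
    """Vectorized season labels; off-season hours get the sentinel -1."""
    years = np.where(index.month >= 10, index.year, index.year - 1)
    years = np.where(np.isin(index.month, _OFF_SEASON_MONTHS), -1, years)
    return years.astype(np.int64)


@dataclasses.dataclass
class HourlyWeatherSeries:
    """Hourly air temperatures for one station across one or more seasons.

    Parameters
    ----------
    station_id
        Text label for the originating station.
    timestamps
        Strictly increasing observation instants.  After regularization
        these are exactly hourly within each season.
    temp_c
        Air temperature in degrees Celsius per instant; ``NaN`` marks a
        missing raw reading (never present after regularization).
    imputed
        Flags hours whose value was gap-filled rather than observed.
    regular
        True once :func:`regularize_hourly` has produced exactly one finite
        value per clock hour per season.
    invalid_seasons
        Season years whose record is too gappy to simulate on (a single
        gap longer than the permitted maximum, or more than 5% of hours
        imputed); the simulator refuses these.
    """

    station_id: str
    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray
    imputed: np.ndarray
    regular: bool = False
    invalid_seasons: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if not (len(self.timestamps) == len(self.temp_c) == len(self.imputed)):
            raise ValueError("timestamps, temp_c and imputed must be equal length")
        if len(self.timestamps) and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        self.invalid_seasons = frozenset(self.invalid_seasons)
        if self.regular and not np.all(np.isfinite(self.temp_c)):
            raise ValueError("a regularized series must be finite everywhere")

    def __len__(self) -> int:
        return len(self.timestamps)

    def seasons(self) -> list[int]:
        """Season years with at least one in-season hour, ascending."""
        years = _season_years_of(self.timestamps)
        return sorted(int(y) for y in np.unique(years) if y >= 0)

    def season_valid(self, year: int) -> bool:
        return year not in self.invalid_seasons and year in self.seasons()

    def season_mask(self, year: int) -> np.ndarray:
        return _season_years_of(self.timestamps) == year

    def season_slice(self, year: int) -> tuple[pd.DatetimeIndex, np.ndarray]:
        """Timestamps and temperatures of one season (no validity check)."""
        m = self.season_mask(year)
        if not m.any():
            raise KeyError(f"no data for season {year}")
        return self.timestamps[m], self.temp_c[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "temp_c": self.temp_c, "imputed": self.imputed}
        )


def read_hourly_table(
    path: str | Path, dialect: str = "simple_csv", station_id: str | None = None
) -> HourlyWeatherSeries:
    """Read a raw (possibly irregular) hourly temperature table.

    Missing sentinels are converted to ``NaN``; rows are sorted ascending by
    time.  No regularization is applied — pass the result through
    :func:`regularize_hourly` before simulation.

    Raises
    ------
    ValueError
        On an empty file or an unparseable row (the message carries the
        1-based line number).
    """
    path = Path(path)
    if station_id is None:
        station_id = path.stem
    if dialect == "simple_csv":
        ts, temp = _read_simple_csv(path)
    elif dialect == "isd_lite":
        ts, temp = _read_isd_lite(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    order = np.argsort(ts.to_numpy(), kind="stable")
    return HourlyWeatherSeries(
        station_id=station_id,
        timestamps=ts[order],
        temp_c=temp[order],
        imputed=np.zeros(len(order), dtype=bool),
    )


def _read_simple_csv(path: Path) -> tuple[pd.DatetimeIndex, np.ndarray]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = {"timestamp", "temp_c"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        line = int(ts.index[ts.isna()][0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: unparseable timestamp at line {line}")
    temp = pd.to_numeric(df["temp_c"], errors="coerce")
    # blank cells are missing readings; non-numeric garbage is an error
    garbage = temp.isna() & df["temp_c"].notna() & (df["temp_c"].astype(str).str.strip() != "")
    if garbage.any():
        line = int(garbage.index[garbage][0]) + 2
        raise ValueError(f"{path}: unparseable temperature at line {line}")
    return pd.DatetimeIndex(ts), temp.to_numpy(dtype=float)


def _read_isd_lite(path: Path) -> tuple[pd.DatetimeIndex, np.ndarray]:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected >=5 whitespace-separated columns")
    parts = {}
    for i, name in enumerate(("year", "month", "day", "hour")):
        col = pd.to_numeric(df[i], errors="coerce")
        if col.isna().any():
            line = int(col.index[col.isna()][0]) + 1
            raise ValueError(f"{path}: unparseable {name} at line {line}")
        parts[name] = col.astype(int)
    try:
        ts = pd.to_datetime(pd.DataFrame(parts))
    except (ValueError, pd.errors.OutOfBoundsDatetime) as exc:
        raise ValueError(f"{path}: invalid date field ({exc})") from None
    raw = pd.to_numeric(df[4], errors="coerce")
    if raw.isna().any():
        line = int(raw.index[raw.isna()][0]) + 1
        raise ValueError(f"{path}: unparseable temperature at line {line}")
    temp = raw.to_numpy(dtype=float)
    temp[temp <= -9999] = np.nan  # documented missing sentinel
    return pd.DatetimeIndex(ts), temp / 10.0


def _longest_true_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))


def regularize_hourly(raw: HourlyWeatherSeries, max_gap_h: int = 6) -> HourlyWeatherSeries:
    """Collapse a raw series onto an exact hourly grid, season by season.

    A reading at clock time [h:00, h+1:00) belongs to hour ``h``; multiple
    readings within an hour are replaced by their arithmetic mean.  Within
    each season the grid runs from the first to the last observed hour.
    Runs of missing hours are linearly interpolated in time and flagged
    imputed; a season containing any run longer than ``max_gap_h`` hours,
    or with more than 5% of its hours imputed, is marked invalid and will
    be skipped by the simulator.  Off-season hours (July-September) are
    dropped.

    The operation is idempotent: re-regularizing a regular series returns
    an identical series, with imputation flags and invalid seasons
    preserved.
    """
    if len(raw) == 0:
        raise ValueError("cannot regularize an empty series")
    in_season = _season_years_of(raw.timestamps) >= 0
    if not in_season.any():
        raise ValueError("no in-season (October-June) observations")
    hours = raw.timestamps[in_season].floor("h")
    temp = pd.Series(raw.temp_c[in_season], index=hours).groupby(level=0).mean()
    imput = pd.Series(raw.imputed[in_season], index=hours).groupby(level=0).any()

    years = _season_years_of(pd.DatetimeIndex(temp.index))
    invalid: set[int] = set(raw.invalid_seasons)
    idx_parts: list[pd.DatetimeIndex] = []
    temp_parts: list[np.ndarray] = []
    imp_parts: list[np.ndarray] = []
    for year in np.unique(years):
        sel = temp[years == year]
        observed = sel.dropna()
        if observed.empty:
            invalid.add(int(year))
            continue
        grid = pd.date_range(observed.index[0], observed.index[-1], freq="h")
        on_grid = sel.reindex(grid)
        missing = on_grid.isna().to_numpy()
        filled = on_grid.interpolate(method="time").to_numpy(dtype=float)
        prior = imput[years == year].reindex(grid).to_numpy()
        prior = np.where(pd.isna(prior), False, prior).astype(bool)
        imp = prior | missing
        if _longest_true_run(missing) > max_gap_h or imp.mean() > 0.05:
            invalid.add(int(year))
        idx_parts.append(grid)
        temp_parts.append(filled)
        imp_parts.append(imp)
    if not idx_parts:
        raise ValueError("no season contains any observed temperature")
    return HourlyWeatherSeries(
        station_id=raw.station_id,
        timestamps=idx_parts[0].append(idx_parts[1:]) if len(idx_parts) > 1 else idx_parts[0],
        temp_c=np.concatenate(temp_parts),
        imputed=np.concatenate(imp_parts),
        regular=True,
        invalid_seasons=frozenset(invalid),
    )


def write_simple_csv(w: HourlyWeatherSeries, path: str | Path) -> None:
    """Write the series in the ``simple_csv`` dialect (imputed flag dropped)."""
    pd.DataFrame({"timestamp": w.timestamps, "temp_c": w.temp_c}).to_csv(path, index=False)
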