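"""Pipeline orchestration: tables in, estimates and simulations out.

Connects the estimation, simulation and synthetic-data layers behind
plain CSV interfaces, and carries the auxiliary field-bloom regression
(day of 50% bloom against thermal-time requirement, per year).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .estimation import (
    AccessionExclusion,
    ForcingTimeCourse,
    TbThetaCurve,
    ThermalTimeFit,
    estimate_accession,
    fit_tb_theta_curve,
)
from .simulator import HRTraits

__all__ = [
    "RunConfig",
    "read_forcing_table",
    "run_estimate",
    "fits_frame",
    "exclusions_frame",
    "curve_from_fits",
    "build_scenarios",
    "bloom_trend_regression",
]

logger = logging.getLogger(__name__)

FORCING_COLUMNS = ["accession", "temp_c", "obs_hour", "cum_open", "n_initial"]


@dataclasses.dataclass
class RunConfig:
    """Top-level run configuration; every random step derives from ``seed``."""

    forcing_csv: str | None = None
    weather_csv: str | None = None
    scenarios_csv: str | None = None
    reference_tb_c: float = 2.2
    reference_theta_ch: float = 7000.0
    thresholds: tuple[int, ...] = (500, 750, 1000)
    gdh_start: str = "hour"
    out_dir: str = "budforce_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data:
            data["thresholds"] = tuple(int(t) for t in data["thresholds"])
        return cls(**data)

    @property
    def reference(self) -> HRTraits:
        return HRTraits(self.reference_tb_c, self.reference_theta_ch)


def read_forcing_table(source: str | Path | pd.DataFrame) -> dict[str, list[ForcingTimeCourse]]:
    """Parse the long-format forcing CSV into per-accession time courses.

    Expected columns: ``accession,temp_c,obs_hour,cum_open,n_initial``.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = set(FORCING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"forcing table missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError("forcing table has no rows")
    out: dict[str, list[ForcingTimeCourse]] = {}
    for (acc, temp), grp in df.groupby(["accession", "temp_c"], sort=True):
        grp = grp.sort_values("obs_hour")
        n_init = grp["n_initial"].unique()
        if len(n_init) != 1:
            raise ValueError(f"{acc} at {temp} C: n_initial is not constant")
        out.setdefault(str(acc), []).append(
            ForcingTimeCourse(
                accession_id=str(acc),
                forcing_temp_c=float(temp),
                obs_hours=grp["obs_hour"].to_numpy(dtype=float),
                cum_open=grp["cum_open"].to_numpy(dtype=float),
                n_initial=int(n_init[0]),
            )
        )
    return out


def run_estimate(
    source: str | Path | pd.DataFrame,
    *,
    seed: int = 0,
    min_points: int = 3,
    n_boot: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate (Tb, theta) per accession and report exclusions.

    Every accession in the input appears exactly once, either in the fits
    table or in the exclusion report.  Per-accession bootstrap seeds are
    spawned deterministically from ``seed``, so a repeated run is
    byte-identical.
    """
    cohort = read_forcing_table(source)
    fits: list[ThermalTimeFit] = []
    exclusions: list[AccessionExclusion] = []
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(cohort))]
    for (acc, courses), sub_seed in zip(sorted(cohort.items()), child_seeds):
        result = estimate_accession(
            courses, min_points=min_points, seed=sub_seed, n_boot=n_boot
        )
        if isinstance(result, AccessionExclusion):
            logger.info("excluded %s: %s", acc, result.reason)
            exclusions.append(result)
        else:
            fits.append(result)
    return fits_frame(fits), exclusions_frame(exclusions)


def fits_frame(fits: Sequence[ThermalTimeFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        tb_lo, tb_hi = f.ci95_tb if f.ci95_tb else (np.nan, np.nan)
        th_lo, th_hi = f.ci95_theta if f.ci95_theta else (np.nan, np.nan)
        rows.append(
            {
                "accession": f.accession_id,
                "n_points": f.n_points,
                "m": f.m,
                "b": f.b,
                "tb_c": f.apparent_tb_c,
                "theta_ch": f.thermal_time_ch,
                "r2": f.r_squared,
                "tb_lo": tb_lo,
                "tb_hi": tb_hi,
                "theta_lo": th_lo,
                "theta_hi": th_hi,
                "status": f.status,
            }
        )
    cols = [
        "accession", "n_points", "m", "b", "tb_c", "theta_ch", "r2",
        "tb_lo", "tb_hi", "theta_lo", "theta_hi", "status",
    ]
    return pd.DataFrame(rows, columns=cols)


def exclusions_frame(exclusions: Sequence[AccessionExclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": e.accession_id,
                "n_reached": e.n_reached,
                "n_courses": e.n_courses,
                "reason": e.reason,
            }
            for e in exclusions
        ],
        columns=["accession", "n_reached", "n_courses", "reason"],
    )


def curve_from_fits(fits: pd.DataFrame) -> TbThetaCurve:
    """Fit Tb = a + c*ln(theta) across the valid per-accession fits."""
    ok = fits[fits["status"] == "ok"]
    return fit_tb_theta_curve(ok["tb_c"], ok["theta_ch"])


def build_scenarios(curve: TbThetaCurve, thetas: Iterable[float]) -> pd.DataFrame:
    """Trait combinations on the fitted Tb-theta line for given thermal times."""
    thetas = list(thetas)
    if any(t <= 0 for t in thetas):
        raise ValueError("all thermal times must be positive")
    return pd.DataFrame(
        {"tb_c": [curve.predict_tb(t) for t in thetas], "theta_ch": thetas},
        columns=["tb_c", "theta_ch"],
    )


def scenarios_from_frame(df: pd.DataFrame) -> list[HRTraits]:
    return [HRTraits(float(r.tb_c), float(r.theta_ch)) for r in df.itertuples()]


def bloom_trend_regression(
    bloom: pd.DataFrame,
    *,
    year_col: str = "year",
    day_col: str = "bloom_doy",
    theta_col: str = "theta_ch",
) -> pd.DataFrame:
    """Per-year OLS of field bloom day on thermal-time requirement.

    Tests, year by year, whether accessions with a larger heat requirement
    bloom later in a common garden: slope in days per degree-hour with a
    two-sided t-test on the slope.  Requires >= 3 paired observations and
    non-constant theta within each year.
    """
    needed = {year_col, day_col, theta_col} - set(bloom.columns)
    if needed:
        raise ValueError(f"bloom table missing column(s) {sorted(needed)}")
    rows = []
    for year, grp in bloom.groupby(year_col, sort=True):
        if len(grp) < 3:
            raise ValueError(f"year {year}: need >= 3 paired observations")
        theta = grp[theta_col].to_numpy(dtype=float)
        day = grp[day_col].to_numpy(dtype=float)
        if np.ptp(theta) == 0:
            raise ValueError(f"year {year}: zero variance in thermal time")
        res = stats.linregress(theta, day)
        rows.append(
            {
                "year": year,
                "slope_day_per_ch": float(res.slope),
                "intercept_day": float(res.intercept),
                "p_value": float(res.pvalue),
                "r_squared": float(res.rvalue**2),
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows)
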