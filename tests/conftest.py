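import numpy as np
import pandas as pd
import pytest

from budforce import (
    HourlyWeatherSeries,
    WeatherSimConfig,
    gen_weather,
)


@pytest.fixture(scope="session")
def winter_weather() -> HourlyWeatherSeries:
    """Ten seeded synthetic dormancy seasons with default climatology."""
    return gen_weather(WeatherSimConfig(n_seasons=10, seed=7))


def constant_weather(temp_c: float, year: int = 2000, station: str = "CONST") -> HourlyWeatherSeries:
    """A full season at one constant temperature (no noise, no cycles)."""
    return gen_weather(
        WeatherSimConfig(
            annual_mean_c=temp_c,
            annual_amplitude_c=0.0,
            diurnal_amplitude_c=0.0,
            ar1_coef=0.0,
            noise_sd_c=0.0,
            n_seasons=1,
            start_year=year,
            station_id=station,
        )
    )


def hourly_series(
    temps, start="2000-10-01", station="T", imputed=None, **kwargs
) -> HourlyWeatherSeries:
    """Small hand-built hourly series starting at ``start``."""
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range(start, periods=len(temps), freq="h")
    if imputed is None:
        imputed = np.zeros(len(temps), dtype=bool)
    return HourlyWeatherSeries(
        station_id=station, timestamps=idx, temp_c=temps, imputed=imputed, **kwargs
    )
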