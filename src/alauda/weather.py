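"""Daily weather series: synthetic generation and CSV I/O.

The simulator only needs daily mean temperature and precipitation.  The
synthetic generator is a standard stochastic weather model for a
temperate maritime climate: a sinusoidal seasonal mean temperature with
Gaussian noise, and precipitation from a two-state wet/dry Markov chain
with gamma-distributed wet-day amounts.  A measured station series in
the same CSV format can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365  # simulation years are fixed-length; no leap days


@dataclass
class WeatherGenParams:
    """Parameters of the synthetic weather generator (Danish-like defaults)."""

    mean_temp_c: float = 8.0          # annual mean temperature
    seasonal_amplitude_c: float = 8.5  # peak deviation from the mean
    peak_doy: int = 200                # warmest day of year (mid-July)
    temp_noise_sd_c: float = 3.0       # day-to-day Gaussian noise
    p_wet_given_dry: float = 0.25      # Markov chain transition probabilities
    p_wet_given_wet: float = 0.55
    rain_gamma_shape: float = 0.8      # wet-day amount distribution (mm)
    rain_gamma_scale_mm: float = 5.0


def seasonal_mean_temp(doy: np.ndarray, gen: WeatherGenParams) -> np.ndarray:
    """Noise-free seasonal temperature curve for day-of-year ``doy``."""
    phase = 2.0 * np.pi * (np.asarray(doy, dtype=float) - gen.peak_doy) / DAYS_PER_YEAR
    return gen.mean_temp_c + gen.seasonal_amplitude_c * np.cos(phase)


def generate_weather(
    years: int,
    seed: int,
    gen: WeatherGenParams | None = None,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Generate a contiguous daily weather series.

    Returns a DataFrame with columns ``year`` (simulation year starting
    at ``start_year``), ``doy`` (1-based day of year), ``mean_temp``
    (degC) and ``precipitation`` (mm/day, >= 0).  Reproducible per seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    gen = gen or WeatherGenParams()
    rng = np.random.default_rng(seed)
    n = years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), years)
    year = np.repeat(np.arange(start_year, start_year + years), DAYS_PER_YEAR)

    temp = seasonal_mean_temp(doy, gen)
    if gen.temp_noise_sd_c > 0:
        temp = temp + rng.normal(0.0, gen.temp_noise_sd_c, n)

    # two-state Markov chain for wet days
    wet = np.zeros(n, dtype=bool)
    u = rng.random(n)
    prev = False
    for i in range(n):
        p = gen.p_wet_given_wet if prev else gen.p_wet_given_dry
        prev = wet[i] = u[i] < p
    rain = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet and gen.rain_gamma_shape > 0:
        rain[wet] = rng.gamma(gen.rain_gamma_shape, gen.rain_gamma_scale_mm, n_wet)

    return pd.DataFrame(
        {"year": year, "doy": doy, "mean_temp": temp, "precipitation": rain}
    )


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Check the weather-series contract; returns the frame unchanged."""
    required = {"year", "doy", "mean_temp", "precipitation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather series missing columns: {sorted(missing)}")
    if (df["precipitation"] < 0).any():
        raise ValueError("negative precipitation in weather series")
    expected_doy = np.tile(
        np.arange(1, DAYS_PER_YEAR + 1), len(df) // DAYS_PER_YEAR + 1
    )[: len(df)]
    if len(df) % DAYS_PER_YEAR != 0 or not np.array_equal(
        df["doy"].to_numpy(), expected_doy
    ):
        raise ValueError("weather series must be contiguous whole years")
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    validate_weather(df).to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    return validate_weather(pd.read_csv(path))
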