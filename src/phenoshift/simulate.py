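"""Synthetic temperature, phenology and climate-delta generators.

These generators carry the statistical structure the analysis assumes — a
seasonal daily temperature cycle with AR(1) noise (window scans are sensitive
to temporal autocorrelation, so white noise would be too easy), event dates
produced from known window-linear or thermal-time parameters plus observation
noise, and Gaussian monthly temperature-change samples — so every downstream
stage can be tested without any external dataset.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar import DailyTemperatureSeries, PhenologySeries, covariate_matrix
from .thermal import DEFAULT_HORIZON, predict_event_days

__all__ = [
    "ClimateSpec",
    "simulate_temperature",
    "simulate_events_linear",
    "simulate_events_mechanistic",
    "simulate_deltas",
]


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of the seasonal + AR(1) daily temperature generator.

    Defaults loosely resemble a maritime temperate climate (annual mean
    ~9.5 degC, ~6.5 degC seasonal amplitude peaking in mid July, day-to-day
    noise sd 2 degC with lag-1 autocorrelation 0.7).  They are configuration,
    not empirical claims.
    """

    mean: float = 9.5          # annual mean, degC
    amplitude: float = 6.5     # seasonal half-range, degC
    phase_day: float = 196.0   # day-of-year of the seasonal peak (mid July)
    noise_sd: float = 2.0      # marginal sd of the AR(1) noise, degC
    rho: float = 0.7           # lag-1 autocorrelation of the noise
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")


def simulate_temperature(
    spec: ClimateSpec, start_year: int, n_years: int
) -> DailyTemperatureSeries:
    """Daily series T(d) = mean + amplitude * cos(2 pi (d - phase)/365.25) + eps(d),
    with eps an AR(1) process of marginal sd ``noise_sd`` and lag-1
    correlation ``rho``."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    idx = pd.date_range(
        dt.date(start_year, 1, 1), dt.date(start_year + n_years - 1, 12, 31), freq="D"
    )
    doy = idx.dayofyear.to_numpy()
    seasonal = spec.mean + spec.amplitude * np.cos(
        2 * np.pi * (doy - spec.phase_day) / 365.25
    )
    rng = np.random.default_rng(spec.seed)
    n = len(idx)
    eps = np.zeros(n)
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.rho**2)
        innov = rng.normal(0.0, innov_sd, size=n)
        eps[0] = rng.normal(0.0, spec.noise_sd)
        for t in range(1, n):
            eps[t] = spec.rho * eps[t - 1] + innov[t]
    return DailyTemperatureSeries(pd.Series(seasonal + eps, index=idx))


def _window_means(temps, years, window, *_):
    start, duration = window
    X, _ = covariate_matrix(temps, years, start, start + duration - 1)
    return X.mean(axis=1)


def simulate_events_linear(
    temps: DailyTemperatureSeries,
    event_years,
    windows,
    slopes,
    intercept: float,
    noise_sd: float,
    seed: int,
    species: str = "synthetic",
) -> PhenologySeries:
    """Events generated as intercept + sum_i slope_i * mean-temp(window_i) + noise.

    ``windows`` is a sequence of (start_offset, duration) pairs and ``slopes``
    the matching days-per-degC sensitivities; events are rounded to integer
    days since first-observation records are integer dated.
    """
    windows = list(windows)
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    if len(windows) != len(slopes):
        raise ValueError("one slope per window required")
    years = np.asarray(list(event_years), dtype=int)
    day = np.full(len(years), float(intercept))
    for window, slope in zip(windows, slopes):
        day += slope * _window_means(temps, years, window)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        day += rng.normal(0.0, noise_sd, size=len(years))
    events = {int(y): int(np.rint(d)) for y, d in zip(years, day)}
    return PhenologySeries(species, events)


def simulate_events_mechanistic(
    temps: DailyTemperatureSeries,
    params,
    event_years,
    noise_sd: float,
    seed: int,
    species: str = "synthetic",
    horizon: int = DEFAULT_HORIZON,
    start_offset: int | None = None,
) -> PhenologySeries:
    """Forward-simulate a thermal-time model plus Gaussian observation noise.

    Years in which the accumulation thresholds are not met by *horizon* are
    recorded in ``no_event_years`` rather than silently dropped.
    """
    years = np.asarray(list(event_years), dtype=int)
    if start_offset is None:
        t_start = getattr(params, "t0", None)
        if t_start is None:
            t_start = int(np.floor(params.t1))
        start_offset = min(int(t_start), 0)
    X, offsets = covariate_matrix(temps, years, start_offset, horizon)
    pred = predict_event_days(params, X, offsets, horizon)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        pred = pred + rng.normal(0.0, noise_sd, size=len(years))
    events: dict[int, int] = {}
    no_event: set[int] = set()
    for y, d in zip(years, pred):
        if np.isnan(d):
            no_event.add(int(y))
        else:
            events[int(y)] = int(np.rint(d))
    return PhenologySeries(species, events, no_event)


def simulate_deltas(
    n_samples: int,
    monthly_means,
    monthly_sds,
    seed: int,
) -> np.ndarray:
    """(n_samples, 12) matrix of monthly temperature changes, Gaussian and
    independent across months and samples."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    means = np.asarray(monthly_means, dtype=float)
    sds = np.asarray(monthly_sds, dtype=float)
    if means.shape != (12,) or sds.shape != (12,):
        raise ValueError("monthly means and sds must each have 12 entries")
    if (sds < 0).any():
        raise ValueError("monthly sds must be >= 0")
    rng = np.random.default_rng(seed)
    return means + sds * rng.standard_normal((n_samples, 12))
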