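"""Synthetic daily climates and quantum-yield observations.

The raw field QY readings and the station extracts behind the analysis are
not deposited, so this module generates data with the same statistical
structure: a sinusoidal seasonal temperature cycle with daily Gaussian
noise, a fixed diurnal max/min spread, an optional linear warming trend
and station-outage missing days; and QY observations drawn from the
logit-linear chilling-unit model itself,

    QY = inverse_logit(a * CU(date) + b + eps),   eps ~ N(0, obs_sd).

Defaults emulate a humid-temperate Kanto-plain climate (annual mean 14.7
degrees C, January mean 3.1 degrees C) and the selected damage model: the
count of days with daily maximum below 9.5 degrees C over the past 46
days, with slope and intercept placing winter QY roughly in 0.05-0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chilling import CUConfig, DailyTemperatureSeries, compute_cu
from .model import inverse_logit

__all__ = [
    "ClimateParams",
    "TrueModel",
    "gen_temperature_series",
    "gen_qy_observations",
    "biweekly_schedule",
    "COLDEST_DOY",
]

# Anchor of the seasonal minimum: late January.
COLDEST_DOY = 25


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the seasonal-sinusoid daily temperature generator."""

    annual_mean: float = 14.7  # degrees C
    seasonal_amplitude: float = 11.6  # degrees C; min = mean - amplitude
    daily_noise_sd: float = 2.0  # degrees C, iid per day
    diurnal_half_range: float = 4.5  # max/min = daily mean +- this
    warming_rate: float = 0.0  # degrees C per year
    missing_fraction: float = 0.0  # proportion of fully-missing days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be >= 0")
        if self.diurnal_half_range < 0:
            raise ValueError("diurnal_half_range must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must lie in [0, 1)")

    def with_seed(self, seed: int) -> "ClimateParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrueModel:
    """Generating model: one CU definition plus logit-scale line and noise."""

    cu_config: CUConfig
    a: float  # logit units per CU unit
    b: float  # logit units
    obs_sd: float  # residual sd on the logit scale

    def __post_init__(self) -> None:
        if self.obs_sd < 0:
            raise ValueError("obs_sd must be >= 0")

    @classmethod
    def default(cls) -> "TrueModel":
        """The selected damage model: day count of tmax < 9.5 over 46 days."""
        return cls(
            cu_config=CUConfig("day_count", "max", 9.5, 46),
            a=-0.08,
            b=0.85,
            obs_sd=0.1,
        )


def gen_temperature_series(
    params: ClimateParams,
    start_date,
    n_days: int,
    site_id: str = "synthetic",
) -> DailyTemperatureSeries:
    """Daily max/min/avg series from the seasonal-sinusoid model.

    Daily mean = annual_mean - amplitude * cos(2 pi (doy - 25) / 365.25)
    + warming_rate * years_since_start + N(0, noise_sd); max and min sit a
    fixed half-range above and below the mean.  A ``missing_fraction`` of
    days, drawn uniformly, lose all three statistics at once (station
    outage).  Fully reproducible from ``params.seed``.
    """
    n_days = int(n_days)
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    years = np.arange(n_days, dtype=float) / 365.25
    mean = (
        params.annual_mean
        - params.seasonal_amplitude * np.cos(2 * np.pi * (doy - COLDEST_DOY) / 365.25)
        + params.warming_rate * years
        + rng.normal(0.0, params.daily_noise_sd, n_days)
    )
    frame = pd.DataFrame(
        {
            "tmax": mean + params.diurnal_half_range,
            "tmin": mean - params.diurnal_half_range,
            "tavg": mean,
        },
        index=dates,
    )
    if params.missing_fraction > 0:
        n_missing = int(round(params.missing_fraction * n_days))
        drop = rng.choice(n_days, size=n_missing, replace=False)
        frame.iloc[drop] = np.nan
    return DailyTemperatureSeries(site_id, frame)


def biweekly_schedule(first_date, last_date, interval_days: int = 14) -> pd.DatetimeIndex:
    """Sampling dates from ``first_date`` stepping ``interval_days``, capped
    at ``last_date`` (inclusive)."""
    first, last = pd.Timestamp(first_date), pd.Timestamp(last_date)
    if last < first:
        raise ValueError("last_date precedes first_date")
    return pd.date_range(first, last, freq=f"{int(interval_days)}D")


def gen_qy_observations(
    series: DailyTemperatureSeries,
    truth: TrueModel,
    first_date,
    interval_days: int = 14,
    last_date=None,
    n_lines: int = 2,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """QY observations drawn from the generating model on a date schedule.

    Every (date, line, replicate) triple gets an independent logit-scale
    Gaussian error, so replicates within a date are exchangeable.  Requires
    the temperature record to start at least window - 1 days before the
    first sampling date so the chilling unit is defined there.  Returns a
    frame with columns site_id, date, line, replicate, qy; QY is strictly
    inside (0, 1) by construction.
    """
    schedule = biweekly_schedule(
        first_date, last_date if last_date is not None else series.dates[-1],
        interval_days,
    )
    L = truth.cu_config.window
    lead = (schedule[0] - series.dates[0]).days + 1
    if lead < L:
        raise ValueError(
            f"temperature history starts {L - lead} day(s) too late for the "
            f"first sampling date {schedule[0].date()} (window L={L})"
        )
    cu = compute_cu(series, truth.cu_config)
    missing = schedule.difference(cu.values.index)
    if len(missing):
        raise ValueError(f"no chilling-unit value for sampling date {missing[0].date()}")
    cu_at = cu.values.loc[schedule].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for d, cu_d in zip(schedule, cu_at):
        for line in range(1, int(n_lines) + 1):
            eps = rng.normal(0.0, truth.obs_sd, int(n_replicates))
            qy = inverse_logit(truth.a * cu_d + truth.b + eps)
            for rep, q in enumerate(np.atleast_1d(qy), start=1):
                rows.append((series.site_id, d, f"line{line}", rep, float(q)))
    return pd.DataFrame(
        rows, columns=["site_id", "date", "line", "replicate", "qy"]
    )
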