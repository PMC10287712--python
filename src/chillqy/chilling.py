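"""Chilling accumulation units from daily temperature records.

A chilling unit (CU) summarises the cold exposure preceding a calendar day:
either the number of days (``day_count``) or the accumulated temperature
deficit in degree-days (``temperature_sum``) on which a chosen daily
statistic (max / min / avg) fell below a threshold ``Th`` within the
``L``-day window ending on, and including, that day.

This module also owns the preprocessing of station records: the
missing-rate admission filter and the neighbour-mean / linear
interpolation of missing days.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "DailyTemperatureSeries",
    "CUConfig",
    "CUSeries",
    "GridSpec",
    "FilterDecision",
    "filter_by_missing_rate",
    "impute_missing",
    "compute_cu",
    "enumerate_grid",
    "period_max_cu",
]

log = logging.getLogger(__name__)

CUType = Literal["day_count", "temperature_sum"]
TempStat = Literal["max", "min", "avg"]

CU_TYPES: tuple[str, ...] = ("day_count", "temperature_sum")
TEMP_STATS: tuple[str, ...] = ("max", "min", "avg")

_STAT_COLUMN = {"max": "tmax", "min": "tmin", "avg": "tavg"}


@dataclass
class DailyTemperatureSeries:
    """Per-site daily max/min/avg temperatures on a gap-free calendar axis.

    Missing days are explicit NaN rows; construction reindexes the data to
    the full daily range so that absent dates become missing rather than
    silent gaps.  Days violating ``tmin <= tavg <= tmax`` are flagged with
    a warning but kept (station records do contain such rows).
    """

    site_id: str
    frame: pd.DataFrame  # DatetimeIndex (daily), columns tmax, tmin, tavg

    def __post_init__(self) -> None:
        f = self.frame
        if not isinstance(f.index, pd.DatetimeIndex):
            f = f.copy()
            f.index = pd.DatetimeIndex(f.index)
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValueError(f"duplicate date {dup.date()} for site {self.site_id}")
        f = f.sort_index()
        missing_cols = [c for c in ("tmax", "tmin", "tavg") if c not in f.columns]
        if missing_cols:
            raise ValueError(f"temperature frame lacks columns {missing_cols}")
        if len(f):
            full = pd.date_range(f.index[0], f.index[-1], freq="D")
            f = f.reindex(full)
        self.frame = f[["tmax", "tmin", "tavg"]].astype(float)
        bad = (
            (self.frame["tmin"] > self.frame["tavg"])
            | (self.frame["tavg"] > self.frame["tmax"])
        )
        if bad.any():
            warnings.warn(
                f"site {self.site_id}: {int(bad.sum())} day(s) violate "
                "tmin <= tavg <= tmax",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def stat(self, temp_stat: str) -> pd.Series:
        """Return the daily series for one statistic ('max'/'min'/'avg')."""
        return self.frame[_STAT_COLUMN[_check_stat(temp_stat)]]

    def missing_rate(self, temp_stat: str) -> float:
        s = self.stat(temp_stat)
        return float(s.isna().sum()) / len(s) if len(s) else float("nan")


def _check_stat(temp_stat: str) -> str:
    if temp_stat not in TEMP_STATS:
        raise ValueError(f"temp_stat must be one of {TEMP_STATS}, got {temp_stat!r}")
    return temp_stat


@dataclass(frozen=True)
class CUConfig:
    """One chilling-unit definition: type, statistic, threshold, window."""

    cu_type: CUType
    temp_stat: TempStat
    threshold: float  # Th, degrees C
    window: int  # L, days

    def __post_init__(self) -> None:
        if self.cu_type not in CU_TYPES:
            raise ValueError(f"cu_type must be one of {CU_TYPES}, got {self.cu_type!r}")
        _check_stat(self.temp_stat)
        if int(self.window) != self.window or self.window < 1:
            raise ValueError(f"window must be a positive integer, got {self.window!r}")
        object.__setattr__(self, "window", int(self.window))


@dataclass
class CUSeries:
    """Date-indexed chilling-unit values for one site and configuration.

    Units are days for ``day_count`` and degree-days for ``temperature_sum``.
    """

    site_id: str
    config: CUConfig
    values: pd.Series  # DatetimeIndex -> CU value


@dataclass(frozen=True)
class ThresholdRange:
    low: float
    high: float
    step: float = 0.25

    def grid(self) -> np.ndarray:
        span = self.high - self.low
        if self.step <= 0:
            raise ValueError("threshold step must be positive")
        n = span / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"threshold step {self.step} does not divide range "
                f"[{self.low}, {self.high}]"
            )
        return np.linspace(self.low, self.high, int(round(n)) + 1)


@dataclass(frozen=True)
class WindowRange:
    min_L: int = 1
    max_L: int = 70
    step: int = 1

    def grid(self) -> np.ndarray:
        if self.step < 1:
            raise ValueError("window step must be a positive integer")
        if (self.max_L - self.min_L) % self.step != 0:
            raise ValueError(
                f"window step {self.step} does not divide range "
                f"[{self.min_L}, {self.max_L}]"
            )
        return np.arange(self.min_L, self.max_L + 1, self.step)


# Default per-statistic threshold ranges: each spans 15 degrees C in 0.25
# steps (61 values) and brackets the per-statistic optima of the selection.
_DEFAULT_THRESHOLDS = {
    "max": ThresholdRange(0.0, 15.0),
    "avg": ThresholdRange(-2.5, 12.5),
    "min": ThresholdRange(-7.0, 8.0),
}


@dataclass(frozen=True)
class GridSpec:
    """Search grid: per-statistic threshold ranges and a shared window range.

    The default reproduces 61 thresholds x 70 windows per (type, statistic)
    pair: 4,270 configurations per pair, 25,620 over the six pairs.
    """

    thresholds: dict[str, ThresholdRange] = field(
        default_factory=lambda: dict(_DEFAULT_THRESHOLDS)
    )
    windows: WindowRange = WindowRange()
    cu_types: tuple[str, ...] = CU_TYPES
    temp_stats: tuple[str, ...] = TEMP_STATS

    def threshold_grid(self, temp_stat: str) -> np.ndarray:
        return self.thresholds[_check_stat(temp_stat)].grid()

    def window_grid(self) -> np.ndarray:
        return self.windows.grid()

    @property
    def n_configs(self) -> int:
        n = 0
        for stat in self.temp_stats:
            n += len(self.cu_types) * len(self.threshold_grid(stat)) * len(
                self.window_grid()
            )
        return n

    @classmethod
    def reduced(
        cls,
        thresholds: Iterable[float],
        windows: Iterable[int],
        cu_types: tuple[str, ...] = CU_TYPES,
        temp_stats: tuple[str, ...] = TEMP_STATS,
    ) -> "GridSpec":
        """Small explicit grid (same thresholds for every statistic)."""
        th = sorted(thresholds)
        wi = sorted(int(w) for w in windows)
        if len(th) > 1:
            steps = np.diff(th)
            if not np.allclose(steps, steps[0]):
                raise ValueError("reduced thresholds must be evenly spaced")
            step = float(steps[0])
        else:
            step = 0.25
        if len(wi) > 1:
            wsteps = np.diff(wi)
            if len(set(wsteps.tolist())) != 1:
                raise ValueError("reduced windows must be evenly spaced")
            wstep = int(wsteps[0])
        else:
            wstep = 1
        return cls(
            thresholds={s: ThresholdRange(th[0], th[-1], step) for s in TEMP_STATS},
            windows=WindowRange(wi[0], wi[-1], wstep),
            cu_types=cu_types,
            temp_stats=temp_stats,
        )


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the missing-rate admission filter for one statistic."""

    accepted: bool
    missing_rate: float
    n_missing: int
    n_days: int


def filter_by_missing_rate(
    series: DailyTemperatureSeries, temp_stat: str, max_rate: float = 0.10
) -> FilterDecision:
    """Admit a station record iff its missing-day rate is <= ``max_rate``.

    The bound is inclusive: a record with exactly the maximum rate passes.
    """
    if len(series) == 0:
        raise ValueError(f"site {series.site_id}: empty series cannot be filtered")
    s = series.stat(temp_stat)
    n_missing = int(s.isna().sum())
    rate = n_missing / len(s)
    return FilterDecision(rate <= max_rate, rate, n_missing, len(s))


def impute_missing(series: DailyTemperatureSeries) -> DailyTemperatureSeries:
    """Fill missing days from their non-missing neighbours.

    A single missing day receives the arithmetic mean of the values
    immediately before and after it; a run of k >= 2 consecutive missing
    days receives linear interpolation between the flanking values (the
    natural extension of the single-day rule).  Non-missing values are
    preserved exactly.  A missing value on the first or last day has no
    flanking pair and is rejected.
    """
    f = series.frame
    for col in ("tmax", "tmin", "tavg"):
        s = f[col]
        if len(s) and s.isna().iloc[0]:
            raise ValueError(
                f"site {series.site_id}: {col} missing on first day "
                f"{f.index[0].date()}; cannot impute at a series boundary"
            )
        if len(s) and s.isna().iloc[-1]:
            raise ValueError(
                f"site {series.site_id}: {col} missing on last day "
                f"{f.index[-1].date()}; cannot impute at a series boundary"
            )
    out = f.interpolate(method="linear", limit_area="inside")
    return DailyTemperatureSeries(series.site_id, out)


def _window_sums(kernel: np.ndarray, window: int) -> np.ndarray:
    """Sum of ``kernel`` over the window ending on each index >= window-1."""
    cs = np.concatenate([[0.0], np.cumsum(kernel)])
    return cs[window:] - cs[:-window]


def compute_cu(
    series: DailyTemperatureSeries,
    config: CUConfig,
    temperature_sum_kind: str = "deficit",
) -> CUSeries:
    """Chilling-unit series for every date with a full accumulation window.

    The window of length L ends on and includes the output day.  "Below the
    threshold" is the strict inequality T < Th.  For ``temperature_sum`` the
    default accumulates the deficit sum(Th - T) over sub-threshold days (the
    usual chilling / degree-day convention, nonnegative and monotone in Th);
    ``temperature_sum_kind='raw'`` instead accumulates the raw temperatures
    of those days.

    Requires an imputed series (no missing values for the used statistic);
    output starts at the first date preceded by window-1 days of history.
    """
    if temperature_sum_kind not in ("deficit", "raw"):
        raise ValueError("temperature_sum_kind must be 'deficit' or 'raw'")
    s = series.stat(config.temp_stat)
    if s.isna().any():
        n_bad = int(s.isna().sum())
        raise ValueError(
            f"site {series.site_id}: {n_bad} missing {config.temp_stat} value(s); "
            "impute before computing chilling units"
        )
    x = s.to_numpy()
    L = config.window
    if len(x) < L:
        log.info(
            "site %s: series of %d day(s) shorter than window %d; no output dates",
            series.site_id,
            len(x),
            L,
        )
        return CUSeries(series.site_id, config, pd.Series(dtype=float))
    below = x < config.threshold
    if config.cu_type == "day_count":
        kernel = below.astype(float)
    elif temperature_sum_kind == "deficit":
        kernel = np.where(below, config.threshold - x, 0.0)
    else:
        kernel = np.where(below, x, 0.0)
    vals = _window_sums(kernel, L)
    idx = series.dates[L - 1 :]
    return CUSeries(series.site_id, config, pd.Series(vals, index=idx))


def enumerate_grid(spec: GridSpec) -> list[CUConfig]:
    """All configurations of a grid in deterministic order.

    Order: cu_type, then temp_stat, then threshold ascending, then window
    ascending.  The default grid yields 4,270 configurations per
    (type, statistic) pair and 25,620 in total.
    """
    configs: list[CUConfig] = []
    windows = spec.window_grid()
    for cu_type, stat in itertools.product(spec.cu_types, spec.temp_stats):
        for th in spec.threshold_grid(stat):
            for L in windows:
                configs.append(CUConfig(cu_type, stat, float(th), int(L)))
    return configs


def period_max_cu(
    cu_series: CUSeries, period: tuple[pd.Timestamp, pd.Timestamp]
) -> float:
    """Maximum chilling-unit value over a date interval (inclusive ends)."""
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    window = cu_series.values.loc[start:end]
    if window.empty:
        raise ValueError(
            f"site {cu_series.site_id}: no CU values in "
            f"[{start.date()}, {end.date()}]"
        )
    return float(window.max())
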