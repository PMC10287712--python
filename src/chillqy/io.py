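"""Tabular I/O and geographic fixture generation.

Two CSV schemas travel through the pipeline:

* daily climate — ``site_id,date,tmax,tmin,tavg``; ISO-8601 dates, one row
  per site-day, empty temperature fields meaning missing;
* QY observations — ``site_id,date,line,replicate,qy``.

Readers validate the header and every cell, reporting the 1-based line
number of the first offence, and reject duplicate (site, date) climate
rows outright; calendar gaps become explicit missing days.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .chilling import DailyTemperatureSeries
from .geo import SiteRecord
from .synthetic import ClimateParams, gen_temperature_series

__all__ = [
    "read_climate_csv",
    "write_climate_csv",
    "read_qy_csv",
    "write_qy_csv",
    "gen_site_network",
    "annual_mean_at_latitude",
]

CLIMATE_HEADER = ["site_id", "date", "tmax", "tmin", "tavg"]
QY_HEADER = ["site_id", "date", "line", "replicate", "qy"]


def _parse_date(text: str, path, lineno: int) -> pd.Timestamp:
    try:
        return pd.Timestamp(text)
    except (ValueError, TypeError):
        raise ValueError(f"{path}:{lineno}: malformed date {text!r}") from None


def _parse_temp(text: str, path, lineno: int) -> float:
    if text == "":
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: non-numeric temperature {text!r}") from None


def read_climate_csv(path) -> dict[str, DailyTemperatureSeries]:
    """Read the daily-climate CSV into one series per site.

    Dates inside a site's span that have no row become fully missing days.
    """
    path = Path(path)
    per_site: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CLIMATE_HEADER:
            raise ValueError(
                f"{path}: unknown climate schema {header}; expected {CLIMATE_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            site, date_s, *temps = row
            date = _parse_date(date_s, path, lineno)
            vals = [_parse_temp(t, path, lineno) for t in temps]
            site_rows = per_site.setdefault(site, {})
            if date in site_rows:
                raise ValueError(
                    f"{path}:{lineno}: duplicate date {date.date()} for site {site}"
                )
            site_rows[date] = vals
    out = {}
    for site, rows in per_site.items():
        frame = pd.DataFrame.from_dict(
            rows, orient="index", columns=["tmax", "tmin", "tavg"]
        )
        out[site] = DailyTemperatureSeries(site, frame)
    return out


def _fmt(v: float) -> str:
    return "" if pd.isna(v) else repr(float(v))


def write_climate_csv(series: list[DailyTemperatureSeries] | DailyTemperatureSeries, path) -> None:
    if isinstance(series, DailyTemperatureSeries):
        series = [series]
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CLIMATE_HEADER)
        for s in series:
            for date, row in s.frame.iterrows():
                w.writerow(
                    [s.site_id, date.date().isoformat(),
                     _fmt(row["tmax"]), _fmt(row["tmin"]), _fmt(row["tavg"])]
                )


def read_qy_csv(path) -> pd.DataFrame:
    """Read the QY observation CSV; every qy must be a number in [0, 1]."""
    path = Path(path)
    rows = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != QY_HEADER:
            raise ValueError(
                f"{path}: unknown QY schema {header}; expected {QY_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            site, date_s, line, rep_s, qy_s = row
            date = _parse_date(date_s, path, lineno)
            try:
                rep = int(rep_s)
                qy = float(qy_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed replicate/qy {rep_s!r}, {qy_s!r}"
                ) from None
            if not (0 <= qy <= 1):
                raise ValueError(f"{path}:{lineno}: qy {qy} outside [0, 1]")
            rows.append((site, date, line, rep, qy))
    return pd.DataFrame(rows, columns=QY_HEADER)


def write_qy_csv(observations: pd.DataFrame, path) -> None:
    obs = observations.copy()
    obs["date"] = pd.DatetimeIndex(obs["date"]).strftime("%Y-%m-%d")
    obs[QY_HEADER].to_csv(path, index=False)


def annual_mean_at_latitude(
    latitude: float, mean_at_equator: float = 27.0, lat_slope: float = -0.34
) -> float:
    """Site annual-mean temperature rule: linear in |latitude|.

    The default slope of -0.34 degrees C per degree of latitude puts a
    humid-temperate ~14.7 degrees C annual mean at 36 degrees.
    """
    return mean_at_equator + lat_slope * abs(latitude)


def gen_site_network(
    n_sites: int,
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    start_date,
    n_days: int,
    base_params: ClimateParams | None = None,
    mean_at_equator: float = 27.0,
    lat_slope: float = -0.34,
    seed: int = 0,
) -> list[SiteRecord]:
    """Synthetic station network on a jittered lattice.

    Sites sit near the nodes of an approximately square lattice spanning
    the ranges, with uniform jitter of half a cell; each site's climate is
    the base parameterisation with its annual mean set by the
    latitude rule and an independent per-site stream drawn from ``seed``.
    """
    n_sites = int(n_sites)
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    if lat_range[0] > lat_range[1] or lon_range[0] > lon_range[1]:
        raise ValueError("empty latitude/longitude range")
    base = base_params or ClimateParams()
    rng = np.random.default_rng(seed)
    ncol = int(np.ceil(np.sqrt(n_sites)))
    nrow = int(np.ceil(n_sites / ncol))
    lat_nodes = np.linspace(lat_range[0], lat_range[1], nrow)
    lon_nodes = np.linspace(lon_range[0], lon_range[1], ncol)
    lat_cell = (lat_range[1] - lat_range[0]) / max(nrow - 1, 1)
    lon_cell = (lon_range[1] - lon_range[0]) / max(ncol - 1, 1)
    sites = []
    k = 0
    for la in lat_nodes:
        for lo in lon_nodes:
            if k >= n_sites:
                break
            lat = float(np.clip(la + rng.uniform(-0.5, 0.5) * lat_cell,
                                max(lat_range[0], -90), min(lat_range[1], 90)))
            lon = float(np.clip(lo + rng.uniform(-0.5, 0.5) * lon_cell,
                                max(lon_range[0], -180), min(lon_range[1], 180)))
            params = ClimateParams(
                annual_mean=annual_mean_at_latitude(lat, mean_at_equator, lat_slope),
                seasonal_amplitude=base.seasonal_amplitude,
                daily_noise_sd=base.daily_noise_sd,
                diurnal_half_range=base.diurnal_half_range,
                warming_rate=base.warming_rate,
                missing_fraction=base.missing_fraction,
                seed=int(rng.integers(2**31)),
            )
            sid = f"site{k:03d}"
            series = gen_temperature_series(params, start_date, n_days, site_id=sid)
            sites.append(SiteRecord(sid, lat, lon, series))
            k += 1
    return sites
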