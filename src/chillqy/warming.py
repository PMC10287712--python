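"""Long-term warming trends in predicted winter damage.

For each station the fitted damage model turns seven decades of daily
temperatures into one number per winter — the seasonal minimum of the
predicted QY.  A per-site straight line through those annual minima
(OLS on season start year) is extrapolated to a future year, the
extrapolated values are thresholded into suitable/unsuitable sites, and
the SVM machinery from the geographic module maps the shifting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import linear_intervals
from .geo import SiteRecord, SuitabilityGrid, svm_interpolate
from .model import ModelFit
from .chilling import compute_cu, impute_missing

__all__ = [
    "TrendModel",
    "seasonal_min_qy",
    "fit_trend",
    "extrapolate",
    "count_suitable_sites",
    "map_decision_boundary",
    "northern_boundary_latitude",
]


@dataclass
class TrendModel:
    """Per-site linear trend of annual-minimum predicted QY vs year."""

    site_id: str
    slope: float  # QY per year
    intercept: float  # QY at year 0
    n_seasons: int
    years: np.ndarray  # season start years used in the fit
    min_qy: np.ndarray

    def line(self, year) -> np.ndarray:
        return self.slope * np.asarray(year, dtype=float) + self.intercept

    def intervals(self, years, level: float = 0.95) -> pd.DataFrame:
        """95% CI and PI of the trend line at the given years (QY scale,
        unclamped)."""
        yh, cl, ch, pl, ph = linear_intervals(
            self.years, self.min_qy, self.slope, self.intercept,
            np.asarray(years, dtype=float), level,
        )
        return pd.DataFrame(
            {"year": years, "qy_hat": yh, "ci_low": cl, "ci_high": ch,
             "pi_low": pl, "pi_high": ph}
        )


def seasonal_min_qy(
    site: SiteRecord,
    fit: ModelFit,
    season_start: tuple[int, int] = (10, 1),
    season_end: tuple[int, int] = (3, 31),
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Annual minimum of predicted QY for every fully covered season.

    A season runs from ``season_start`` (month, day) to ``season_end`` in
    the following calendar year and is labelled by its start year.
    Seasons whose window (plus the chilling-unit lead-in) is not fully
    covered by the record are skipped and listed with the reason.
    Returns (frame with site_id, season, min_qy; skipped list).
    """
    if fit.config is None:
        raise ValueError("fit must carry its chilling-unit configuration")
    series = site.series
    if series.frame.isna().any().any():
        series = impute_missing(series)
    cu = compute_cu(series, fit.config)
    if cu.values.empty:
        raise ValueError(f"site {site.site_id}: record shorter than the CU window")
    qy_pred = pd.Series(fit.predict_qy(cu.values.to_numpy()), index=cu.values.index)
    first_year = series.dates[0].year - 1
    last_year = series.dates[-1].year
    rows, skipped = [], []
    for year in range(first_year, last_year + 1):
        start = pd.Timestamp(year, *season_start)
        end = pd.Timestamp(year + 1, *season_end)
        if start < cu.values.index[0] or end > cu.values.index[-1]:
            n_have = len(qy_pred.loc[start:end])
            if n_have:
                skipped.append((year, f"season {year} only partially covered"))
            continue
        rows.append((site.site_id, year, float(qy_pred.loc[start:end].min())))
    return pd.DataFrame(rows, columns=["site_id", "season", "min_qy"]), skipped


def fit_trend(annual_min: pd.DataFrame) -> TrendModel:
    """OLS of annual-minimum QY on season start year; needs >= 3 seasons."""
    if len(annual_min) < 3:
        raise ValueError(f"need at least 3 seasons, got {len(annual_min)}")
    x = annual_min["season"].to_numpy(dtype=float)
    y = annual_min["min_qy"].to_numpy(dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("all seasons share one year label")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    site = annual_min["site_id"].iloc[0] if "site_id" in annual_min else ""
    return TrendModel(
        site_id=str(site),
        slope=slope,
        intercept=float(ym - slope * xm),
        n_seasons=len(x),
        years=x,
        min_qy=y,
    )


def extrapolate(trend: TrendModel, target_year: float) -> float:
    """Trend-line QY at ``target_year``, clamped into [0, 1].

    At a year inside the fitted range this is exactly the regression
    line's value — there is no discontinuity between interpolation and
    extrapolation.
    """
    return float(np.clip(trend.line(target_year), 0.0, 1.0))


def count_suitable_sites(values, threshold: float = 0.20) -> int:
    """Sites whose predicted annual-minimum QY strictly exceeds the
    threshold (a site exactly at it does not count)."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite predicted QY values")
    return int((v > threshold).sum())


def map_decision_boundary(
    sites: pd.DataFrame,
    grid_resolution: float,
    svm_params: dict | None = None,
    bounding_box: tuple[float, float, float, float] | None = None,
    seed: int = 0,
) -> SuitabilityGrid:
    """SVM classification map of suitable/unsuitable sites (delegates to
    :func:`chillqy.geo.svm_interpolate` in classification mode)."""
    return svm_interpolate(
        sites,
        grid_resolution,
        mode="classification",
        svm_params=svm_params,
        bounding_box=bounding_box,
        seed=seed,
    )


def northern_boundary_latitude(grid: SuitabilityGrid) -> float:
    """Mean, over longitude columns, of the northernmost suitable cell
    latitude — a scalar summary of how far poleward the boundary sits."""
    cells = grid.cells
    if "suitable" not in cells:
        raise ValueError("grid has no class labels")
    suitable = cells[cells["suitable"]]
    if suitable.empty:
        raise ValueError("no suitable cells on the grid")
    return float(suitable.groupby("lon")["lat"].max().mean())
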