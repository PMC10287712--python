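"""Geographic suitability mapping from per-site chilling exposure.

Each station record is reduced to a single scalar — the period-maximum
chilling unit (worst winter on record) or a seasonal-minimum predicted
QY — and a support-vector machine trained on (latitude, longitude) fills
in a regular grid between the stations, either as a smooth regression
surface or as a suitable/unsuitable classification whose decision
boundary traces the plantation limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .chilling import (
    CUConfig,
    DailyTemperatureSeries,
    compute_cu,
    filter_by_missing_rate,
    impute_missing,
    period_max_cu,
)

__all__ = [
    "SiteRecord",
    "SuitabilityGrid",
    "site_period_max_cu",
    "network_period_max_cu",
    "svm_interpolate",
    "classify_suitability",
]

log = logging.getLogger(__name__)

ValueKind = Literal["cu_max", "qy_min"]


@dataclass
class SiteRecord:
    """A station: identifier, coordinates, daily temperature record."""

    site_id: str
    latitude: float
    longitude: float
    series: DailyTemperatureSeries

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180 <= self.longitude <= 180):
            raise ValueError(f"longitude {self.longitude} out of range")


@dataclass
class SuitabilityGrid:
    """Regular lat/lon lattice of interpolated values and class labels."""

    grid_resolution: float
    cells: pd.DataFrame  # columns lat, lon, value (+ suitable after classify)
    value_kind: ValueKind | None = None
    threshold: float | None = None
    training_predictions: pd.DataFrame | None = None
    svm_params: dict = field(default_factory=dict)

    @property
    def n_suitable(self) -> int:
        if "suitable" not in self.cells:
            raise ValueError("grid not yet classified")
        return int(self.cells["suitable"].sum())


def site_period_max_cu(
    site: SiteRecord,
    cu_config: CUConfig,
    period: tuple,
    max_missing_rate: float = 0.10,
) -> float:
    """Worst chilling exposure of one site over a period.

    Composition of the admission filter, neighbour-mean imputation, the
    chilling-unit computation and the period maximum.  Raises ValueError
    (site excluded) when the record fails the missing-rate filter or is
    shorter than the accumulation window.
    """
    decision = filter_by_missing_rate(site.series, cu_config.temp_stat, max_missing_rate)
    if not decision.accepted:
        raise ValueError(
            f"site {site.site_id} excluded: missing rate "
            f"{decision.missing_rate:.3f} > {max_missing_rate}"
        )
    if len(site.series) < cu_config.window + 1:
        raise ValueError(
            f"site {site.site_id} excluded: record of {len(site.series)} day(s) "
            f"shorter than window {cu_config.window} + 1"
        )
    imputed = impute_missing(site.series)
    cu = compute_cu(imputed, cu_config)
    return period_max_cu(cu, period)


def network_period_max_cu(
    sites: list[SiteRecord],
    cu_config: CUConfig,
    period: tuple,
    max_missing_rate: float = 0.10,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-site period-max CU over a network; excluded sites listed.

    Returns (frame with site_id, lat, lon, value) and a list of
    (site_id, reason) for sites that failed the filter or were too short.
    Output order follows the input order site by site, so the result is
    invariant to how the caller batches the network.
    """
    rows, excluded = [], []
    for site in sites:
        try:
            value = site_period_max_cu(site, cu_config, period, max_missing_rate)
        except ValueError as exc:
            excluded.append((site.site_id, str(exc)))
            continue
        rows.append((site.site_id, site.latitude, site.longitude, value))
    if excluded:
        log.info("%d site(s) excluded from the network", len(excluded))
    return (
        pd.DataFrame(rows, columns=["site_id", "lat", "lon", "value"]),
        excluded,
    )


def _grid_centres(
    bounding_box: tuple[float, float, float, float], resolution: float
) -> pd.DataFrame:
    """Regular lattice with origin at the box's south-west corner."""
    lat_min, lat_max, lon_min, lon_max = bounding_box
    lats = np.arange(lat_min, lat_max + resolution / 2, resolution)
    lons = np.arange(lon_min, lon_max + resolution / 2, resolution)
    gg = np.meshgrid(lats, lons, indexing="ij")
    return pd.DataFrame({"lat": gg[0].ravel(), "lon": gg[1].ravel()})


def svm_interpolate(
    sites: pd.DataFrame,
    grid_resolution: float,
    mode: Literal["regression", "classification"] = "regression",
    svm_params: dict | None = None,
    bounding_box: tuple[float, float, float, float] | None = None,
    seed: int = 0,
    cos_lat_scaling: bool = False,
) -> SuitabilityGrid:
    """Interpolate site values onto a lat/lon grid with an RBF SVM.

    ``sites`` needs columns lat, lon and value (regression) or suitable
    (classification).  Coordinates are fed in raw degrees by default;
    ``cos_lat_scaling`` multiplies longitude by cos(mean latitude) as a
    high-latitude sanity option.  Training-site predictions are attached
    for diagnostics.  Deterministic for fixed inputs, parameters and seed.
    """
    params = dict(svm_params or {})
    params.setdefault("kernel", "rbf")
    if len(sites) < 10:
        raise ValueError(f"need at least 10 sites, got {len(sites)}")
    target_col = "suitable" if mode == "classification" else "value"
    if target_col not in sites.columns:
        raise ValueError(f"sites frame lacks column {target_col!r} for mode {mode}")
    target = sites[target_col].to_numpy()
    if mode == "classification":
        if len(np.unique(target)) < 2:
            raise ValueError("classification needs both classes among the sites")
        svm = SVC(random_state=seed, **params)
        target = target.astype(int)
    elif mode == "regression":
        if not np.all(np.isfinite(sites["value"])):
            raise ValueError("non-finite site values")
        svm = SVR(**params)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if bounding_box is None:
        bounding_box = (
            float(sites["lat"].min()),
            float(sites["lat"].max()),
            float(sites["lon"].min()),
            float(sites["lon"].max()),
        )
    cells = _grid_centres(bounding_box, grid_resolution)

    def features(frame: pd.DataFrame) -> np.ndarray:
        X = frame[["lat", "lon"]].to_numpy(dtype=float)
        if cos_lat_scaling:
            X = X.copy()
            X[:, 1] *= np.cos(np.deg2rad(sites["lat"].mean()))
        return X

    svm.fit(features(sites), target)
    cells = cells.copy()
    pred = svm.predict(features(cells))
    train_pred = svm.predict(features(sites))
    if mode == "classification":
        cells["suitable"] = pred.astype(bool)
        training = sites[["lat", "lon"]].assign(predicted=train_pred.astype(bool))
    else:
        cells["value"] = pred
        training = sites[["lat", "lon"]].assign(predicted=train_pred)
    return SuitabilityGrid(
        grid_resolution=grid_resolution,
        cells=cells,
        training_predictions=training,
        svm_params=params,
    )


def classify_suitability(
    grid: SuitabilityGrid, threshold: float, value_kind: ValueKind
) -> tuple[SuitabilityGrid, int]:
    """Threshold interpolated values into suitable/unsuitable cells.

    For ``cu_max`` a cell is suitable when value <= threshold (a site at
    exactly the limiting chill counts as suitable); for ``qy_min`` when
    value >= threshold.  Returns the grid (suitable column added) and the
    suitable-cell count.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    cells = grid.cells.copy()
    if value_kind == "cu_max":
        cells["suitable"] = cells["value"] <= threshold
    elif value_kind == "qy_min":
        cells["suitable"] = cells["value"] >= threshold
    else:
        raise ValueError(f"unknown value_kind {value_kind!r}")
    out = SuitabilityGrid(
        grid_resolution=grid.grid_resolution,
        cells=cells,
        value_kind=value_kind,
        threshold=threshold,
        training_predictions=grid.training_predictions,
        svm_params=grid.svm_params,
    )
    return out, out.n_suitable
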