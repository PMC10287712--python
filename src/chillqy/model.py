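"""Logit-linear regression of quantum yield on chilling units.

The response is the leaf photosynthetic quantum yield QY in [0, 1],
modelled linearly on the logit scale:

    logit(QY) = a * CU + b + eps,    eps ~ N(0, sigma^2)

For one chilling-unit configuration the fit is ordinary least squares on
(CU, logit QY) pairs; the Gaussian log-likelihood uses the maximum-
likelihood variance RSS/n so that AIC = 2k - 2 logLik with k = 3 free
parameters (slope, intercept, residual variance) matches the Gaussian-GLM
convention.  Model selection is an exhaustive minimum-AIC search over a
threshold x window grid for all six chilling-unit families; the search is
vectorised over the grid but is exactly the per-configuration fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .chilling import (
    CUConfig,
    CUSeries,
    DailyTemperatureSeries,
    GridSpec,
    enumerate_grid,
)

__all__ = [
    "logit",
    "inverse_logit",
    "assemble_design",
    "fit_logit_linear",
    "grid_search",
    "ModelFit",
    "GridSearchResult",
    "DEFAULT_EPS",
    "AIC_TIE_TOL",
]

DEFAULT_EPS = 1e-3  # clamp bound: QY of exactly 0 or 1 must not give +-inf
AIC_TIE_TOL = 1e-9

Aggregation = Literal["per_observation", "per_line_date_mean"]


def logit(p, eps: float = DEFAULT_EPS):
    """log(p / (1-p)) with p clamped into [eps, 1-eps].

    Rejects values outside [0, 1]; the clamp only guards the boundaries so
    that QY readings of exactly 0 (deep-winter necrosis) stay finite.
    """
    p = np.asarray(p, dtype=float)
    if not (0 < eps < 0.5):
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = special.logit(np.clip(p, eps, 1 - eps))
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    """exp(x) / (1 + exp(x)); exact two-sided inverse of the clamped logit."""
    out = special.expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelFit:
    """OLS fit of logit(QY) on one chilling-unit series."""

    config: CUConfig | None
    a: float
    b: float
    sigma: float  # ML residual sd, sqrt(RSS/n)
    n_obs: int
    log_lik: float
    aic: float
    r_squared: float

    def predict_logit(self, cu) -> np.ndarray:
        return self.a * np.asarray(cu, dtype=float) + self.b

    def predict_qy(self, cu) -> np.ndarray:
        return inverse_logit(self.predict_logit(cu))


@dataclass
class GridSearchResult:
    """Exhaustive-search output: full fit table, argmin, near-ties."""

    fits: pd.DataFrame  # one row per config, enumeration order
    best: ModelFit
    tie_report: list[CUConfig] = field(default_factory=list)


def assemble_design(
    cu_series: CUSeries,
    observations: pd.DataFrame,
    aggregation: Aggregation = "per_line_date_mean",
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Pair each QY response with the chilling unit of its observation date.

    ``observations`` needs columns date, line, replicate, qy.  With
    ``per_line_date_mean`` the replicate leaves within (line, date) are
    averaged on the QY scale before the logit transform; with
    ``per_observation`` every leaf is its own response.  Returns a frame
    with columns date, line, cu, logit_qy.
    """
    obs = _check_observations(observations)
    if aggregation == "per_line_date_mean":
        obs = (
            obs.groupby(["line", "date"], as_index=False, sort=True)["qy"]
            .mean()
        )
    elif aggregation != "per_observation":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    missing = set(obs["date"]) - set(cu_series.values.index)
    if missing:
        d = min(missing)
        raise ValueError(
            f"no chilling-unit value for observation date {pd.Timestamp(d).date()}"
        )
    out = obs.copy()
    out["cu"] = cu_series.values.loc[out["date"]].to_numpy()
    out["logit_qy"] = logit(out["qy"].to_numpy(), eps=eps)
    return out[[c for c in ("date", "line", "replicate", "cu", "logit_qy") if c in out]]


def _check_observations(observations: pd.DataFrame) -> pd.DataFrame:
    if len(observations) == 0:
        raise ValueError("empty observation set")
    required = {"date", "line", "qy"}
    if not required.issubset(observations.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    obs = observations.copy()
    obs["date"] = pd.DatetimeIndex(obs["date"])
    q = obs["qy"].to_numpy(dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("qy values must lie in [0, 1]")
    return obs


def _ols_stats(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS plus Gaussian ML likelihood, shared scalar path."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    a = sxy / sxx
    b = ym - a * xm
    rss = max(syy - a * sxy, 0.0)
    sigma2 = rss / n
    with np.errstate(divide="ignore"):
        log_lik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    r_squared = 1.0 - rss / syy if syy > 0 else 1.0
    return a, b, rss, float(np.sqrt(sigma2)), float(log_lik), r_squared


def fit_logit_linear(
    pairs: pd.DataFrame | tuple[Sequence[float], Sequence[float]],
    config: CUConfig | None = None,
) -> ModelFit:
    """OLS of logit(QY) on CU with ML variance and k = 3 AIC.

    ``pairs`` is either the frame from :func:`assemble_design` or a
    (cu, logit_qy) pair of vectors.  Needs at least 3 pairs and a
    non-constant predictor.
    """
    if isinstance(pairs, pd.DataFrame):
        x = pairs["cu"].to_numpy(dtype=float)
        y = pairs["logit_qy"].to_numpy(dtype=float)
    else:
        x = np.asarray(pairs[0], dtype=float)
        y = np.asarray(pairs[1], dtype=float)
    if len(x) != len(y):
        raise ValueError("cu and logit_qy vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs to fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant chilling-unit predictor: slope unidentifiable")
    a, b, _rss, sigma, log_lik, r2 = _ols_stats(x, y)
    return ModelFit(
        config=config,
        a=a,
        b=b,
        sigma=sigma,
        n_obs=n,
        log_lik=log_lik,
        aic=6.0 - 2.0 * log_lik,
        r_squared=r2,
    )


def grid_search(
    series: DailyTemperatureSeries,
    observations: pd.DataFrame,
    spec: GridSpec | None = None,
    aggregation: Aggregation = "per_line_date_mean",
    temperature_sum_kind: str = "deficit",
    eps: float = DEFAULT_EPS,
) -> GridSearchResult:
    """Fit every chilling-unit configuration and select the minimum AIC.

    The temperature series must already be admitted and imputed, and every
    observation date must be preceded by at least max(L) - 1 days of
    record so the largest window is complete.  Configurations whose fit is
    unidentifiable (constant CU over the observation dates) are recorded
    with AIC = +inf rather than dropped.  Near-ties of the minimum (within
    1e-9) are broken by enumeration order and reported.
    """
    spec = spec or GridSpec()
    design = _aggregate_responses(observations, aggregation, eps)
    pos = series.dates.get_indexer(pd.DatetimeIndex(design["date"]))
    if np.any(pos < 0):
        bad = design["date"][pos < 0].iloc[0]
        raise ValueError(f"observation date {pd.Timestamp(bad).date()} not in series")
    max_L = int(spec.window_grid().max())
    shortfall = (max_L - 1) - int(pos.min())
    if shortfall > 0:
        raise ValueError(
            f"first observation date lacks {shortfall} day(s) of temperature "
            f"history for the largest window L={max_L}"
        )
    y = design["logit_qy"].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 responses, got {n}")
    ym = y.mean()
    syy = float(((y - ym) ** 2).sum())
    windows = spec.window_grid().astype(int)

    frames = []
    for cu_type in spec.cu_types:
        for stat in spec.temp_stats:
            x_days = series.stat(stat)
            if x_days.isna().any():
                raise ValueError(
                    f"missing {stat} values in series; impute before the search"
                )
            ths = spec.threshold_grid(stat)
            X = _cu_at_positions(
                x_days.to_numpy(), ths, windows, pos, cu_type, temperature_sum_kind
            )  # (n_th, n_L, n_obs)
            n_th, n_L, _ = X.shape
            X = X.reshape(n_th * n_L, n)
            frames.append(
                _vectorised_ols(X, y, ym, syy, cu_type, stat, ths, windows)
            )
    fits = pd.concat(frames, ignore_index=True)
    finite_min = fits["aic"].min()
    if not (finite_min < np.inf):
        raise ValueError("all configurations failed to fit (constant CU everywhere)")
    tie_mask = fits["aic"] <= finite_min + AIC_TIE_TOL
    tie_rows = fits[tie_mask]
    best_row = tie_rows.iloc[0]
    best = ModelFit(
        config=CUConfig(
            best_row["cu_type"],
            best_row["temp_stat"],
            float(best_row["threshold"]),
            int(best_row["window"]),
        ),
        a=float(best_row["a"]),
        b=float(best_row["b"]),
        sigma=float(best_row["sigma"]),
        n_obs=n,
        log_lik=float(best_row["log_lik"]),
        aic=float(best_row["aic"]),
        r_squared=float(best_row["r_squared"]),
    )
    ties = [
        CUConfig(r.cu_type, r.temp_stat, float(r.threshold), int(r.window))
        for r in tie_rows.itertuples()
    ]
    return GridSearchResult(fits=fits, best=best, tie_report=ties)


def _aggregate_responses(
    observations: pd.DataFrame, aggregation: Aggregation, eps: float
) -> pd.DataFrame:
    obs = _check_observations(observations)
    if aggregation == "per_line_date_mean":
        obs = obs.groupby(["line", "date"], as_index=False, sort=True)["qy"].mean()
    elif aggregation != "per_observation":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    obs = obs.sort_values(["date", "line"], kind="stable").reset_index(drop=True)
    obs["logit_qy"] = logit(obs["qy"].to_numpy(), eps=eps)
    return obs


def _cu_at_positions(
    x_days: np.ndarray,
    thresholds: np.ndarray,
    windows: np.ndarray,
    pos: np.ndarray,
    cu_type: str,
    temperature_sum_kind: str,
) -> np.ndarray:
    """CU values at selected day positions for a whole Th x L grid.

    Rolling window sums via one cumulative sum per threshold; the window
    ends on and includes the output day and uses strict T < Th.
    """
    below = x_days[None, :] < thresholds[:, None]
    if cu_type == "day_count":
        kernel = below.astype(float)
    elif temperature_sum_kind == "deficit":
        kernel = np.where(below, thresholds[:, None] - x_days[None, :], 0.0)
    elif temperature_sum_kind == "raw":
        kernel = np.where(below, x_days[None, :], 0.0)
    else:
        raise ValueError("temperature_sum_kind must be 'deficit' or 'raw'")
    cs = np.concatenate(
        [np.zeros((len(thresholds), 1)), np.cumsum(kernel, axis=1)], axis=1
    )
    hi = cs[:, pos + 1]  # (n_th, n_obs)
    lo_idx = (pos + 1)[None, :] - windows[:, None]  # (n_L, n_obs), all >= 0
    return hi[:, None, :] - cs[:, lo_idx]


def _vectorised_ols(
    X: np.ndarray,
    y: np.ndarray,
    ym: float,
    syy: float,
    cu_type: str,
    stat: str,
    thresholds: np.ndarray,
    windows: np.ndarray,
) -> pd.DataFrame:
    n = len(y)
    xm = X.mean(axis=1)
    xc = X - xm[:, None]
    sxx = (xc**2).sum(axis=1)
    sxy = xc @ (y - ym)
    ok = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        b = ym - a * xm
        rss = np.clip(syy - a * sxy, 0.0, None)
        sigma2 = rss / n
        log_lik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        aic = 6.0 - 2.0 * log_lik
        r2 = 1.0 - rss / syy if syy > 0 else np.ones_like(rss)
    aic = np.where(ok, aic, np.inf)
    nan = np.nan
    return pd.DataFrame(
        {
            "cu_type": cu_type,
            "temp_stat": stat,
            "threshold": np.repeat(thresholds, len(windows)),
            "window": np.tile(windows, len(thresholds)),
            "n_obs": n,
            "a": np.where(ok, a, nan),
            "b": np.where(ok, b, nan),
            "sigma": np.where(ok, np.sqrt(sigma2), nan),
            "log_lik": np.where(ok, log_lik, nan),
            "aic": aic,
            "r_squared": np.where(ok, r2, nan),
            "failed": ~ok,
        }
    )
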