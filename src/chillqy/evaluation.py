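"""Model validation: interval prediction, coverage counts, fit metrics.

Intervals are the standard simple-regression ones, built on the logit
scale with the unbiased residual variance s^2 = RSS/(n-2) and Student-t
quantiles (the AIC machinery uses the ML variance; interval calibration
holds exactly under the unbiased convention).  Because the inverse logit
is strictly monotone, interval endpoints map to endpoints on the QY
scale and coverage counts are identical on either scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import DEFAULT_EPS, ModelFit, inverse_logit, logit

__all__ = [
    "IntervalPrediction",
    "ValidationReport",
    "linear_intervals",
    "predict_with_intervals",
    "coverage_count",
    "prediction_metrics",
]

IntervalKind = Literal["confidence", "prediction"]


@dataclass(frozen=True)
class IntervalPrediction:
    """Point prediction with 95% mean-response (CI) and new-observation
    (PI) bounds, all on the QY scale."""

    date: object
    cu: float
    qy_hat: float
    ci_low: float
    ci_high: float
    pi_low: float
    pi_high: float


@dataclass(frozen=True)
class ValidationReport:
    season: str
    n_points: int
    n_within_interval: int
    interval_kind: IntervalKind
    pearson_r: float
    r_squared_pred: float


def linear_intervals(
    x_train: np.ndarray,
    y_train: np.ndarray,
    a: float,
    b: float,
    x_new: np.ndarray,
    level: float = 0.95,
):
    """CI/PI half-geometry of simple OLS on whatever scale x, y live on.

    Returns (y_hat, ci_low, ci_high, pi_low, pi_high).  The mean-response
    band is y_hat +- t * s * sqrt(1/n + (x - xbar)^2 / Sxx); the
    prediction band adds +1 under the square root.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    n = len(x_train)
    if n < 3:
        raise ValueError(f"need at least 3 training points, got {n}")
    xbar = x_train.mean()
    sxx = float(((x_train - xbar) ** 2).sum())
    if sxx == 0:
        raise ValueError("constant predictor: interval geometry undefined")
    resid = y_train - (a * x_train + b)
    s2 = float((resid**2).sum()) / (n - 2)
    s = np.sqrt(s2)
    tq = stats.t.ppf(0.5 + level / 2, n - 2)
    y_hat = a * x_new + b
    lev = 1.0 / n + (x_new - xbar) ** 2 / sxx
    half_ci = tq * s * np.sqrt(lev)
    half_pi = tq * s * np.sqrt(1.0 + lev)
    return y_hat, y_hat - half_ci, y_hat + half_ci, y_hat - half_pi, y_hat + half_pi


def predict_with_intervals(
    fit: ModelFit,
    cu_values: Sequence[float],
    training_pairs: pd.DataFrame | tuple,
    dates: Sequence | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted QY with 95% CI and PI at the given chilling-unit values.

    ``training_pairs`` must be the (cu, logit_qy) data the fit was computed
    on — the interval width depends on their leverage geometry.  Bounds are
    formed on the logit scale and mapped through the inverse logit.
    """
    if isinstance(training_pairs, pd.DataFrame):
        x_tr = training_pairs["cu"].to_numpy(dtype=float)
        y_tr = training_pairs["logit_qy"].to_numpy(dtype=float)
    else:
        x_tr = np.asarray(training_pairs[0], dtype=float)
        y_tr = np.asarray(training_pairs[1], dtype=float)
    if fit.n_obs < 3:
        raise ValueError("fit with fewer than 3 observations cannot give intervals")
    cu = np.asarray(cu_values, dtype=float)
    yh, cl, ch, pl, ph = linear_intervals(x_tr, y_tr, fit.a, fit.b, cu, level)
    out = pd.DataFrame(
        {
            "cu": cu,
            "qy_hat": inverse_logit(yh),
            "ci_low": inverse_logit(cl),
            "ci_high": inverse_logit(ch),
            "pi_low": inverse_logit(pl),
            "pi_high": inverse_logit(ph),
        }
    )
    if dates is not None:
        out.insert(0, "date", list(dates))
    return out


def coverage_count(
    predictions: pd.DataFrame,
    observations: pd.DataFrame,
    interval_kind: IntervalKind = "confidence",
) -> tuple[int, int]:
    """Count observations inside the chosen 95% band, endpoints inclusive.

    ``predictions`` is the frame from :func:`predict_with_intervals` (with
    a date column); ``observations`` needs columns date and qy.  Every
    observation date must have a prediction.
    """
    if interval_kind == "confidence":
        lo_col, hi_col = "ci_low", "ci_high"
    elif interval_kind == "prediction":
        lo_col, hi_col = "pi_low", "pi_high"
    else:
        raise ValueError(f"unknown interval_kind {interval_kind!r}")
    merged = observations.merge(
        predictions[["date", lo_col, hi_col]], on="date", how="left", validate="m:1"
    )
    if merged[lo_col].isna().any():
        bad = merged.loc[merged[lo_col].isna(), "date"].iloc[0]
        raise ValueError(f"no prediction for observation date {bad}")
    inside = (merged["qy"] >= merged[lo_col]) & (merged["qy"] <= merged[hi_col])
    return int(inside.sum()), len(merged)


def prediction_metrics(
    predicted: Sequence[float],
    observed: Sequence[float],
    scale: Literal["logit", "qy"] = "qy",
    eps: float = DEFAULT_EPS,
) -> tuple[float, float]:
    """Pearson r and predictive R^2 = 1 - sum (o-p)^2 / sum (o-obar)^2.

    Unlike an in-sample R^2 the predictive version is not bounded below by
    zero; it is reported as computed.  With ``scale='logit'`` both vectors
    are logit-transformed first.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o):
        raise ValueError("predicted and observed differ in length")
    if len(o) < 3:
        raise ValueError(f"need at least 3 points, got {len(o)}")
    if scale == "logit":
        p, o = logit(p, eps=eps), logit(o, eps=eps)
    elif scale != "qy":
        raise ValueError(f"unknown scale {scale!r}")
    if np.ptp(o) == 0:
        raise ValueError("constant observed vector: correlation undefined")
    # a constant prediction has no correlation with anything; keep R^2 defined
    r = float(np.corrcoef(p, o)[0, 1]) if np.ptp(p) > 0 else float("nan")
    ss_res = float(((o - p) ** 2).sum())
    ss_tot = float(((o - o.mean()) ** 2).sum())
    return r, 1.0 - ss_res / ss_tot
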