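"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive — double loops, polyfit, direct
density evaluation — and shares no code with the implementation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from chillqy import DailyTemperatureSeries


def make_series(
    tmax=None, tmin=None, tavg=None, start="2020-01-01", site_id="s"
) -> DailyTemperatureSeries:
    """Build a small series from plain lists (None fields filled from tavg
    or a constant so invariant checks stay quiet)."""
    vals = [v for v in (tmax, tmin, tavg) if v is not None]
    n = len(vals[0])
    base = np.asarray(vals[0], dtype=float)
    frame = pd.DataFrame(
        {
            "tmax": np.asarray(tmax, dtype=float) if tmax is not None else base + 5,
            "tmin": np.asarray(tmin, dtype=float) if tmin is not None else base - 5,
            "tavg": np.asarray(tavg, dtype=float) if tavg is not None else base,
        },
        index=pd.date_range(start, periods=n, freq="D"),
    )
    return DailyTemperatureSeries(site_id, frame)


def brute_cu(values, cu_type: str, th: float, L: int) -> np.ndarray:
    """Literal double loop over (output day, window day)."""
    values = np.asarray(values, dtype=float)
    out = []
    for d in range(L - 1, len(values)):
        acc = 0.0
        for t in values[d - L + 1 : d + 1]:
            if t < th:
                acc += 1.0 if cu_type == "day_count" else th - t
        out.append(acc)
    return np.array(out)


def ols_ml_oracle(x, y):
    """polyfit OLS plus direct Gaussian density evaluation at the residuals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    sigma = np.sqrt((resid**2).sum() / len(y))
    log_lik = stats.norm.logpdf(resid, 0.0, sigma).sum()
    return a, b, sigma, log_lik, 6.0 - 2.0 * log_lik
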