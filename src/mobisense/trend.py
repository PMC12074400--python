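"""Gradual mobility-decline detection via windowed linear regression.

Hourly activity levels are averaged into one daily activity level (DAL) per
day; an ordinary-least-squares line is fit to the most recent 21 days (day
index as regressor) and the slope, R² and two-sided p-value of the slope
summarize the trend.  A decline is flagged when the slope is negative and
statistically significant.  A compound 1 %/day reduction can be applied to a
series to emulate gradual mobility loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity_encoding import activity_level

__all__ = [
    "TrendResult",
    "daily_activity_levels",
    "apply_simulated_decline",
    "regress_trend",
    "rolling_trend",
    "plot_trend",
]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend over the analysis window.

    ``slope`` is in AL units per day; ``decline`` is true iff the slope is
    negative and its two-sided p-value is below ``alpha``.
    """

    window_days: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    decline: bool
    alpha: float = 0.05


def daily_activity_levels(vectors: pd.DataFrame) -> pd.Series:
    """Daily activity level: mean of the 24 hourly ALs of each day.

    Hours with no events are explicit zero rows upstream, so a partially
    quiet day is averaged over all 24 slices, not only the active ones.
    """
    al = activity_level(vectors)
    dal = al.groupby(vectors.index.get_level_values("date")).mean()
    dal.name = "DAL"
    dal.index.name = "date"
    return dal


def apply_simulated_decline(series: pd.Series, daily_rate: float = 0.01,
                            mode: str = "compound") -> pd.Series:
    """Scale a daily series by a simulated per-day activity reduction.

    ``compound`` multiplies day k by (1 - rate)^k; ``linear`` multiplies by
    (1 - rate*k) floored at zero.  Day 0 is always unchanged.
    """
    if not (0.0 <= daily_rate < 1.0):
        raise ValueError("daily rate must lie in [0, 1)")
    if mode not in ("compound", "linear"):
        raise ValueError(f"unknown decline mode {mode!r}")
    k = np.arange(len(series), dtype=float)
    if mode == "compound":
        factor = (1.0 - daily_rate) ** k
    else:
        factor = np.maximum(0.0, 1.0 - daily_rate * k)
    return series * factor


def regress_trend(series: pd.Series, window_days: int = 21,
                  alpha: float = 0.05) -> TrendResult:
    """OLS trend on the most recent ``window_days`` points of a daily series."""
    if len(series) < window_days:
        raise ValueError(
            f"series has {len(series)} days, shorter than window {window_days}"
        )
    y = series.to_numpy(dtype=float)[-window_days:]
    x = np.arange(window_days, dtype=float)
    if np.ptp(y) == 0.0:
        return TrendResult(window_days, 0.0, float(y[0]), 0.0, 1.0, False, alpha)
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue ** 2)
    p = float(fit.pvalue)
    return TrendResult(window_days, slope, intercept, r2, p,
                       decline=(slope < 0.0 and p < alpha), alpha=alpha)


def rolling_trend(series: pd.Series, window_days: int = 21,
                  alpha: float = 0.05) -> pd.DataFrame:
    """One :func:`regress_trend` result per day once a full window exists."""
    rows = []
    for end in range(window_days, len(series) + 1):
        res = regress_trend(series.iloc[:end], window_days, alpha)
        rows.append((series.index[end - 1], res.slope, res.intercept,
                     res.r_squared, res.p_value, res.decline))
    return pd.DataFrame(
        rows, columns=["window_end_date", "slope", "intercept", "R2",
                       "p_value", "decline_flag"],
    ).set_index("window_end_date")


def plot_trend(series: pd.Series, result: TrendResult, ax=None):
    """Scatter of daily activity levels with the fitted trend line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    y = series.to_numpy(dtype=float)[-result.window_days:]
    x = np.arange(result.window_days)
    ax.scatter(x, y, label="DAL")
    ax.plot(x, result.intercept + result.slope * x, color="C1",
            label=f"slope={result.slope:.3f}, R²={result.r_squared:.2f}, "
                  f"p={result.p_value:.3g}")
    ax.set_xlabel("day in window")
    ax.set_ylabel("daily activity level")
    ax.legend()
    return ax
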