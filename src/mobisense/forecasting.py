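"""Seasonal forecasting of per-place hourly activity.

The built-in baseline predicts each place's hourly count as the training mean
for that hour of day (optionally hour × weekday), capturing the daily and
weekly seasonality of a single resident's routine.  External univariate
forecasters can be plugged in through :class:`Forecaster`; each place
component is forecast independently and the predicted activity level is the
L2 norm of the assembled component vector.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .activity_encoding import activity_level

__all__ = [
    "Forecaster",
    "SeasonalBaselineForecaster",
    "fit_seasonal_baseline",
    "forecast_horizon",
    "evaluate_rmse",
    "get_forecaster",
    "register_forecaster",
    "FORECASTERS",
]


@runtime_checkable
class Forecaster(Protocol):
    """Contract for pluggable forecasters.

    ``fit`` receives the (date, hour)-indexed per-place training table;
    ``predict`` receives a (date, hour) MultiIndex and returns a same-shaped
    table of non-negative component predictions.
    """

    name: str

    def fit(self, train: pd.DataFrame) -> "Forecaster": ...

    def predict(self, index: pd.MultiIndex) -> pd.DataFrame: ...


class SeasonalBaselineForecaster:
    """Deterministic hour-of-day (or hour × weekday) mean profile.

    Modes
    -----
    ``hour``
        24 per-place means; needs at least 1 full training day.
    ``hour_x_weekday``
        168 per-place means; needs at least 7 full training days so every
        weekday is represented.
    """

    name = "baseline"

    def __init__(self, mode: str = "hour"):
        if mode not in ("hour", "hour_x_weekday"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self._means: pd.DataFrame | None = None
        self.columns_: list | None = None

    @staticmethod
    def _keys(index: pd.MultiIndex, mode: str):
        dates = pd.to_datetime(index.get_level_values("date"))
        hours = index.get_level_values("hour").astype(int)
        if mode == "hour":
            return pd.Index(hours, name="hour")
        return pd.MultiIndex.from_arrays([dates.weekday, hours],
                                         names=["weekday", "hour"])

    def fit(self, train: pd.DataFrame) -> "SeasonalBaselineForecaster":
        n_days = pd.Index(train.index.get_level_values("date")).nunique()
        need = 7 if self.mode == "hour_x_weekday" else 1
        if n_days < need:
            raise ValueError(
                f"mode {self.mode!r} needs >= {need} training day(s), got {n_days}"
            )
        keys = self._keys(train.index, self.mode)
        self._means = train.groupby(keys).mean()
        self.columns_ = list(train.columns)
        return self

    def predict(self, index: pd.MultiIndex) -> pd.DataFrame:
        if self._means is None:
            raise RuntimeError("forecaster is not fitted")
        keys = self._keys(index, self.mode)
        preds = self._means.reindex(keys)
        unseen = preds.isna().any(axis=1)
        if unseen.any():
            import warnings
            warnings.warn(
                f"{int(unseen.sum())} requested slice(s) have an hour/weekday "
                "combination unseen in training; predicting 0", stacklevel=2,
            )
            preds = preds.fillna(0.0)
        preds = preds.clip(lower=0.0)
        preds.index = index
        return preds


def fit_seasonal_baseline(train: pd.DataFrame,
                          mode: str = "hour") -> SeasonalBaselineForecaster:
    """Fit the built-in seasonal baseline on training activity vectors."""
    return SeasonalBaselineForecaster(mode=mode).fit(train)


def forecast_horizon(model: Forecaster, index: pd.MultiIndex) -> pd.DataFrame:
    """One non-negative forecast vector per requested (date, hour) slice."""
    return model.predict(index)


def evaluate_rmse(predictions: pd.DataFrame, observations: pd.DataFrame,
                  target: str = "norm") -> float:
    """Root-mean-squared forecast error.

    ``target='norm'`` compares the observed activity level (L2 norm of each
    observed vector) with the L2 norm of each forecast vector — the scalar
    series a monitoring dashboard would plot.  ``target='per_component'``
    pools the residuals of all K place components.
    """
    if target not in ("norm", "per_component"):
        raise ValueError(f"unknown RMSE target {target!r}")
    if not predictions.index.equals(observations.index):
        raise ValueError("prediction and observation slices are misaligned")
    if target == "norm":
        obs = activity_level(observations).to_numpy()
        pred = np.linalg.norm(predictions.to_numpy(dtype=float), axis=1)
        resid = obs - pred
    else:
        resid = (observations.to_numpy(dtype=float)
                 - predictions.to_numpy(dtype=float)).ravel()
    return float(np.sqrt(np.mean(resid ** 2)))


FORECASTERS: dict[str, type] = {"baseline": SeasonalBaselineForecaster}


def register_forecaster(name: str, cls: type) -> None:
    """Register an external forecaster class under a CLI-selectable name."""
    FORECASTERS[name] = cls


def get_forecaster(name: str, **kwargs) -> Forecaster:
    if name not in FORECASTERS:
        raise KeyError(f"unknown forecaster {name!r}; known: {sorted(FORECASTERS)}")
    return FORECASTERS[name](**kwargs)
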