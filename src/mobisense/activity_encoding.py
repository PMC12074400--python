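"""Behaviorally-meaningful-place (BMP) encoding of hourly sensor counts.

A residential space is abstracted as K places (kitchen, bedroom, circulation,
...), each backed by a set of sensors treated as one compound sensor.  Hourly
per-sensor counts are summed into a K-vector per hour — the activity vector —
whose L2 norm is the hourly activity level AL.  Averaging AL by hour of day
over a training span gives the historical activity level HAL(h), the baseline
against which observed activity is later judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BMPMap",
    "HourlyBaseline",
    "load_bmp_map",
    "encode_activity_vectors",
    "activity_level",
    "hourly_baseline",
]


@dataclass(frozen=True)
class BMPMap:
    """Ordered mapping place label → tuple of sensor ids.

    With ``allow_overlap`` false (the default) every sensor belongs to at most
    one place, so summing counts into places conserves the total event count.
    """

    places: tuple[tuple[str, tuple[str, ...]], ...]
    allow_overlap: bool = False

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.places]

    @property
    def k(self) -> int:
        return len(self.places)

    @property
    def sensors(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, ids in self.places:
            for s in ids:
                seen.setdefault(s, None)
        return list(seen)

    def sensor_place(self, sensor_id: str) -> str | None:
        """First-listed place of a sensor, or None if unmapped."""
        for label, ids in self.places:
            if sensor_id in ids:
                return label
        return None


def load_bmp_map(config: Mapping | str) -> BMPMap:
    """Build a validated :class:`BMPMap` from a config mapping or YAML path.

    Config layout::

        places:
          P1: [M001, M002, ...]
          P2: [...]
        allow_overlap: false        # optional
        on_duplicate: error|first   # optional, default error

    A sensor listed under two places is an error unless ``allow_overlap`` is
    true or ``on_duplicate: first`` is set, in which case the sensor is kept
    in its first-listed place (with a warning) so that event conservation
    still holds.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "places" not in config:
        raise ValueError("BMP config must be a mapping with a 'places' key")
    allow_overlap = bool(config.get("allow_overlap", False))
    on_duplicate = config.get("on_duplicate", "error")
    if on_duplicate not in ("error", "first"):
        raise ValueError(f"on_duplicate must be 'error' or 'first', got {on_duplicate!r}")

    places: list[tuple[str, tuple[str, ...]]] = []
    seen: dict[str, str] = {}
    for label, ids in config["places"].items():
        if not ids:
            raise ValueError(f"place {label!r} has no sensors")
        kept_ids = []
        for sid in ids:
            sid = str(sid)
            if sid in seen and not allow_overlap:
                if on_duplicate == "error":
                    raise ValueError(
                        f"sensor {sid} assigned to both {seen[sid]!r} and "
                        f"{label!r}; set allow_overlap or on_duplicate: first"
                    )
                warnings.warn(
                    f"sensor {sid} listed in both {seen[sid]!r} and {label!r}; "
                    f"keeping first-listed assignment {seen[sid]!r}",
                    stacklevel=2,
                )
                continue
            if sid in seen and allow_overlap:
                warnings.warn(
                    f"sensor {sid} overlaps places {seen[sid]!r} and {label!r}",
                    stacklevel=2,
                )
            seen.setdefault(sid, label)
            kept_ids.append(sid)
        if not kept_ids:
            raise ValueError(f"place {label!r} has no sensors after duplicate removal")
        places.append((str(label), tuple(kept_ids)))
    return BMPMap(places=tuple(places), allow_overlap=allow_overlap)


def load_shipped_bmp_map(name: str) -> BMPMap:
    """Load one of the packaged example maps (``aruba`` or ``hh120``)."""
    path = resources.files("mobisense.configs") / f"{name}_bmp.yaml"
    with resources.as_file(path) as p:
        return load_bmp_map(str(p))


def encode_activity_vectors(table: pd.DataFrame, bmp_map: BMPMap) -> pd.DataFrame:
    """Sum per-sensor hourly counts into per-place activity vectors.

    Returns a table indexed like ``table`` (date, hour) with one column per
    place.  Mapped sensors absent from the table contribute zero; table
    columns not in the map are ignored with a one-time warning.
    """
    unmapped = [c for c in table.columns if bmp_map.sensor_place(c) is None]
    if unmapped:
        warnings.warn(
            f"ignoring {len(unmapped)} unmapped sensor column(s): "
            f"{unmapped[:8]}", stacklevel=2,
        )
    out = pd.DataFrame(index=table.index)
    counted: set[str] = set()
    for label, ids in bmp_map.places:
        cols = [s for s in ids if s in table.columns and s not in counted]
        counted.update(cols)
        out[label] = table[cols].sum(axis=1).astype(int) if cols else 0
    return out


def activity_level(vectors: pd.DataFrame | Sequence[float] | np.ndarray):
    """Activity level AL: the L2 norm of the per-place count vector.

    Accepts a single vector (returns a float) or a (date, hour)-indexed table
    of vectors (returns a Series of AL values).
    """
    if isinstance(vectors, pd.DataFrame):
        return pd.Series(
            np.linalg.norm(vectors.to_numpy(dtype=float), axis=1),
            index=vectors.index, name="AL",
        )
    return float(np.linalg.norm(np.asarray(vectors, dtype=float)))


@dataclass
class HourlyBaseline:
    """Hour-of-day activity baseline learned from a training span.

    ``hal[h]`` is the mean of AL over all training slices at hour ``h``
    (mean of norms, not norm of the mean vector).  ``place_means`` holds the
    analogous per-place means used by the seasonal forecasting baseline.
    """

    hal: np.ndarray                      # shape (24,)
    place_means: pd.DataFrame            # index hour 0-23, columns = places
    n_training_slices: int = 0
    training_span: tuple | None = None

    def hal_at(self, hour: int) -> float:
        return float(self.hal[int(hour)])


def hourly_baseline(vectors: pd.DataFrame) -> HourlyBaseline:
    """Learn the hour-of-day baseline from training activity vectors.

    Hours never observed in training get HAL(h) = 0 with a warning.
    """
    if vectors.empty:
        raise ValueError("training data is empty")
    hours = vectors.index.get_level_values("hour")
    al = activity_level(vectors)
    hal = al.groupby(hours).mean().reindex(range(24))
    missing = hal.index[hal.isna()].tolist()
    if missing:
        warnings.warn(f"hours {missing} absent from training data; HAL set to 0",
                      stacklevel=2)
        hal = hal.fillna(0.0)
    place_means = vectors.groupby(hours).mean().reindex(range(24)).fillna(0.0)
    place_means.index.name = "hour"
    dates = vectors.index.get_level_values("date")
    return HourlyBaseline(
        hal=hal.to_numpy(dtype=float),
        place_means=place_means,
        n_training_slices=len(vectors),
        training_span=(min(dates), max(dates)),
    )
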