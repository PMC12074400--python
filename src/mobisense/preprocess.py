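"""Event filtering, per-sensor debouncing, and hourly aggregation.

The pipeline keeps only events that carry mobility information: motion-sensor
ON firings and door-contact OPEN firings.  Temperature, light and other
non-mobility sensors are dropped, as are the complementary OFF/CLOSE
transitions (a PIR's OFF merely marks the end of its retrigger window, not a
movement).  Repeat firings of the same sensor within a short interval are then
debounced, and the surviving events are counted per sensor per clock hour.
"""

from __future__ import annotations

from datetime import timedelta
from typing import Sequence

import pandas as pd

from .events_io import SensorEvent

__all__ = [
    "filter_relevant_events",
    "debounce_events",
    "aggregate_hourly",
    "preprocess_events",
]


def filter_relevant_events(events: Sequence[SensorEvent]) -> list[SensorEvent]:
    """Keep motion-ON and door-OPEN events; drop everything else."""
    kept = []
    for ev in events:
        if ev.category == "motion" and ev.value.upper() == "ON":
            kept.append(ev)
        elif ev.category == "door" and ev.value.upper() == "OPEN":
            kept.append(ev)
    return kept


def debounce_events(events: Sequence[SensorEvent],
                    threshold_seconds: float = 60.0,
                    mode: str = "anchor") -> list[SensorEvent]:
    """Suppress repeat firings of the same sensor within ``threshold_seconds``.

    Sensors are debounced independently; events of different sensors never
    suppress each other.  Two semantics are available:

    * ``anchor`` (default): scan in time order keeping the last *retained*
      event as anchor; drop events closer than the threshold to the anchor; a
      retained event becomes the new anchor.  A dropped event cannot itself
      suppress later events, so a long rapid burst collapses to events spaced
      at least one threshold apart.
    * ``raw``: compare each event to the previous *raw* event of the same
      sensor, so a burst with sub-threshold spacing collapses to its first
      event only.

    Input must be sorted by timestamp.  Idempotent: debouncing an already
    debounced sequence changes nothing.
    """
    if threshold_seconds <= 0:
        raise ValueError("debounce threshold must be positive")
    if mode not in ("anchor", "raw"):
        raise ValueError(f"unknown debounce mode: {mode!r}")
    thr = timedelta(seconds=threshold_seconds)
    last_kept: dict[str, object] = {}
    last_raw: dict[str, object] = {}
    kept: list[SensorEvent] = []
    for ev in events:
        ref = last_kept.get(ev.sensor_id) if mode == "anchor" else last_raw.get(ev.sensor_id)
        if ref is None or ev.timestamp - ref >= thr:
            kept.append(ev)
            last_kept[ev.sensor_id] = ev.timestamp
        last_raw[ev.sensor_id] = ev.timestamp
    return kept


def aggregate_hourly(events: Sequence[SensorEvent],
                     sensor_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Count events per sensor per clock hour.

    Returns a table indexed by (date, hour 0–23) with one integer column per
    sensor.  The hour bin is left-closed, right-open: an event at exactly
    10:00:00 counts in hour 10.  Every hour of every day in the observed date
    span is present, with explicit zeros where nothing fired.

    ``sensor_ids`` optionally fixes the column set (sensors that never fire
    still get a zero column); otherwise columns are the sensors observed.
    """
    if not events:
        cols = sorted(sensor_ids) if sensor_ids else []
        idx = pd.MultiIndex.from_arrays([[], []], names=["date", "hour"])
        return pd.DataFrame(0, index=idx, columns=cols, dtype=int)

    df = pd.DataFrame(
        {
            "date": [e.timestamp.date() for e in events],
            "hour": [e.timestamp.hour for e in events],
            "sensor_id": [e.sensor_id for e in events],
        }
    )
    counts = (
        df.groupby(["date", "hour", "sensor_id"]).size().unstack(fill_value=0)
    )
    if sensor_ids:
        counts = counts.reindex(columns=sorted(set(sensor_ids) | set(counts.columns)),
                                fill_value=0)
    counts = counts[sorted(counts.columns)]

    first, last = df["date"].min(), df["date"].max()
    all_days = pd.date_range(first, last, freq="D").date
    full_idx = pd.MultiIndex.from_product([all_days, range(24)],
                                          names=["date", "hour"])
    counts = counts.reindex(full_idx, fill_value=0).astype(int)
    counts.columns.name = None
    return counts


def preprocess_events(events: Sequence[SensorEvent],
                      debounce_seconds: float = 60.0,
                      debounce_mode: str = "anchor",
                      sensor_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Filter → debounce → aggregate, in that order.

    Filtering comes first so that discarded OFF/CLOSE transitions cannot
    suppress the ON/OPEN events that follow them within the debounce window.
    """
    kept = filter_relevant_events(events)
    kept = debounce_events(kept, debounce_seconds, debounce_mode)
    return aggregate_hourly(kept, sensor_ids=sensor_ids)
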