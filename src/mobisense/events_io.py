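"""Reading and writing CASAS-dialect binary-sensor event logs.

CASAS smart-home testbeds publish plain-text logs with one sensor event per
line.  Two dialects are supported:

* ``aruba``:  ``<date> <time> <sensor_id> <value> [<activity ...>]``
* ``hh120``:  ``<date> <time> <sensor_id> <location> <value> [<activity ...>]``

Timestamps follow the CASAS convention ``YYYY-MM-DD HH:MM:SS`` with optional
fractional seconds.  Any other layout is rejected rather than guessed, since a
silently mis-parsed timestamp would corrupt the hourly aggregation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence, TextIO

import pandas as pd

__all__ = [
    "SensorEvent",
    "ReadResult",
    "DialectError",
    "DEFAULT_CATEGORY_PREFIXES",
    "sensor_category",
    "read_casas_events",
    "write_events",
    "write_hourly_counts",
    "read_hourly_counts",
]

#: Prefix → category map used when no override is supplied.  Longest prefix
#: wins, so "MA016" is motion even though "M" alone would also match.
DEFAULT_CATEGORY_PREFIXES: dict[str, str] = {
    "MA": "motion",
    "M": "motion",
    "D": "door",
    "T": "temperature",
    "LS": "light",
    "L": "light",
}

_TS_FORMATS = ("%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S")

#: Sensor-value tokens used to tell the two dialects apart on 5-token lines.
_VALUE_TOKENS = {"ON", "OFF", "OPEN", "CLOSE", "ABSENT", "PRESENT"}


class DialectError(ValueError):
    """Raised when a stream does not parse as the requested dialect."""


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped firing of a binary sensor.

    ``category`` is derived from the sensor-id prefix (or a config override);
    ``location`` is only populated by the 5-field HH120 dialect; ``activity``
    preserves the raw annotation token(s) verbatim, including CASAS
    ``begin``/``end`` markers.
    """

    timestamp: datetime
    sensor_id: str
    value: str
    category: str = "other"
    location: str | None = None
    activity: str | None = None


@dataclass
class ReadResult:
    """Parsed events plus bookkeeping from :func:`read_casas_events`."""

    events: list[SensorEvent] = field(default_factory=list)
    skipped: int = 0
    dialect: str = "aruba"

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def sensor_category(sensor_id: str, prefixes: dict[str, str] | None = None) -> str:
    """Category of a sensor id by longest-prefix match; ``other`` if none."""
    prefixes = prefixes if prefixes is not None else DEFAULT_CATEGORY_PREFIXES
    for pref in sorted(prefixes, key=len, reverse=True):
        if sensor_id.startswith(pref):
            return prefixes[pref]
    return "other"


def _parse_timestamp(date_tok: str, time_tok: str) -> datetime | None:
    raw = f"{date_tok} {time_tok}"
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(raw, fmt)
        except ValueError:
            continue
    return None


def _parse_line(tokens: list[str], dialect: str,
                prefixes: dict[str, str] | None) -> SensorEvent | None:
    if dialect == "aruba":
        if len(tokens) < 4:
            return None
        ts = _parse_timestamp(tokens[0], tokens[1])
        if ts is None:
            return None
        sensor_id, value = tokens[2], tokens[3]
        activity = " ".join(tokens[4:]) or None
        location = None
    else:  # hh120
        if len(tokens) < 5:
            return None
        ts = _parse_timestamp(tokens[0], tokens[1])
        if ts is None:
            return None
        sensor_id, location, value = tokens[2], tokens[3], tokens[4]
        activity = " ".join(tokens[5:]) or None
    return SensorEvent(
        timestamp=ts,
        sensor_id=sensor_id,
        value=value,
        category=sensor_category(sensor_id, prefixes),
        location=location,
        activity=activity,
    )


def _detect_dialect(lines: list[list[str]]) -> str:
    """Vote over non-empty lines: a value-like 4th token means Aruba."""
    votes = {"aruba": 0, "hh120": 0}
    for tokens in lines:
        if len(tokens) < 4:
            continue
        if tokens[3].upper() in _VALUE_TOKENS:
            votes["aruba"] += 1
        elif len(tokens) >= 5 and tokens[4].upper() in _VALUE_TOKENS:
            votes["hh120"] += 1
        elif len(tokens) == 4:
            votes["aruba"] += 1
        else:
            votes["hh120"] += 1
    return "hh120" if votes["hh120"] > votes["aruba"] else "aruba"


def read_casas_events(
    source: TextIO | str | Iterable[str],
    dialect: str = "auto",
    category_prefixes: dict[str, str] | None = None,
    max_skip_fraction: float = 0.10,
) -> ReadResult:
    """Parse a CASAS event log.

    Parameters
    ----------
    source
        A text stream, a path, or an iterable of lines.
    dialect
        ``aruba`` (4-field), ``hh120`` (5-field, with a location token) or
        ``auto`` to detect from the token layout.
    category_prefixes
        Optional override of the sensor-id prefix → category map.
    max_skip_fraction
        If more than this fraction of non-empty lines fail to parse, a
        :class:`DialectError` is raised (the dialect is presumed wrong).

    Returns
    -------
    ReadResult
        Events sorted by timestamp (stable on input order for ties), the
        number of skipped lines, and the dialect actually used.
    """
    if dialect not in ("aruba", "hh120", "auto"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(source, str):
        with open(source, "r") as fh:
            return read_casas_events(fh, dialect, category_prefixes,
                                     max_skip_fraction)
    token_lines = [ln.split() for ln in source]
    token_lines = [t for t in token_lines if t]
    if not token_lines:
        return ReadResult([], 0, dialect if dialect != "auto" else "aruba")
    if dialect == "auto":
        dialect = _detect_dialect(token_lines)

    events: list[SensorEvent] = []
    skipped = 0
    for tokens in token_lines:
        ev = _parse_line(tokens, dialect, category_prefixes)
        if ev is None:
            skipped += 1
        else:
            events.append(ev)
    if skipped / len(token_lines) > max_skip_fraction:
        raise DialectError(
            f"{skipped}/{len(token_lines)} lines unparseable as dialect "
            f"{dialect!r}; wrong dialect or corrupt file"
        )
    events.sort(key=lambda e: e.timestamp)  # sort() is stable: ties keep input order
    return ReadResult(events, skipped, dialect)


def _format_timestamp(ts: datetime) -> str:
    if ts.microsecond:
        return ts.strftime("%Y-%m-%d %H:%M:%S.%f")
    return ts.strftime("%Y-%m-%d %H:%M:%S")


def write_events(events: Sequence[SensorEvent], sink: TextIO | str,
                 dialect: str = "aruba") -> int:
    """Write events in a CASAS dialect; returns the number of lines written.

    Re-reading the sink with the same dialect reproduces the events
    field-for-field (round-trip identity).  Events must carry sortable
    timestamps and be in timestamp order.
    """
    if dialect not in ("aruba", "hh120"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            return write_events(events, fh, dialect)
    last = None
    n = 0
    for ev in events:
        if ev.timestamp is None or pd.isna(ev.timestamp):
            raise ValueError(f"event {ev.sensor_id} has an unusable timestamp")
        if last is not None and ev.timestamp < last:
            raise ValueError("events must be sorted by timestamp before writing")
        last = ev.timestamp
        fields = [_format_timestamp(ev.timestamp), ev.sensor_id]
        if dialect == "hh120":
            fields.append(ev.location if ev.location is not None else "Ignore")
        fields.append(ev.value)
        if ev.activity is not None:
            fields.append(ev.activity)
        sink.write(" ".join(fields) + "\n")
        n += 1
    return n


def events_to_frame(events: Iterable[SensorEvent]) -> pd.DataFrame:
    """Tabular view of an event sequence (one row per event)."""
    return pd.DataFrame(
        {
            "timestamp": [e.timestamp for e in events],
            "sensor_id": [e.sensor_id for e in events],
            "category": [e.category for e in events],
            "value": [e.value for e in events],
            "location": [e.location for e in events],
            "activity": [e.activity for e in events],
        }
    )


def write_hourly_counts(table: pd.DataFrame, sink: TextIO | str) -> None:
    """Write an hourly-count table as ``Date,Hour,Events_count_<id>,...`` CSV.

    ``table`` is indexed by (date, hour) with one column per sensor id and
    non-negative integer cells.  Duplicate (date, hour) keys are rejected.
    """
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate (date, hour) keys: {dupes[:5]}")
    if (table.to_numpy() < 0).any():
        raise ValueError("hourly counts must be non-negative")
    out = table.copy()
    out.columns = [f"Events_count_{c}" for c in out.columns]
    out.insert(0, "Hour", [h for _, h in table.index])
    out.insert(0, "Date", [pd.Timestamp(d).strftime("%Y-%m-%d") for d, _ in table.index])
    if isinstance(sink, str):
        out.to_csv(sink, index=False)
    else:
        out.to_csv(sink, index=False)


def read_hourly_counts(source: TextIO | str) -> pd.DataFrame:
    """Read the hourly-count CSV back into a (date, hour)-indexed table."""
    df = pd.read_csv(source)
    if "Date" not in df.columns or "Hour" not in df.columns:
        raise ValueError("hourly-count CSV must have Date and Hour columns")
    dates = pd.to_datetime(df["Date"]).dt.date
    hours = df["Hour"].astype(int)
    counts = df.drop(columns=["Date", "Hour"])
    counts.columns = [c.removeprefix("Events_count_") for c in counts.columns]
    counts.index = pd.MultiIndex.from_arrays([dates, hours], names=["date", "hour"])
    if counts.index.duplicated().any():
        raise ValueError("duplicate (date, hour) keys in hourly-count CSV")
    return counts.astype(int)
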