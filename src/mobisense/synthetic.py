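"""Synthetic single-resident event streams with injectable mobility anomalies.

The generator emulates the statistical structure the detection pipeline
assumes: a regular daily routine expressed as per-place, per-hour expected
retained-event counts, with optional weekday modulation.  Hourly counts are
drawn Poisson, apportioned uniformly across the sensors of the place, and
event times are laid out with a minimum per-sensor spacing wider than the
debounce threshold, so the stream passes preprocessing unchanged and every
pipeline stage is testable without external recordings.

Anomalies are injected at two levels: point anomalies (prolonged inactivity
or outings) edit the event stream directly and are logged as ground truth;
gradual decline scales the generative intensities by a compounding per-day
factor, mimicking slowly fading mobility.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np

from .events_io import SensorEvent, sensor_category
from .evaluation import GroundTruthPeriod

__all__ = [
    "AnomalySpec",
    "SimConfig",
    "default_sim_config",
    "simulate_event_stream",
    "inject_point_anomalies",
    "inject_gradual_decline",
    "sample_daytime_inactivity",
]


@dataclass(frozen=True)
class AnomalySpec:
    """A point anomaly to inject: [start, end) of kind inactivity | outing."""

    start: datetime
    end: datetime
    kind: str = "inactivity"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("anomaly end must follow start")
        if self.kind not in ("inactivity", "outing"):
            raise ValueError(f"unknown anomaly kind {self.kind!r}")


@dataclass(frozen=True)
class SimConfig:
    """Generative description of a monitored single-resident home.

    ``profile[place]`` is a 24-vector of expected retained events per hour;
    ``weekday_factors`` modulates whole days (Monday first).  ``min_gap``
    (seconds) is the spacing enforced between events of the same sensor so
    the stream survives a 60 s debounce untouched.  ``decline_rate`` > 0
    compounds a per-day intensity reduction from ``decline_start_day`` on.
    """

    sensors: dict[str, str]                      # sensor id -> place label
    profile: dict[str, tuple[float, ...]]        # place -> 24 hourly rates
    days: int = 21
    start_date: date = date(2024, 3, 4)          # a Monday
    weekday_factors: tuple[float, ...] = (1.0,) * 7
    min_gap: float = 70.0
    door_sensor: str | None = None
    anomalies: tuple[AnomalySpec, ...] = ()
    decline_start_day: int | None = None
    decline_rate: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("span must be at least one day")
        if self.min_gap <= 0:
            raise ValueError("minimum inter-event gap must be positive")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout probability must lie in [0, 1)")
        if not (0.0 <= self.decline_rate < 1.0):
            raise ValueError("decline rate must lie in [0, 1)")
        if len(self.weekday_factors) != 7:
            raise ValueError("weekday_factors needs 7 entries (Monday first)")
        places = set(self.sensors.values())
        for place, rates in self.profile.items():
            if len(rates) != 24:
                raise ValueError(f"profile for {place!r} needs 24 hourly rates")
            if any(r < 0 for r in rates):
                raise ValueError(f"negative intensity in profile for {place!r}")
            n_sensors = sum(1 for p in self.sensors.values() if p == place)
            if n_sensors == 0:
                raise ValueError(f"place {place!r} has no sensors")
            # Expected counts must leave headroom for the spacing constraint.
            peak = max(rates) * max(self.weekday_factors)
            if peak > 0.5 * n_sensors * 3600.0 / self.min_gap:
                raise ValueError(
                    f"intensity {peak:g} for {place!r} too high for "
                    f"{n_sensors} sensor(s) at min gap {self.min_gap:g}s"
                )
        for place in places - set(self.profile):
            raise ValueError(f"no intensity profile for place {place!r}")
        span_start = datetime.combine(self.start_date, datetime.min.time())
        span_end = span_start + timedelta(days=self.days)
        for a in self.anomalies:
            if a.start < span_start or a.end > span_end:
                raise ValueError(f"anomaly {a} outside the simulated span")

    @property
    def places(self) -> list[str]:
        return list(self.profile)

    def place_sensors(self, place: str) -> list[str]:
        return [s for s, p in self.sensors.items() if p == place]


#: Default routine: quiet nights, kitchen peaks at meal times, living-room
#: presence through the day and evening, constant low bathroom use, sparse
#: entrance/door traffic.  Units: expected retained events per hour.
_DEFAULT_PROFILE: dict[str, tuple[float, ...]] = {
    "kitchen": (0, 0, 0, 0, 0, 0, 4, 20, 16, 4, 4, 4, 16, 12, 4, 4, 4, 8, 20, 16,
                4, 2, 0, 0),
    "living": (0, 0, 0, 0, 0, 0, 2, 4, 8, 16, 16, 16, 8, 12, 20, 20, 16, 12, 8,
               12, 16, 12, 2, 0),
    "bedroom": (1.2, 1.2, 1.2, 1.2, 1.2, 1.2, 12, 4, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2,
                2, 2, 2, 4, 16, 4),
    "bathroom": (0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 12, 8, 4, 4, 4, 4, 4, 4, 4, 4, 4,
                 4, 4, 4, 4, 8, 8, 2),
    "entrance": (0, 0, 0, 0, 0, 0, 0, 2, 4, 2, 2, 1.2, 1.2, 1.2, 1.2, 1.2, 2, 4,
                 2, 1.2, 1.2, 0.8, 0, 0),
}

_DEFAULT_SENSORS: dict[str, str] = {
    "M001": "kitchen", "M002": "kitchen", "M003": "kitchen",
    "M004": "living", "M005": "living", "M006": "living",
    "M007": "bedroom", "M008": "bedroom",
    "M009": "bathroom",
    "M010": "entrance", "D001": "entrance", "D002": "entrance",
}


def default_sim_config(days: int = 21, **overrides) -> SimConfig:
    """The packaged single-resident routine over ``days`` days."""
    cfg = dict(
        sensors=dict(_DEFAULT_SENSORS),
        profile={p: tuple(v) for p, v in _DEFAULT_PROFILE.items()},
        days=days,
        door_sensor="D001",
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def _place_times(rng: np.random.Generator, hour_start: datetime, k: int,
                 earliest: datetime, gap: float) -> list[datetime]:
    """k event times in [hour_start, hour_start+1h) spaced >= gap seconds,
    the first no earlier than ``earliest`` (spacing from the previous hour)."""
    window_start = max(hour_start, earliest)
    window = (hour_start + timedelta(hours=1) - window_start).total_seconds()
    slack = window - (k - 1) * gap
    if slack <= 0:
        raise ValueError(
            f"cannot place {k} events with gap {gap:g}s in {window:g}s"
        )
    offsets = np.sort(rng.uniform(0.0, slack, size=k))
    return [window_start + timedelta(seconds=float(off + i * gap))
            for i, off in enumerate(offsets)]


def simulate_event_stream(
    config: SimConfig, seed: int | np.random.Generator = 0,
) -> tuple[list[SensorEvent], list[GroundTruthPeriod]]:
    """Draw a full event stream and the ground-truth log of injected anomalies.

    Deterministic for a fixed (config, seed).  Returns timestamp-sorted
    events (motion sensors fire ON, door sensors OPEN) and one
    :class:`GroundTruthPeriod` per injected anomaly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[SensorEvent] = []
    last_time: dict[str, datetime] = {}
    gap = config.min_gap

    for d in range(config.days):
        day = config.start_date + timedelta(days=d)
        wfactor = config.weekday_factors[day.weekday()]
        decline = 1.0
        if config.decline_start_day is not None and d >= config.decline_start_day:
            decline = (1.0 - config.decline_rate) ** (d - config.decline_start_day)
        for hour in range(24):
            hour_start = datetime.combine(day, datetime.min.time()) + timedelta(hours=hour)
            for place in config.places:
                lam = config.profile[place][hour] * wfactor * decline
                count = int(rng.poisson(lam)) if lam > 0 else 0
                if count == 0:
                    continue
                sensors = config.place_sensors(place)
                picks = rng.integers(0, len(sensors), size=count)
                per_sensor: dict[str, int] = {}
                for i in picks:
                    sid = sensors[int(i)]
                    per_sensor[sid] = per_sensor.get(sid, 0) + 1
                for sid in sensors:           # fixed order for determinism
                    k = per_sensor.get(sid, 0)
                    if k == 0:
                        continue
                    earliest = last_time.get(sid, datetime.min) + timedelta(seconds=gap)
                    times = _place_times(rng, hour_start, k, earliest, gap)
                    last_time[sid] = times[-1]
                    cat = sensor_category(sid)
                    value = "OPEN" if cat == "door" else "ON"
                    for ts in times:
                        events.append(SensorEvent(timestamp=ts, sensor_id=sid,
                                                  value=value, category=cat))

    if config.dropout_prob > 0:
        keep = rng.uniform(size=len(events)) >= config.dropout_prob
        events = [e for e, k in zip(events, keep) if k]

    events.sort(key=lambda e: e.timestamp)
    truth: list[GroundTruthPeriod] = []
    if config.anomalies:
        events, truth = inject_point_anomalies(
            events, config.anomalies, door_sensor=config.door_sensor
        )
    return events, truth


def inject_point_anomalies(
    events: Sequence[SensorEvent],
    anomalies: Sequence[AnomalySpec],
    kind: str | None = None,
    door_sensor: str | None = None,
) -> tuple[list[SensorEvent], list[GroundTruthPeriod]]:
    """Carve point anomalies out of an event stream.

    ``inactivity`` removes every event inside the interval.  ``outing`` does
    the same but adds door-OPEN events at both interval boundaries on
    ``door_sensor`` (leaving and returning).  Intervals must not overlap.
    ``kind`` overrides the kind of every supplied spec when given.
    """
    specs = [
        a if kind is None else AnomalySpec(a.start, a.end, kind)
        for a in anomalies
    ]
    ordered = sorted(specs, key=lambda a: a.start)
    for first, second in zip(ordered, ordered[1:]):
        if second.start < first.end:
            raise ValueError(
                f"injected intervals overlap: {first.start}-{first.end} "
                f"and {second.start}-{second.end}"
            )
    out = [
        e for e in events
        if not any(a.start <= e.timestamp < a.end for a in ordered)
    ]
    log: list[GroundTruthPeriod] = []
    for a in ordered:
        if a.kind == "outing":
            if door_sensor is None:
                raise ValueError("outing injection requires a door sensor")
            for ts in (a.start, a.end):
                out.append(SensorEvent(timestamp=ts, sensor_id=door_sensor,
                                       value="OPEN", category="door"))
        log.append(GroundTruthPeriod(a.start, a.end, label=a.kind,
                                     source="injection"))
    out.sort(key=lambda e: e.timestamp)
    return out, log


def inject_gradual_decline(config: SimConfig, start_day: int = 0,
                           daily_rate: float = 0.01) -> SimConfig:
    """Return a config whose intensities fade by ``daily_rate`` per day.

    From ``start_day`` on, day d's intensities are scaled by
    (1 - daily_rate)^(d - start_day), so the expected daily activity level
    declines compoundly — the generative analogue of a slow mobility loss.
    """
    if not (0.0 <= daily_rate < 1.0):
        raise ValueError("daily rate must lie in [0, 1)")
    if not (0 <= start_day < config.days):
        raise ValueError("decline start day outside the simulated span")
    return replace(config, decline_start_day=start_day, decline_rate=daily_rate)


def sample_daytime_inactivity(
    config: SimConfig,
    n_periods: int,
    seed: int | np.random.Generator = 0,
    first_day: int = 0,
    hour_range: tuple[int, int] = (8, 18),
    duration_hours: tuple[float, float] = (1.5, 3.0),
) -> list[AnomalySpec]:
    """Draw non-overlapping daytime inactivity intervals, one per chosen day.

    Days are sampled without replacement from [first_day, config.days), so
    intervals can never overlap.  Start hour is uniform over ``hour_range``
    and duration uniform over ``duration_hours`` (hours).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    available = config.days - first_day
    if n_periods > available:
        raise ValueError(f"cannot place {n_periods} one-per-day periods in "
                         f"{available} days")
    days = rng.choice(np.arange(first_day, config.days), size=n_periods,
                      replace=False)
    specs = []
    for d in sorted(int(x) for x in days):
        dur = float(rng.uniform(*duration_hours))
        latest_start = hour_range[1] - dur
        start_h = float(rng.uniform(hour_range[0], latest_start))
        start = (datetime.combine(config.start_date, datetime.min.time())
                 + timedelta(days=d, hours=start_h))
        specs.append(AnomalySpec(start, start + timedelta(hours=dur),
                                 kind="inactivity"))
    return specs
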