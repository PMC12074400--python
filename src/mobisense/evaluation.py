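"""Ground-truth extraction and detection scoring for inactivity anomalies.

Ground truth is a set of prolonged-inactivity periods (> 1 h by default,
nighttime excluded), obtained either from a simulator's injection log or from
gaps in an annotated event stream.  Scoring uses mixed counting units that
match how prolonged-inactivity detection is naturally evaluated: true
positives and false negatives are counted over ground-truth *periods* (a
period is detected if any overlapping hourly slice raises an alert), while
false positives and true negatives are counted over the normal hourly
*slices* outside the night window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, time, timedelta
from typing import Sequence

import pandas as pd

from .events_io import SensorEvent

__all__ = [
    "GroundTruthPeriod",
    "ConfusionCounts",
    "DetectionMetrics",
    "extract_inactivity_ground_truth",
    "score_detection",
    "detection_metrics",
    "metrics_report",
]

#: Annotation fragments that mark legitimate low-activity context.
DEFAULT_CONTEXT_KEYWORDS = ("leave", "enter", "out", "relax")


@dataclass(frozen=True)
class GroundTruthPeriod:
    """A known low-activity interval: [start, end), with its provenance."""

    start: datetime
    end: datetime
    label: str = "inactivity"          # inactivity | outing | decline
    source: str = "annotation"         # annotation | injection

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"period end must follow start: {self}")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN over ground-truth periods; FP/TN over normal hourly slices."""

    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class DetectionMetrics:
    """Detection rate TP/(TP+FN) and false-positive rate FP/(FP+TN).

    ``*_display`` are truncated (not rounded) to two decimals, the rendering
    convention used for reporting: 49/60 = 0.8166... displays as 0.81.
    """

    detection_rate: float
    false_positive_rate: float

    @property
    def detection_rate_display(self) -> float:
        return math.floor(self.detection_rate * 100) / 100

    @property
    def false_positive_rate_display(self) -> float:
        return math.floor(self.false_positive_rate * 100) / 100


def _in_night(ts_start: datetime, ts_end: datetime,
              night_window: tuple[int, int]) -> bool:
    """Does [ts_start, ts_end) intersect the (possibly wrapping) night window?"""
    night_start, night_end = night_window
    t = ts_start
    while t < ts_end:
        h = t.hour
        if night_start > night_end:          # wraps midnight, e.g. 22 -> 7
            if h >= night_start or h < night_end:
                return True
        elif night_start <= h < night_end:
            return True
        t = (t.replace(minute=0, second=0, microsecond=0) + timedelta(hours=1))
    return False


def extract_inactivity_ground_truth(
    events: Sequence[SensorEvent] | None = None,
    min_duration: timedelta = timedelta(hours=1),
    night_window: tuple[int, int] = (22, 7),
    injection_log: Sequence[GroundTruthPeriod] | pd.DataFrame | None = None,
    context_keywords: Sequence[str] = DEFAULT_CONTEXT_KEYWORDS,
) -> list[GroundTruthPeriod]:
    """Derive the set of true prolonged-inactivity periods.

    Preference order: a simulator ``injection_log`` (exact by construction)
    is passed through, keeping periods longer than ``min_duration`` that do
    not touch the night window.  Otherwise, maximal gaps between successive
    retained events exceeding ``min_duration`` become candidate periods;
    where the bordering events carry annotations, a gap is kept only if some
    bordering annotation matches an outing/relaxation keyword.  With neither
    an injection log nor annotated events, ground truth is unobtainable.
    """
    if injection_log is not None:
        if isinstance(injection_log, pd.DataFrame):
            periods = [
                GroundTruthPeriod(
                    start=pd.Timestamp(r["start"]).to_pydatetime(),
                    end=pd.Timestamp(r["end"]).to_pydatetime(),
                    label=str(r.get("kind", "inactivity")),
                    source="injection",
                )
                for _, r in injection_log.iterrows()
            ]
        else:
            periods = list(injection_log)
        return [
            p for p in periods
            if p.duration > min_duration
            and not _in_night(p.start, p.end, night_window)
        ]

    if not events:
        raise ValueError("ground truth unobtainable: no injection log and no events")
    if all(e.activity is None for e in events):
        raise ValueError(
            "ground truth unobtainable: events carry no annotations "
            "and no injection log was supplied"
        )
    keywords = tuple(k.lower() for k in context_keywords)
    periods: list[GroundTruthPeriod] = []
    for prev, nxt in zip(events, events[1:]):
        gap = nxt.timestamp - prev.timestamp
        if gap <= min_duration:
            continue
        annotations = [a for a in (prev.activity, nxt.activity) if a]
        if annotations and not any(
            kw in a.lower() for a in annotations for kw in keywords
        ):
            continue
        if _in_night(prev.timestamp, nxt.timestamp, night_window):
            continue
        periods.append(
            GroundTruthPeriod(prev.timestamp, nxt.timestamp,
                              label="inactivity", source="annotation")
        )
    return periods


def _slice_bounds(key) -> tuple[datetime, datetime]:
    date, hour = key
    start = datetime.combine(pd.Timestamp(date).date(), time(int(hour)))
    return start, start + timedelta(hours=1)


def score_detection(
    assessments: pd.DataFrame,
    truth: Sequence[GroundTruthPeriod],
    night_window: tuple[int, int] = (22, 7),
    return_slices: bool = False,
):
    """Confusion counts of hourly alerts against ground-truth periods.

    A truth period is a TP if at least one overlapping hourly slice has
    ``alert`` true, else an FN.  Every slice that overlaps no truth period
    and lies outside the night window is an FP if alerting, else a TN.
    With ``return_slices`` the evaluated normal-slice keys are also returned
    for inspection.
    """
    if "alert" not in assessments.columns:
        raise ValueError("assessments must have an 'alert' column")
    bounds = [_slice_bounds(k) for k in assessments.index]
    alerts = assessments["alert"].to_numpy(dtype=bool)

    tp = fn = 0
    overlapped = [False] * len(bounds)
    for period in truth:
        hit = False
        any_overlap = False
        for i, (s, e) in enumerate(bounds):
            if s < period.end and period.start < e:
                any_overlap = True
                overlapped[i] = True
                if alerts[i]:
                    hit = True
        if not any_overlap:
            raise ValueError(
                f"truth period {period.start} - {period.end} lies outside "
                "the assessment span"
            )
        tp += hit
        fn += not hit

    fp = tn = 0
    normal_keys = []
    night_start, night_end = night_window
    for i, ((s, _), key) in enumerate(zip(bounds, assessments.index)):
        if overlapped[i]:
            continue
        h = s.hour
        is_night = (h >= night_start or h < night_end) if night_start > night_end \
            else (night_start <= h < night_end)
        if is_night:
            continue
        normal_keys.append(key)
        if alerts[i]:
            fp += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
    return (counts, normal_keys) if return_slices else counts


def detection_metrics(counts: ConfusionCounts) -> DetectionMetrics:
    """Detection rate and false-positive rate from confusion counts."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no ground-truth periods evaluated (TP + FN = 0)")
    if counts.fp + counts.tn == 0:
        raise ValueError("no normal slices evaluated (FP + TN = 0)")
    return DetectionMetrics(
        detection_rate=counts.tp / (counts.tp + counts.fn),
        false_positive_rate=counts.fp / (counts.fp + counts.tn),
    )


def metrics_report(results: dict[str, ConfusionCounts]) -> pd.DataFrame:
    """Tabular report (one row per dataset) with truncated display rates."""
    rows = []
    for name, c in results.items():
        m = detection_metrics(c)
        rows.append((name, c.tp, c.fn, c.fp, c.tn,
                     m.detection_rate_display, m.false_positive_rate_display))
    return pd.DataFrame(
        rows,
        columns=["Dataset", "TP", "FN", "FP", "TN",
                 "Detection Rate", "False Positive Rate"],
    )
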