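"""End-to-end orchestration: events → counts → places → forecast → alerts.

These helpers wire the individual stages together the way the CLI and the
reproducibility experiments use them: split the hourly activity-vector table
into a training and a monitoring span by calendar day, learn the hour-of-day
baseline and the seasonal forecast on the training span, and score every
monitored hour with the fuzzy module.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .activity_encoding import (BMPMap, HourlyBaseline, encode_activity_vectors,
                                hourly_baseline)
from .anomaly_fuzzy import FuzzyConfig, assess_anomalies
from .evaluation import (ConfusionCounts, DetectionMetrics, GroundTruthPeriod,
                         detection_metrics, extract_inactivity_ground_truth,
                         score_detection)
from .forecasting import fit_seasonal_baseline, forecast_horizon, get_forecaster
from .preprocess import preprocess_events
from .synthetic import (SimConfig, default_sim_config, inject_gradual_decline,
                        sample_daytime_inactivity, simulate_event_stream)
from .trend import TrendResult, daily_activity_levels, regress_trend

__all__ = [
    "split_train_test",
    "bmp_map_from_sim",
    "detect_anomalies",
    "DetectionRun",
    "run_detection_experiment",
    "run_decline_experiment",
]


def split_train_test(vectors: pd.DataFrame,
                     train_days: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First ``train_days`` calendar days train; the remainder is monitored."""
    days = sorted(set(vectors.index.get_level_values("date")))
    if train_days < 1 or train_days >= len(days):
        raise ValueError(
            f"train_days={train_days} must leave at least one test day "
            f"out of {len(days)}"
        )
    train_set = set(days[:train_days])
    mask = [d in train_set for d in vectors.index.get_level_values("date")]
    mask = np.asarray(mask)
    return vectors[mask], vectors[~mask]


def bmp_map_from_sim(config: SimConfig) -> BMPMap:
    """Place map induced by a simulator config (one place per profile key)."""
    places = tuple(
        (place, tuple(config.place_sensors(place))) for place in config.places
    )
    return BMPMap(places=places)


def detect_anomalies(
    vectors: pd.DataFrame,
    train_days: int = 28,
    forecaster: str = "baseline",
    forecaster_mode: str = "hour",
    fuzzy: FuzzyConfig | None = None,
    threshold: float | None = None,
) -> tuple[pd.DataFrame, HourlyBaseline]:
    """Score the post-training span of an activity-vector table.

    Returns the per-hour assessment table (dist, oal, pa, alert) for the
    monitored span and the learned hourly baseline.
    """
    train, test = split_train_test(vectors, train_days)
    baseline = hourly_baseline(train)
    if forecaster == "baseline":
        model = fit_seasonal_baseline(train, mode=forecaster_mode)
    else:
        model = get_forecaster(forecaster).fit(train)
    predicted = forecast_horizon(model, test.index)
    assessments = assess_anomalies(test, predicted, baseline, fuzzy, threshold)
    return assessments, baseline


@dataclass
class DetectionRun:
    """Everything a detection experiment produced, for inspection."""

    assessments: pd.DataFrame
    truth: list[GroundTruthPeriod]
    counts: ConfusionCounts
    metrics: DetectionMetrics
    baseline: HourlyBaseline


def run_detection_experiment(
    seed: int,
    train_days: int = 28,
    test_days: int = 21,
    n_inactivity: int = 10,
    sim_config: SimConfig | None = None,
    fuzzy: FuzzyConfig | None = None,
    threshold: float | None = None,
    night_window: tuple[int, int] = (22, 7),
) -> DetectionRun:
    """Seeded end-to-end point-anomaly experiment on synthetic data.

    Simulates ``train_days`` clean days followed by ``test_days`` monitored
    days carrying ``n_inactivity`` injected daytime inactivity periods
    (1.5–3 h, one per affected day), runs the full pipeline with default
    configs, and scores detections against the injection log.
    """
    rng = np.random.default_rng(seed)
    cfg = sim_config or default_sim_config(days=train_days + test_days)
    specs = sample_daytime_inactivity(cfg, n_inactivity, seed=rng,
                                      first_day=train_days)
    cfg = replace(cfg, anomalies=tuple(specs))
    events, injection_log = simulate_event_stream(cfg, rng)
    counts_table = preprocess_events(events, sensor_ids=list(cfg.sensors))
    vectors = encode_activity_vectors(counts_table, bmp_map_from_sim(cfg))
    assessments, baseline = detect_anomalies(
        vectors, train_days=train_days, fuzzy=fuzzy, threshold=threshold
    )
    truth = extract_inactivity_ground_truth(injection_log=injection_log,
                                            night_window=night_window)
    counts = score_detection(assessments, truth, night_window=night_window)
    return DetectionRun(assessments, truth, counts,
                        detection_metrics(counts), baseline)


def run_decline_experiment(
    seed: int,
    days: int = 21,
    daily_rate: float = 0.01,
    window_days: int = 21,
    alpha: float = 0.05,
    sim_config: SimConfig | None = None,
) -> TrendResult:
    """Seeded gradual-decline experiment at the generative level.

    Simulates ``days`` days whose intensities fade by ``daily_rate`` per day
    (compound) from day 0, runs preprocessing and place encoding, and
    regresses the daily activity levels over the trailing window.
    With ``daily_rate=0`` this doubles as a null (no-decline) run.
    """
    cfg = sim_config or default_sim_config(days=days)
    if daily_rate > 0:
        cfg = inject_gradual_decline(cfg, start_day=0, daily_rate=daily_rate)
    events, _ = simulate_event_stream(cfg, np.random.default_rng(seed))
    counts_table = preprocess_events(events, sensor_ids=list(cfg.sensors))
    vectors = encode_activity_vectors(counts_table, bmp_map_from_sim(cfg))
    dal = daily_activity_levels(vectors)
    return regress_trend(dal, window_days=window_days, alpha=alpha)
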