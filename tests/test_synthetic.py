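"""Synthetic event-stream generator: determinism, statistics, closure."""

import io
from dataclasses import replace
from datetime import datetime, timedelta

import numpy as np
import pytest

from mobisense.activity_encoding import encode_activity_vectors
from mobisense.events_io import read_casas_events, write_events
from mobisense.pipeline import bmp_map_from_sim
from mobisense.preprocess import preprocess_events
from mobisense.synthetic import (AnomalySpec, default_sim_config,
                                 inject_gradual_decline,
                                 inject_point_anomalies,
                                 sample_daytime_inactivity,
                                 simulate_event_stream)


@pytest.fixture(scope="module")
def small_config():
    return default_sim_config(days=3)


def test_zero_intensity_gives_empty_stream(small_config):
    cfg = replace(small_config,
                  profile={p: (0.0,) * 24 for p in small_config.profile})
    events, truth = simulate_event_stream(cfg, 1)
    assert events == [] and truth == []


def test_seeded_determinism(small_config):
    a, _ = simulate_event_stream(small_config, 42)
    b, _ = simulate_event_stream(small_config, 42)
    assert a == b
    c, _ = simulate_event_stream(small_config, 43)
    assert a != c


def test_per_sensor_spacing_respects_min_gap(small_config):
    events, _ = simulate_event_stream(small_config, 5)
    by_sensor = {}
    for e in events:
        by_sensor.setdefault(e.sensor_id, []).append(e.timestamp)
    for times in by_sensor.values():
        gaps = [(b - a).total_seconds() for a, b in zip(times, times[1:])]
        assert all(g >= small_config.min_gap for g in gaps)


def test_poisson_mean_recovery():
    """Sample mean hourly count per place converges to the intensity."""
    cfg = default_sim_config(days=120)
    events, _ = simulate_event_stream(cfg, 11)
    table = preprocess_events(events, sensor_ids=list(cfg.sensors))
    vectors = encode_activity_vectors(table, bmp_map_from_sim(cfg))
    hours = vectors.index.get_level_values("hour")
    for place in ("kitchen", "living"):
        for h in (8, 14, 19):
            lam = cfg.profile[place][h]
            sample = vectors.loc[hours == h, place]
            se = np.sqrt(lam / len(sample))
            assert abs(sample.mean() - lam) < 3 * se + 1e-9, (place, h)


def test_closure_through_write_read_preprocess_encode(small_config):
    """The stream survives serialization, filtering and debouncing intact."""
    events, _ = simulate_event_stream(small_config, 9)
    buf = io.StringIO()
    write_events(events, buf, dialect="aruba")
    buf.seek(0)
    back = read_casas_events(buf, dialect="aruba")
    assert len(back) == len(events)
    table = preprocess_events(back.events, sensor_ids=list(small_config.sensors))
    assert table.to_numpy().sum() == len(events)
    vectors = encode_activity_vectors(table, bmp_map_from_sim(small_config))
    assert vectors.to_numpy().sum() == len(events)


class TestPointAnomalies:
    def _interval(self, day_hour, duration_h):
        start = datetime(2024, 3, 4) + timedelta(hours=day_hour)
        return AnomalySpec(start, start + timedelta(hours=duration_h))

    def test_inactivity_empties_the_window(self, small_config):
        spec = self._interval(14, 2.5)
        events, _ = simulate_event_stream(small_config, 3)
        out, log = inject_point_anomalies(events, [spec])
        assert not any(spec.start <= e.timestamp < spec.end for e in out)
        assert log[0].label == "inactivity" and log[0].source == "injection"

    def test_outing_adds_two_boundary_door_events(self, small_config):
        spec = self._interval(10, 2)
        events, _ = simulate_event_stream(small_config, 3)
        out, _ = inject_point_anomalies(events, [spec], kind="outing",
                                        door_sensor="D001")
        boundary = [e for e in out if e.timestamp in (spec.start, spec.end)]
        assert len(boundary) == 2
        assert all(e.sensor_id == "D001" and e.value == "OPEN" for e in boundary)
        interior = [e for e in out if spec.start < e.timestamp < spec.end]
        assert interior == []

    def test_overlapping_intervals_rejected(self, small_config):
        events, _ = simulate_event_stream(small_config, 3)
        with pytest.raises(ValueError, match="overlap"):
            inject_point_anomalies(
                events, [self._interval(10, 3), self._interval(12, 2)])

    def test_injection_log_round_trips_through_ground_truth(self, small_config):
        from mobisense.evaluation import extract_inactivity_ground_truth
        specs = [self._interval(9, 2), self._interval(38, 1.5)]
        events, _ = simulate_event_stream(small_config, 3)
        _, log = inject_point_anomalies(events, specs)
        truth = extract_inactivity_ground_truth(injection_log=log)
        assert [(p.start, p.end) for p in truth] == \
               [(s.start, s.end) for s in specs]


class TestGradualDecline:
    def test_zero_rate_is_identity(self, small_config):
        cfg = inject_gradual_decline(small_config, 0, 0.0)
        a, _ = simulate_event_stream(small_config, 4)
        b, _ = simulate_event_stream(cfg, 4)
        assert a == b

    def test_expected_intensity_scales_compoundly(self):
        """Day k of a declining run has mean activity ~ (1-rate)^k baseline."""
        rate, days = 0.2, 4         # aggressive rate so one seed suffices
        cfg = inject_gradual_decline(default_sim_config(days=days), 0, rate)
        events, _ = simulate_event_stream(cfg, 8)
        table = preprocess_events(events, sensor_ids=list(cfg.sensors))
        daily = table.groupby(level="date").sum().sum(axis=1).to_numpy(dtype=float)
        base = daily[0]
        for k in range(1, days):
            expected = base * (1 - rate) ** k
            assert abs(daily[k] - expected) < 4 * np.sqrt(expected)

    def test_rate_domain(self, small_config):
        with pytest.raises(ValueError):
            inject_gradual_decline(small_config, 0, 1.0)


def test_sampled_daytime_inactivity_is_valid(small_config):
    cfg = default_sim_config(days=30)
    specs = sample_daytime_inactivity(cfg, 10, seed=3, first_day=10)
    assert len(specs) == 10
    days = {s.start.date() for s in specs}
    assert len(days) == 10          # one per day, hence non-overlapping
    for s in specs:
        assert 8 <= s.start.hour
        assert s.end.hour <= 18
        assert timedelta(hours=1.5) <= s.end - s.start <= timedelta(hours=3)


def test_infeasible_intensity_rejected():
    with pytest.raises(ValueError, match="too high"):
        default_sim_config(days=2, profile={"kitchen": (100.0,) * 24},
                           sensors={"M001": "kitchen"})
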