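"""Fuzzy anomaly scoring: membership, inference, alerting."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mobisense.activity_encoding import HourlyBaseline
from mobisense.anomaly_fuzzy import (FuzzyConfig, TrapezoidSet, alert_flag,
                                     assess_anomalies, deviation_distance,
                                     fuzzify, infer_anomaly_probability,
                                     observed_activity_ratio)


@pytest.fixture(scope="module")
def config():
    return FuzzyConfig.default()


def numeric_centroid(trap: TrapezoidSet, height: float = 1.0) -> float:
    """Independent quadrature centroid of a (possibly clipped) trapezoid."""
    def mu(x):
        if x < trap.a or x > trap.d:
            return 0.0
        if trap.a < trap.b and x < trap.b:
            m = (x - trap.a) / (trap.b - trap.a)
        elif x <= trap.c:
            m = 1.0
        else:
            m = (trap.d - x) / (trap.d - trap.c) if trap.d > trap.c else 1.0
        return min(m, height)
    pts = sorted({trap.a, trap.b, trap.c, trap.d, 0.0, 1.0})
    area, _ = integrate.quad(mu, 0, 1, points=pts, limit=200)
    moment, _ = integrate.quad(lambda x: x * mu(x), 0, 1, points=pts, limit=200)
    return moment / area


class TestDeviationDistance:
    def test_identical_vectors(self):
        assert deviation_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_against_zero_vector(self):
        assert deviation_distance([3, 4, 0, 0, 0], [0, 0, 0, 0, 0]) == 5.0

    def test_symmetric(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert deviation_distance(a, b) == pytest.approx(deviation_distance(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviation_distance([1, 2], [1, 2, 3])


class TestOAL:
    def test_ratio(self):
        assert observed_activity_ratio(1.5, 3.0) == 0.5
        assert observed_activity_ratio(3.0, 3.0) == 1.0

    def test_quiet_hour_in_quiet_baseline_is_normal(self):
        assert observed_activity_ratio(0.0, 0.0) == 1.0

    def test_activity_in_silent_baseline_hits_cap(self):
        assert observed_activity_ratio(4.0, 0.0, cap=2.0) == 2.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            observed_activity_ratio(-1.0, 2.0)


class TestFuzzify:
    def test_plateau_gives_full_membership(self, config):
        mid = config.oal_sets["Medium"].plateau_center
        mu = fuzzify(mid, config.oal_sets)
        assert mu["Medium"] == 1.0 and mu["Low"] == 0.0 and mu["High"] == 0.0

    def test_symmetric_crossover_is_half_half(self, config):
        # OAL Low falls 0.3→0.6 while Medium rises 0.3→0.6: midpoint 0.45.
        mu = fuzzify(0.45, config.oal_sets)
        assert mu["Low"] == pytest.approx(0.5)
        assert mu["Medium"] == pytest.approx(0.5)

    def test_out_of_universe_saturates_to_boundary_set(self, config):
        mu = fuzzify(5.0, config.oal_sets)
        assert mu["High"] == 1.0
        mu = fuzzify(-1.0, config.oal_sets)
        assert mu["Low"] == 1.0

    def test_matches_pointwise_formula_oracle(self, config, rng):
        for sets in (config.oal_sets, config.dist_sets):
            for x in rng.uniform(0, 2, size=40):
                mu = fuzzify(x, sets)
                for label, t in sets.items():
                    if x < t.a or x > t.d:
                        expected = 0.0
                    elif x < t.b:
                        expected = (x - t.a) / (t.b - t.a)
                    elif x <= t.c:
                        expected = 1.0
                    else:
                        expected = (t.d - x) / (t.d - t.c)
                    assert mu[label] == pytest.approx(expected, abs=1e-12)

    def test_malformed_breakpoints_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TrapezoidSet(0.5, 0.3, 0.6, 0.7)


class TestInference:
    def test_single_rule_centroid_matches_quadrature_oracle(self, config):
        # OAL deep in High, Dist deep in Low: only (High, Low) -> Low fires.
        pa = infer_anomaly_probability(
            config.oal_sets["High"].plateau_center,
            config.dist_sets["Low"].plateau_center, config)
        assert pa == pytest.approx(numeric_centroid(config.pa_sets["Low"]),
                                   abs=1e-6)
        # OAL deep in Low, Dist deep in High: only (Low, High) -> High fires.
        pa = infer_anomaly_probability(
            config.oal_sets["Low"].plateau_center,
            config.dist_sets["High"].plateau_center, config)
        assert pa == pytest.approx(numeric_centroid(config.pa_sets["High"]),
                                   abs=1e-6)

    def test_winning_label_matches_rule_base_at_all_plateaus(self, config):
        centroids = {lab: numeric_centroid(t) for lab, t in config.pa_sets.items()}
        for (ol, dl), pl in config.rules.items():
            pa = infer_anomaly_probability(config.oal_sets[ol].plateau_center,
                                           config.dist_sets[dl].plateau_center,
                                           config)
            winner = min(centroids, key=lambda lab: abs(pa - centroids[lab]))
            assert winner == pl, f"rule ({ol}, {dl}) -> {pl} won {winner}"

    def test_monotone_and_bounded_on_coarse_grid(self, config):
        grid = np.linspace(0, 2, 21)
        pa = np.array([[infer_anomaly_probability(o, d, config) for d in grid]
                       for o in grid])
        assert ((pa >= 0) & (pa <= 1)).all()
        assert (np.diff(pa, axis=0) <= 1e-9).all()   # non-increasing in OAL
        assert (np.diff(pa, axis=1) >= -1e-9).all()  # non-decreasing in Dist

    def test_min_max_variant_stays_bounded(self, config):
        cfg = FuzzyConfig(config.oal_sets, config.dist_sets, config.pa_sets,
                          config.rules, inference="min_max")
        for o, d in [(0.1, 0.1), (1.0, 0.4), (1.9, 1.9), (0.45, 0.65)]:
            assert 0.0 <= infer_anomaly_probability(o, d, cfg) <= 1.0


class TestAlert:
    def test_strictly_above_threshold(self):
        assert alert_flag(0.71, 0.7) is True
        assert alert_flag(0.70, 0.7) is False
        assert alert_flag(0.71, 0.65) is True

    def test_lowering_threshold_can_only_add_alerts(self):
        pas = np.linspace(0, 1, 101)
        high = sum(alert_flag(p, 0.7) for p in pas)
        low = sum(alert_flag(p, 0.65) for p in pas)
        assert low >= high

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            alert_flag(0.5, 0.0)
        with pytest.raises(ValueError):
            alert_flag(0.5, 1.0)


class TestConfigValidation:
    def test_incomplete_rule_base_rejected(self, config):
        rules = dict(config.rules)
        rules.pop(("Low", "Low"))
        with pytest.raises(ValueError, match="incomplete"):
            FuzzyConfig(config.oal_sets, config.dist_sets, config.pa_sets, rules)

    def test_uncovered_universe_rejected(self, config):
        gappy = {"Low": TrapezoidSet(0, 0, 0.2, 0.3),
                 "High": TrapezoidSet(1.5, 1.6, 2, 2)}
        with pytest.raises(ValueError, match="not covered"):
            FuzzyConfig(gappy, config.dist_sets, config.pa_sets,
                        {(o, d): "Low" for o in gappy for d in config.dist_sets})

    def test_threshold_bounds_rejected(self, config):
        with pytest.raises(ValueError, match="threshold"):
            FuzzyConfig(config.oal_sets, config.dist_sets, config.pa_sets,
                        config.rules, alert_threshold=1.0)


def test_assess_anomalies_flags_inactive_hour(config):
    idx = pd.MultiIndex.from_tuples(
        [(date(2024, 4, 1), 9), (date(2024, 4, 1), 10)], names=["date", "hour"])
    observed = pd.DataFrame({"A": [12, 0], "B": [5, 0]}, index=idx)
    predicted = pd.DataFrame({"A": [12.0, 12.0], "B": [5.0, 5.0]}, index=idx)
    hal = np.zeros(24)
    hal[9] = hal[10] = 13.0
    baseline = HourlyBaseline(hal=hal, place_means=pd.DataFrame())
    out = assess_anomalies(observed, predicted, baseline, config)
    # hour 9 matches the forecast: normal; hour 10 is totally inactive
    assert not out.loc[(date(2024, 4, 1), 9), "alert"]
    assert out.loc[(date(2024, 4, 1), 10), "alert"]
    assert out.loc[(date(2024, 4, 1), 10), "pa"] > 0.7
    assert (out["pa"].between(0, 1)).all()
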