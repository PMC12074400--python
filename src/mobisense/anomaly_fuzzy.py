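"""Mamdani fuzzy scoring of hourly mobility anomalies.

Each monitored hour yields two crisp inputs: the observed/historical activity
ratio OAL = AL / HAL (below 1 means quieter than usual) and the Euclidean
deviation Dist between the observed and forecast per-place count vectors.
Both are fuzzified over Low/Medium/High trapezoid sets, a 9-rule base maps
them to a Low/Medium/High anomaly consequent, and centroid defuzzification
over [0, 1] produces the anomaly probability PA.  An alert fires when PA
strictly exceeds a tunable threshold (default 0.7).

Two inference schemes are available.  The default, ``product_sum``,
activates each rule with the product of its antecedent memberships and adds
same-consequent activations (capped at 1) before clipping and centroid.
Because adjacent input sets form a Ruspini partition (memberships sum to 1),
rule activations then sum to exactly 1 and each consequent's height varies
bilinearly between the values the rule table prescribes at the plateaus —
which makes PA monotone in both inputs, matching the rule table's intent
(quieter-than-usual and larger deviation can never lower the anomaly score).
Classic Mamdani ``min_max`` (min activation, max aggregation) is provided
for comparison but exhibits small non-monotone ripples at set crossovers,
where min-capped activations of same-consequent rules dip or bulge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .activity_encoding import HourlyBaseline, activity_level

__all__ = [
    "TrapezoidSet",
    "FuzzyConfig",
    "deviation_distance",
    "observed_activity_ratio",
    "fuzzify",
    "infer_anomaly_probability",
    "alert_flag",
    "assess_anomalies",
]

_DEFUZZ_POINTS = 4001  # grid for centroid integration over the PA universe


@dataclass(frozen=True)
class TrapezoidSet:
    """Trapezoid membership function with breakpoints a <= b <= c <= d.

    Membership ramps 0→1 on [a, b], is 1 on [b, c] and ramps 1→0 on [c, d].
    a == b (or c == d) gives a vertical shoulder, used at universe edges.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"breakpoints must be ordered: {self}")

    def membership(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x >= self.a) & (x < self.b)
            out[rising] = (x[rising] - self.a) / (self.b - self.a)
        plateau = (x >= self.b) & (x <= self.c)
        out[plateau] = 1.0
        if self.d > self.c:
            falling = (x > self.c) & (x <= self.d)
            out[falling] = (self.d - x[falling]) / (self.d - self.c)
        return out if out.ndim else float(out)

    @property
    def plateau_center(self) -> float:
        return 0.5 * (self.b + self.c)

    def centroid(self) -> float:
        """Exact centroid of the full-height trapezoid (closed form)."""
        a, b, c, d = self.a, self.b, self.c, self.d
        area = 0.5 * (b - a) + (c - b) + 0.5 * (d - c)
        if area == 0:
            return 0.5 * (a + d)
        moment = ((b - a) * (a + 2 * b) / 6.0
                  + (c * c - b * b) / 2.0
                  + (d - c) * (2 * c + d) / 6.0)
        return moment / area


def _parse_sets(spec: Mapping) -> dict[str, TrapezoidSet]:
    return {label: TrapezoidSet(*map(float, bps)) for label, bps in spec.items()}


@dataclass
class FuzzyConfig:
    """Validated fuzzy-inference configuration.

    ``rules`` maps (OAL label, Dist label) → PA label and must cover all
    label combinations.  Input universes must be fully covered: every value
    has positive total membership.
    """

    oal_sets: dict[str, TrapezoidSet]
    dist_sets: dict[str, TrapezoidSet]
    pa_sets: dict[str, TrapezoidSet]
    rules: dict[tuple[str, str], str]
    oal_universe: tuple[float, float] = (0.0, 2.0)
    dist_universe: tuple[float, float] = (0.0, 2.0)
    pa_universe: tuple[float, float] = (0.0, 1.0)
    alert_threshold: float = 0.7
    dist_normalization: str = "hal_plus_one"
    inference: str = "product_sum"
    epsilon: float = 1e-6
    oal_cap: float = 2.0
    _pa_grid: np.ndarray = field(init=False, repr=False)
    _pa_memberships: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self):
        self.validate()
        lo, hi = self.pa_universe
        self._pa_grid = np.linspace(lo, hi, _DEFUZZ_POINTS)
        self._pa_memberships = {
            lab: s.membership(self._pa_grid) for lab, s in self.pa_sets.items()
        }

    def validate(self) -> None:
        if not (0.0 < self.alert_threshold < 1.0):
            raise ValueError("alert threshold must lie strictly in (0, 1)")
        if self.dist_normalization not in ("hal_plus_one", "none"):
            raise ValueError(f"unknown dist normalization {self.dist_normalization!r}")
        if self.inference not in ("product_sum", "min_max"):
            raise ValueError(f"unknown inference scheme {self.inference!r}")
        for oal_lab in self.oal_sets:
            for dist_lab in self.dist_sets:
                if (oal_lab, dist_lab) not in self.rules:
                    raise ValueError(f"rule base incomplete: missing ({oal_lab}, {dist_lab})")
        for (ol, dl), pl in self.rules.items():
            if ol not in self.oal_sets or dl not in self.dist_sets or pl not in self.pa_sets:
                raise ValueError(f"rule ({ol}, {dl}) -> {pl} references unknown label")
        for name, sets, universe in (
            ("oal", self.oal_sets, self.oal_universe),
            ("dist", self.dist_sets, self.dist_universe),
            ("pa", self.pa_sets, self.pa_universe),
        ):
            grid = np.linspace(universe[0], universe[1], 501)
            total = np.sum([s.membership(grid) for s in sets.values()], axis=0)
            if (total <= 0).any():
                gap = grid[total <= 0][0]
                raise ValueError(f"{name} universe not covered near {gap:.3f}")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "FuzzyConfig":
        rules = {}
        for entry in cfg["rules"]:
            ol, dl, pl = entry
            rules[(ol, dl)] = pl
        return cls(
            oal_sets=_parse_sets(cfg["oal"]["sets"]),
            dist_sets=_parse_sets(cfg["dist"]["sets"]),
            pa_sets=_parse_sets(cfg["pa"]["sets"]),
            rules=rules,
            oal_universe=tuple(cfg["oal"].get("universe", (0.0, 2.0))),
            dist_universe=tuple(cfg["dist"].get("universe", (0.0, 2.0))),
            pa_universe=tuple(cfg["pa"].get("universe", (0.0, 1.0))),
            alert_threshold=float(cfg.get("alert_threshold", 0.7)),
            dist_normalization=cfg.get("dist_normalization", "hal_plus_one"),
            inference=cfg.get("inference", "product_sum"),
            epsilon=float(cfg.get("epsilon", 1e-6)),
            oal_cap=float(cfg.get("oal_cap", 2.0)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "FuzzyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FuzzyConfig":
        path = resources.files("mobisense.configs") / "default_fuzzy.yaml"
        with resources.as_file(path) as p:
            return cls.from_yaml(str(p))


def deviation_distance(observed, predicted) -> float:
    """Euclidean distance between observed and forecast place vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"vector length mismatch: {obs.shape} vs {pred.shape}")
    return float(np.linalg.norm(obs - pred))


def observed_activity_ratio(al: float, hal: float,
                            epsilon: float = 1e-6, cap: float = 2.0) -> float:
    """OAL = AL / HAL with a defined value for quiet baseline hours.

    When HAL is effectively zero the ratio is undefined; a quiet hour in a
    quiet baseline (AL also ~0) is normal, so OAL = 1.  Activity in an hour
    that is historically silent is unusual and maps to ``cap``.
    """
    if al < 0 or hal < 0:
        raise ValueError("activity levels cannot be negative")
    if hal > epsilon:
        return float(al / hal)
    return 1.0 if al <= epsilon else float(cap)


def fuzzify(value: float, sets: Mapping[str, TrapezoidSet]) -> dict[str, float]:
    """Membership degree of ``value`` in each labelled set.

    Values outside the sets' overall support are clamped to the nearest
    boundary, so edge shoulders saturate instead of dropping to zero.
    """
    lo = min(s.a for s in sets.values())
    hi = max(s.d for s in sets.values())
    v = min(max(float(value), lo), hi)
    return {label: float(s.membership(v)) for label, s in sets.items()}


def infer_anomaly_probability(oal: float, dist: float, config: FuzzyConfig) -> float:
    """Fuzzy inference: rule activation, clipped consequents, centroid.

    ``dist`` is expected on the same scale as the configured Dist sets (i.e.
    already normalized if the config prescribes normalization).  The scheme
    (activation t-norm and aggregation) follows ``config.inference``.
    """
    mu_oal = fuzzify(oal, config.oal_sets)
    mu_dist = fuzzify(dist, config.dist_sets)
    additive = config.inference == "product_sum"
    heights = {lab: 0.0 for lab in config.pa_sets}
    for (ol, dl), pl in config.rules.items():
        if additive:
            act = mu_oal[ol] * mu_dist[dl]
            heights[pl] = min(1.0, heights[pl] + act)
        else:
            act = min(mu_oal[ol], mu_dist[dl])
            heights[pl] = max(heights[pl], act)

    agg = np.zeros_like(config._pa_grid)
    for lab, h in heights.items():
        if h > 0:
            clipped = np.minimum(h, config._pa_memberships[lab])
            agg = agg + clipped if additive else np.maximum(agg, clipped)
    if additive:
        np.minimum(agg, 1.0, out=agg)

    area = np.trapezoid(agg, config._pa_grid)
    if area <= 0:
        warnings.warn("zero aggregated area; returning PA universe midpoint",
                      stacklevel=2)
        return 0.5 * (config.pa_universe[0] + config.pa_universe[1])
    moment = np.trapezoid(agg * config._pa_grid, config._pa_grid)
    return float(moment / area)


def alert_flag(pa: float, threshold: float = 0.7) -> bool:
    """True iff PA strictly exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("alert threshold must lie strictly in (0, 1)")
    return bool(pa > threshold)


def assess_anomalies(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    baseline: HourlyBaseline,
    config: FuzzyConfig | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score every hourly slice of ``observed`` against its forecast.

    Parameters
    ----------
    observed, predicted
        (date, hour)-indexed per-place tables with identical index and
        columns (forecasts from :mod:`mobisense.forecasting`).
    baseline
        Training baseline supplying HAL(h) for the OAL ratio and for the
        Dist normalization.
    config
        Fuzzy configuration; the packaged default when omitted.
    threshold
        Overrides the config's alert threshold if given.

    Returns
    -------
    DataFrame indexed like ``observed`` with columns
    ``dist`` (raw, unnormalized), ``oal``, ``pa``, ``alert``.
    """
    if config is None:
        config = FuzzyConfig.default()
    thr = config.alert_threshold if threshold is None else threshold
    if not (0.0 < thr < 1.0):
        raise ValueError("alert threshold must lie strictly in (0, 1)")
    if not observed.index.equals(predicted.index):
        raise ValueError("observed and predicted slices are misaligned")
    if list(observed.columns) != list(predicted.columns):
        raise ValueError("observed and predicted place columns differ")

    al = activity_level(observed)
    rows = []
    for (key, obs_row), (_, pred_row) in zip(observed.iterrows(), predicted.iterrows()):
        hour = key[1] if isinstance(key, tuple) else key.hour
        hal = baseline.hal_at(hour)
        dist = deviation_distance(obs_row.to_numpy(), pred_row.to_numpy())
        oal = observed_activity_ratio(float(al.loc[key]), hal,
                                      config.epsilon, config.oal_cap)
        dist_in = dist / (hal + 1.0) if config.dist_normalization == "hal_plus_one" else dist
        pa = infer_anomaly_probability(oal, dist_in, config)
        rows.append((dist, oal, pa, alert_flag(pa, thr)))
    out = pd.DataFrame(rows, index=observed.index,
                       columns=["dist", "oal", "pa", "alert"])
    out["alert"] = out["alert"].astype(bool)
    return out
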