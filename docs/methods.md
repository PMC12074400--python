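# Methods

This note documents the models, parameter choices, and numerical decisions
behind mobisense, and what its synthetic experiments do and do not show.

## Problem setting and assumptions

A single resident lives in a home instrumented with binary sensors: PIR
motion detectors that fire `ON` when movement starts, and door contacts that
fire `OPEN`. The method rests on two assumptions. First, daily indoor
activity is substantially regular — regular enough that a seasonal model of
per-place event counts is a usable norm. Second, mobility loss expresses
itself in that count stream: acutely, as hours with far less activity than
the norm (a fall, a collapse), and chronically, as a slow downward drift of
total daily activity. Both assumptions fail for multi-resident homes, which
are out of scope.

## Pipeline stages

### Preprocessing

Only motion-`ON` and door-`OPEN` events are retained. `OFF`/`CLOSE` mark the
end of a sensor's retrigger or contact cycle, not a movement, and
temperature/light channels are unrelated to mobility. Filtering precedes
debouncing so a discarded `OFF` cannot suppress a following `ON`.

Debouncing removes events of the *same* sensor closer than 60 s to the last
retained event of that sensor ("retained-anchor" semantics): a long rapid
burst collapses to events spaced at least one threshold apart, and the
operation is idempotent. The alternative reading — compare to the previous
*raw* event, so a dense burst collapses to its first event only — is
available as `mode="raw"`. Different sensors never suppress each other.
Hourly aggregation uses the event's local clock hour, left-closed
right-open, with explicit zero rows for quiet hours; timestamps are naive
local time throughout (no time-zone handling), which matches how such logs
are recorded.

### Place encoding

A `BMPMap` assigns each sensor to exactly one behaviorally meaningful place
(K = 5 in the shipped configs, but every formula is K-generic). Disjointness
is enforced by default because it makes place encoding conservative: summed
place counts equal total retained events. The shipped HH120 map contains a
sensor listed under two places in its source; the loader's
`on_duplicate: first` policy keeps it in its first-listed place and warns,
preserving conservation.

`AL` is the L2 norm of the hourly place-count vector: it grows with overall
volume of movement but, unlike a plain sum, weights concentrated activity
slightly higher than the same count scattered thinly. `HAL(h)` is the *mean
of the norms* over training slices at hour h — not the norm of the mean
vector. The two differ (norm of mean ≤ mean of norms); the mean-of-norms
reading keeps `OAL = AL/HAL` centred at ≈ 1 for typical hours.

### Forecasting

The built-in forecaster is a seasonal group-by mean: each place's predicted
count at hour h is its training mean at hour h (`hour` mode, default) or at
(weekday, hour) (`hour_x_weekday`, needs ≥ 7 training days). It is
deterministic, needs no tuning, and captures exactly the daily/weekly
seasonality the anomaly detector relies on. Sophisticated univariate models
(Prophet-style trend/seasonality decompositions, SARIMA, …) can be attached
through the `Forecaster` protocol — fit on the per-place history, predict
per slice key, each component univariately — and compared with
`evaluate_rmse`. RMSE is offered on two targets because both are defensible
and they answer different questions: `norm` compares the scalar AL series
with the norm of the forecast vector (what a monitoring plot shows);
`per_component` pools all K place residuals (what the forecaster actually
fits). Components are clipped at zero since counts cannot be negative.

### Fuzzy anomaly scoring

Inputs:

* `OAL = AL/HAL` on a [0, 2] universe: Low (0, 0, 0.3, 0.6),
  Medium (0.3, 0.6, 0.9, 1.2), High (0.9, 1.2, 2, 2). OAL = 1 ("as active
  as usual") straddles Medium/High; OAL below ~0.3 is firmly Low.
* `Dist`, normalized to `dist_rel = Dist/(HAL+1)` before fuzzification, on
  a [0, 2] universe: Low (0, 0, 0.3, 0.5), Medium (0.3, 0.5, 0.55, 0.75),
  High (0.55, 0.75, 2, 2).

The Dist normalization and breakpoints were derived from the statistic's
scale rather than picked symmetrically. Under Poisson counts with per-place
means m and total intensity S, ordinary stochastic jitter gives
`dist_rel ≈ √S/(HAL+1) ≈ 0.3–0.5`, while total inactivity in a normally
active hour gives `dist_rel = ‖m‖/(HAL+1) ≈ 0.75–0.95` — and can *never*
reach values much above 1, because `‖m‖ < HAL + 1` always. The High set
must therefore be fully active by ≈ 0.75, or the rule that drives
inactivity alerts (Low OAL ∧ High Dist → High PA) would be unreachable for
the very anomaly the system exists to catch. Values beyond the universe
saturate into the boundary sets. The per-home alternative of an absolute
Dist scale is available via `dist_normalization: none` plus custom
breakpoints.

Output PA sets over [0, 1]: Low (0, 0, 0.25, 0.5), Medium
(0.25, 0.5, 0.5, 0.75), High (0.5, 0.75, 1, 1); the full-height centroids
are 0.194 / 0.5 / 0.806, so a fully active High rule clears the default
alert threshold 0.7 while Medium does not. Alerts are strict
(`PA > threshold`).

The rule base (9 rules) encodes: quiet *and* off-pattern is anomalous;
quiet alone is suspicious (Medium); normal or high activity is benign
regardless of Dist — deviations at normal activity mean re-arranged, not
absent, mobility.

**Inference scheme.** The default is product-t-norm activation with
additive (capped) aggregation of same-consequent rules, then clipping and
centroid defuzzification on a 4001-point grid. The reason is monotonicity:
adjacent input sets form Ruspini partitions (memberships sum to 1), so with
product/sum the nine activations sum to exactly 1 and each consequent's
height interpolates bilinearly between the plateau values the rule table
prescribes; a 201×201 grid sweep shows PA non-increasing in OAL and
non-decreasing in Dist to machine precision. Classic min–max Mamdani
(`inference: min_max`) is retained for comparison, but it provably ripples
at set crossovers: two same-consequent rules each min-capped at 0.5 produce
an aggregated set whose clipped centroid differs from the full-height one,
so PA dips or bulges by up to ~0.03 against the rule table's intended
ordering. Degenerate zero-area aggregates (impossible with validated
configs, whose universes must be fully covered) return the PA midpoint with
a warning.

`OAL` edge cases: when `HAL ≤ ε` (default 10⁻⁶) the ratio is undefined; a
quiet hour in a quiet baseline is normal (OAL = 1), activity in a
historically silent hour maps to the cap (default 2.0, firmly High — which
by the rule base is benign: unusual *extra* activity is not a mobility
loss).

### Trend analysis

`DAL(d)` is the mean of the day's 24 hourly ALs (explicit zero hours
included). The trend statistic is OLS of the trailing 21 daily values on
the day index: slope (AL/day), R², and the two-sided p-value of the slope.
The decline flag requires *both* slope < 0 and p < α (default 0.05) — the
minimal decision rule consistent with reporting a statistically significant
downward trend; the one-sided nature of the question halves the effective
type-I rate (≈ α/2 on stationary series, verified at 500 runs). A
zero-variance window is defined as slope 0, R² 0, p 1, no flag. Simulated
decline defaults to compound (`(1−r)^k`, the conventional reading of a
daily percentage reduction); a linear variant is provided. 21 days is long
enough to average out weekday structure yet short enough to matter
clinically; it slides day-by-day in monitoring mode.

### Evaluation

Mixed counting units are deliberate: TP/FN are counted over ground-truth
*periods* (a period is detected if ≥ 1 overlapping hourly slice alerts —
the operationally meaningful question), while FP/TN are counted over normal
hourly *slices* outside the night window (22:00–07:00, configurable), the
natural unit of the detector's output. Consequently TP+FN equals the number
of periods while FP+TN equals the number of evaluated normal slices, and
rates from the two pools are not symmetric. Display rates are truncated
(not rounded) to two decimals — 49/60 = 0.8166 shows as 0.81 — with full
precision always returned alongside. The evaluated-slice set can be
returned for inspection (`return_slices=True`).

## The synthetic generator

The generator is the package's study-condition definition, not a
convenience fixture. It emulates: per-place hourly intensity profiles with
a realistic single-resident shape (quiet 23:00–06:00; kitchen peaks at
meal times; living-room presence through the day and evening; constant low
bathroom use; sparse door traffic), optional weekday modulation, Poisson
hourly counts apportioned uniformly across a place's sensors, and event
times spaced ≥ 70 s per sensor so the stream survives the 60 s debounce
unchanged (closure: simulate → write → read → preprocess → encode is
count-lossless). Intensities total ≈ 534 retained events/day (busy-hour
AL ≈ 15–25), chosen so that day-to-day relative DAL variability under pure
Poisson noise is ≈ 5 % of baseline — the noise scenario the decline-power
analysis is defined for — and broadly comparable to real testbed
magnitudes. Injected inactivity removes all events in an interval; outings
additionally add door-`OPEN` events at both boundaries; gradual decline
scales intensities by `(1−r)^(d−d₀)`. A per-sensor dropout probability
(default 0) can thin the stream to probe robustness.

What it does **not** emulate: annotation noise, sensor faults beyond
dropout, behavioural drift, visitors/multi-resident interleaving,
relaxation periods (legitimate quiet daytime hours), and over-dispersed
counts. The last two matter most for external validity: real homes have
benign quiet spells that this generator lacks, so the near-zero synthetic
false-positive rate is an upper bound on real-data specificity, not an
estimate of it. Detection rates on the generator show the pipeline's
mechanics are sound, not what it would score on real recordings.

## Experiment sizes and numerical choices

The packaged experiments use 28 training days + 21 monitored days with 10
injected daytime inactivity periods (1.5–3 h, one per affected day, drawn
uniformly over 08:00–18:00) for point-anomaly detection, averaged over 20
seeds; 100 seeded 21-day runs for decline power; 500 stationary daily
series for type-I control. Defuzzification uses a 4001-point trapezoid-rule
grid (breakpoints of the default output sets lie exactly on grid nodes, so
single-rule centroids agree with quadrature to < 10⁻⁶). Timestamp parsing
accepts `YYYY-MM-DD HH:MM:SS(.ffffff)` only; other layouts are skipped and
counted rather than guessed, and a stream with > 10 % unparseable lines
fails loudly as a wrong-dialect signal.

## Known limitations

* One-hour resolution implies up to one hour of detection latency, and
  sub-hour anomalies dilute into their slice.
* The decline model is linear-in-window; genuinely nonlinear decline
  (plateaus, steps) is only caught insofar as a 21-day linear fit picks it
  up.
* Distinguishing benign relaxation from true inactivity is unsolved here;
  on real data the false-positive rate is governed by exactly those hours.
* The fuzzy breakpoints are defaults calibrated to the Dist/OAL scales
  above; a home with a very different activity magnitude profile warrants
  re-examining the Dist sets (they are fully config-exposed).
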