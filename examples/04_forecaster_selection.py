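"""Score forecasters by held-out RMSE, the model-selection workflow.

Simulates 42 days, trains each registered forecaster on the first 28, and
reports RMSE on the remaining 14 days — both on the activity-level (L2) norm
series and pooled per-place components.  External forecasters plug into the
same registry via mobisense.register_forecaster.
"""

from mobisense import (default_sim_config, simulate_event_stream,
                       preprocess_events, encode_activity_vectors,
                       evaluate_rmse, forecast_horizon, get_forecaster)
from mobisense.forecasting import FORECASTERS, SeasonalBaselineForecaster
from mobisense.pipeline import bmp_map_from_sim, split_train_test

cfg = default_sim_config(days=42)
events, _ = simulate_event_stream(cfg, seed=12)
table = preprocess_events(events, sensor_ids=list(cfg.sensors))
vectors = encode_activity_vectors(table, bmp_map_from_sim(cfg))
train, test = split_train_test(vectors, train_days=28)

candidates = {name: get_forecaster(name) for name in FORECASTERS}
candidates["baseline_weekly"] = SeasonalBaselineForecaster(mode="hour_x_weekday")

print(f"{'forecaster':>18} {'RMSE(norm)':>11} {'RMSE(components)':>17}")
for name, model in candidates.items():
    model.fit(train)
    pred = forecast_horizon(model, test.index)
    print(f"{name:>18} {evaluate_rmse(pred, test, 'norm'):>11.3f} "
          f"{evaluate_rmse(pred, test, 'per_component'):>17.3f}")

print("\nlower RMSE means the forecaster tracks the routine more closely; "
      "the norm target scores the scalar activity-level series a dashboard "
      "would plot, the component target scores each place separately.")
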