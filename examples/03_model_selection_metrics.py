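"""Score two mechanistic forecasters with the model-selection metrics.

Runs both the ultradian and the meal model over the same patient and prints
the MSE / linear-correlation / KL-divergence triple for each.  The metrics
deliberately measure different things (pointwise error, trend agreement,
distributional closeness) and need not agree on a "best" model.
"""

from glucoda.evaluate import evaluate_forecaster
from glucoda.synth import CohortConfig, simulate_patient
from glucoda.ukf import run_filter

patient = simulate_patient(CohortConfig(model_id="ultradian", regime="typical",
                                        n_days=7, seed=3))
meal_times = patient.timeline.meals["time_min"].to_numpy()

for model_id in ("ultradian", "meal"):
    run = run_filter(patient.timeline, model_id, mode="dual")
    rep = evaluate_forecaster(model_id, run.forecasts, run.measured,
                              times=run.times, meal_times=meal_times)
    print(f"{model_id:10s} MSE {rep.mse:7.1f}  "
          f"LC r={rep.lc[0]:+.2f} (p={rep.lc[1]:.2g})  "
          f"LC(2h) r={rep.lc_2h[0]:+.2f}  KL {rep.kl:.3f} nats")
print("\nLower MSE/KL and higher correlation are better; the generating "
      "model (ultradian) should win on most, not necessarily all, metrics.")
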