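"""Sequentially average two model forecasters.

At each measurement the combination weight w1 is refit on all *past*
forecast/measurement pairs (grid search over [0, 1]), then applied to the
next forecast -- strictly causal online averaging.  Printed: each model's
MSE, the averaged MSE, and the weight trajectory endpoints.
"""

from glucoda.average import sequential_average
from glucoda.synth import CohortConfig, simulate_patient
from glucoda.ukf import run_filter

patient = simulate_patient(CohortConfig(model_id="ultradian", regime="typical",
                                        n_days=7, seed=4))
run_u = run_filter(patient.timeline, "ultradian", mode="dual")
run_m = run_filter(patient.timeline, "meal", mode="dual")

combo = sequential_average(run_u, run_m, metric="mse", warmup_n=10)

print(f"ultradian dual-UKF MSE: {run_u.mse:7.1f} (mg/dl)^2")
print(f"meal      dual-UKF MSE: {run_m.mse:7.1f}")
print(f"mse-based sequential average: {combo.mse:7.1f}")
print(f"w1 (ultradian weight): starts 0.50, ends {combo.weights[-1]:.2f}")
# The averaged forecast should sit at or below the better single model once
# enough history has accumulated to estimate the weights.
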