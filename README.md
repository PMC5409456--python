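# glucoda

Personalized blood-glucose forecasting for type 2 diabetes from the data
patients actually collect: a handful of finger-stick glucose readings a day
and meal carbohydrate records. The engine is *data assimilation* — a
mechanistic glucose–insulin ODE model is run continuously and a **modified
dual unscented Kalman filter** corrects both the model state and a small set
of physiologic parameters at every measurement, so the model personalizes
and adapts online without a training set.

The package provides:

* two mechanistic models — the 6-state **ultradian** glucose–insulin
  oscillator and the 12-state **meal-simulation** model with explicit
  gastro-intestinal transit (`glucoda.models`);
* the modified dual UKF with sigma-point positivity constraints,
  covariance-proportional augmentation, a forgetting-factor parameter
  filter, and three ablation modes (`glucoda.ukf`);
* model-selection metrics — MSE, (lagged) linear correlation, KDE-based KL
  divergence (`glucoda.evaluate`) — and strictly causal online model
  averaging (`glucoda.average`);
* clinical derivations — daily HbA1c estimates via the ADAG relation and
  dynamic post-meal forecast ranges with capture-fraction scoring
  (`glucoda.forecast`);
* a fixed-hyperparameter Gaussian-process baseline (`glucoda.gpmr`);
* a virtual-patient generator emulating dense / typical / sparse
  self-monitoring regimes with known ground truth (`glucoda.synth`);
* readers/writers for the delimited formats, a flat config format, and a
  thin `glucoda` CLI (`glucoda.timeline`, `glucoda.cli`).

## The model in one paragraph

Write the physiology as x' = f(x, w) with state x (insulin/glucose
compartments), parameters w, and glucose measurements yₖ = h(xₖ) + noise at
irregular times tₖ. Between measurements the filter integrates the belief
mean forward — the central-sigma-point trace χ₀(t), a continuous off-data
glucose forecast. At each measurement the unscented transform propagates
2n+1 sigma points through the flow, and the state is corrected by
x̂ₖ = x̂ₖ|ₖ₋₁ + Kₖ(yₖ − ŷₖ|ₖ₋₁). A second, 3-dimensional UKF does the same
for a parameter subset (ultradian: insulin exchange rate E, plasma insulin
volume Vp, insulin degradation time tp; meal model: insulin volume VI and
glucose kinetics rates k1, k2), with its prior covariance inflated by a
forgetting factor 1/λ each step so the parameters can track behavior
change. Negative sigma-point elements are replaced by the smallest positive
value of that coordinate across the set (physiology is non-negative), and
forecast products — post-meal point forecasts, HbA1c, forecast ranges — are
read off χ₀.

## Worked example

```python
from glucoda.synth import CohortConfig, simulate_patient
from glucoda.studies import PARAM_OFFSET
from glucoda.ukf import run_filter

patient = simulate_patient(CohortConfig(model_id="ultradian",
                                        regime="typical", n_days=10, seed=2))
truth = {k: patient.true_params[k] for k in ("E", "Vp", "tp")}
init = {k: truth[k] * f for k, f in PARAM_OFFSET.items()}  # start 30% off
run = run_filter(patient.timeline, "ultradian", mode="dual", init_params=init)
print(run.mse, run.param_means[-1])
```

Running `python examples/02_dual_ukf_forecast.py` (which does the above and
prints a summary) gives:

```
measurements assimilated: 60
one-step-ahead forecast MSE: 199.8 (mg/dl)^2 (rmse 14.1 mg/dl; meter noise sd was 10)

estimated parameters (init -> final vs truth):
  E  :   0.260 ->   0.204 (truth   0.200)
  Vp :   3.900 ->   2.963 (truth   3.000)
  tp :   4.200 ->   5.628 (truth   6.000)

mean relative parameter error: 0.30 at init -> 0.03 after 60 measurements
```

The mean relative error of the three personalized parameters drops from 30%
at initialization to 3% after ten days of routine self-monitoring data — the
filter has personalized the model online; the overall forecast RMSE
(14.1 mg/dl, dominated by the mis-parameterized early days) approaches the
10 mg/dl meter noise floor as it converges. The other
scripts in `examples/` walk through simulation, model-selection metrics,
sequential model averaging, the GP baseline, and the clinical report
(HbA1c + forecast ranges), one capability each.

A shell pipeline does the same end to end:

```bash
glucoda --seed 7 simulate --regime typical --days 28 --out-dir sim/
glucoda --seed 7 run --measurements sim/measurements.csv --meals sim/meals.csv \
        --model ultradian --mode dual --out-dir sim/
glucoda report --trace sim/trace_ultradian_dual.csv \
        --measurements sim/measurements.csv --meals sim/meals.csv --out-dir sim/
```

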