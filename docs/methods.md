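# Methods

## Problem and approach

People with type 2 diabetes manage blood glucose largely through nutrition,
guided by sparse, irregular self-measurements (a handful of finger-stick
readings a day at best). This package forecasts post-meal glucose for such a
patient by data assimilation: a mechanistic glucose–insulin ODE model is run
continuously, and each new measurement is used to correct both the model
state and a small set of physiologic parameters, personalizing the model
online without a training set. The forecaster is a *modified dual unscented
Kalman filter* (UKF); around it sit model-selection metrics, online model
averaging, clinically framed derivations (HbA1c, post-meal forecast ranges),
a Gaussian-process baseline, and a virtual-patient generator that provides
ground truth for every claim the test suite makes.

## Mechanistic models

**Ultradian model** (6 states, `glucoda.models.UltradianModel`): plasma
insulin, interstitial insulin, glucose mass, and a three-stage hepatic delay
chain, after Sturis and colleagues. Insulin secretion saturates in glucose;
insulin exchanges between plasma and interstitium at rate `E`; clearance is
linear with time constants `tp` (plasma) and `ti` (interstitial); glucose is
produced by the liver through the delay chain and consumed by
insulin-independent and insulin-dependent utilization. The model oscillates
with a period on the order of 1–2 hours when driven, which is the feature
that makes its post-meal forecast *ranges* informative. Nutrition enters as
an exogenous glucose-appearance rate: each meal contributes a single
exponential absorption kernel (decay 1/120 min⁻¹, 1 g carbohydrate → 1000 mg
glucose), additive across meals. The kernel form is this package's choice —
a one-parameter causal kernel whose integral equals the meal's carbohydrate
mass; the canonical model only requires *some* exogenous forcing.

**Meal model** (12 states, `glucoda.models.MealModel`): the meal-simulation
model of Dalla Man and colleagues ("normal" parameter set), with a
two-compartment stomach, gut absorption, plasma/tissue glucose masses,
liver/plasma insulin, delayed insulin signals, insulin action, and a
portal-secretion pair. Meal carbohydrate is injected as an impulse into the
solid-stomach compartment; gastric emptying follows the standard
dose-dependent tanh law. Two reductions are deliberate: hepatic insulin
extraction is held at its basal constant (the time-varying extraction adds a
13th state beyond the model's stated dimension), and the reference basal
values (Gb, Ib) are set self-consistently so that the fasting equilibrium
sits exactly at zero insulin action and zero secretion provision — without
this, the rest state carries small negative auxiliaries that the sigma-point
positivity rule would distort.

Estimated (personalized) subsets — chosen because they shift the mean and
variance of glucose and are relatively independent: ultradian `(E, Vp, tp)`;
meal `(VI, k1, k2)`.

Integration uses `scipy.integrate.solve_ivp` (RK45, rtol = atol = 1e-6),
dense output on a 1-minute grid, with the batch of sigma points stacked into
a single solve for speed. No clipping happens inside the integrator;
non-negativity is enforced only where the filter constructs sigma points.

## The modified dual UKF

Each measurement triggers, in order: (1) *state prediction* — sigma points
are placed from the posterior state covariance inflated by a factor
(1 + 0.1), positivity-constrained, propagated through the ODE flow to the
measurement time; (2) *state correction* — a standard Kalman update of the
6- or 12-dimensional state from the scalar glucose innovation, with the
posterior covariance symmetrized and eigenvalue-floored; (3) *parameter
correction* — a separate 3-dimensional UKF whose prior covariance is
inflated by 1/λ (forgetting factor λ = 0.985) and whose sigma points are
mapped to predicted measurements by re-integrating the last corrected state
under each candidate parameter vector.

The three modifications relative to a textbook dual UKF, all motivated by
online clinical robustness:

* covariance-proportional augmentation of the state sigma points replaces an
  assumed additive process-noise term (`q_state` defaults to 0);
* the forgetting factor lets parameters drift with behavior instead of
  freezing once their covariance collapses;
* negative sigma-point elements are replaced coordinate-wise by the smallest
  positive value of that coordinate across the set (zero if none), and only
  the real part of the covariance square root is used for placement.

Defaults: measurement variance R = (15 mg/dl)² (glucometer-scale error),
unscented scaling α = 1, β = 2, κ = 3 − n, initial covariances diagonal at
(10% of the mean)² per coordinate, initial state at the model's fasting
equilibrium, initial parameters at their canonical published values. All are
configurable. Every recorded forecast is produced *before* the corresponding
correction, so forecast error statistics are out of sample by construction.
Sigma points whose propagation fails are dropped and the weights
renormalized when at least n + 1 survive; otherwise the step is declared a
prediction failure, logged, and the belief carried forward — the run never
crashes mid-stream.

Three filter modes support ablation: `none` (reset glucose to the latest
measurement, integrate forward with fixed parameters), `state`, and `dual`.

## Model averaging and metrics

Forecast combination is a convex weighted sum; with two models a single
weight w₁ suffices. Retrospective optimization grid-searches w₁ over [0, 1]
in steps of 0.01 under one of three objectives: minimize MSE, maximize the
Pearson correlation between combined forecasts and measurements, or minimize
the KL divergence between the kernel density estimate (KDE) of the combined
forecast values and the KDE of the measurements. The KL route combines the
forecast *values* first and then takes one KDE, not a mixture of KDEs. Ties
break toward 0.5 to avoid locking onto a single model. The sequential
scheme refits the weights at each step on strictly past pairs (w₁ = 0.5
during a 10-measurement warmup), keeping the combined forecast causal.

Metrics: MSE; Pearson r with two-sided p (scipy), including lagged variants
restricted to measurements 45–75 ("1h") or 105–135 ("2h") minutes post-meal
(the tolerance bands are this package's choice); KL divergence by quadrature
of p·log(p/q) on a fixed glucose grid (20–400 mg/dl, 1 mg/dl step), with
Gaussian KDE (Silverman bandwidth), q floored at 1e-12 and the integrand
restricted to p > 1e-12 because KDE tails underflow. The KL direction
defaults to p = forecasts, q = measurements and is configurable.

## Clinical derivations

HbA1c ↔ mean glucose uses the ADAG linear relation (mean glucose = 28.7 ×
HbA1c − 46.7), so a sustained 126 mg/dl reads 6.0%. Daily HbA1c estimates
average the continuous model forecast over a trailing window (default 1 day,
90-day option): the HbA1c a patient would reach if they held that day's mean
glucose. Post-meal forecast intervals summarize the continuous forecast
30–120 minutes after a meal as mean ± sd, mean ± variance, or [min, max];
the capture fraction is the percentage of measurements 30–180 minutes
post-meal falling inside their meal's interval. Pairing measurements out to
180 minutes (beyond the 120-minute band window) is a deliberate reading of
"future measurements": the band is a forecast product, the later
measurements are its test.

## Gaussian-process baseline

A squared-exponential-kernel GP maps (pre-meal glucose, carbohydrate grams)
to post-meal glucose. Pairing rules are strict: the pre-meal reading must
lie within 15 minutes of the meal, and the first reading 45–180 minutes
after the meal is the target. Hyperparameters are fixed, not optimized:
unit length scales on standardized inputs, signal variance equal to the
training-output variance, observation noise (15 mg/dl)². Evaluation is
sequential with a growing training set, warm-starting on 50 meals; fewer
qualifying pairs than that raises an explicit insufficient-data signal
(sparse monitoring regimes genuinely cannot feed this baseline).
Standardization statistics are recomputed from the current training set at
every step.

## Virtual patients

The generator integrates ground truth from either model with known
parameters, then overlays a monitoring schedule and i.i.d. Gaussian meter
noise (default sd 10 mg/dl, floored at 20 mg/dl). Three regimes emulate
observed self-monitoring patterns: *dense* (pre-meal −5 min; post-meal +60,
+120, and +180 with probability 0.3; default 27 days), *typical* (pre −5,
post +120; default 28 days), *sparse* (Poisson 1.6 readings/day at uniform
random clock times over 15 days, ≈ 24 total). Meals: 3/day near 07:30,
12:30, 18:30 with ±45 min jitter, carbohydrates ~ Normal(50, 15²) g
truncated at 0, with an optional linear drift of the mean emulating gradual
dietary change. The truth trajectory is independent of the measurement
schedule.

What the simulator does **not** emulate: exercise, stress, sleep, illness,
medication changes, non-carbohydrate macronutrients, carbohydrate-estimate
error, or any model-mismatch between the generating physiology and the
filter's model family (when the filter uses the generating model, only
parameters are unknown). Passing tests therefore demonstrate that the
machinery is correct and self-consistent — that parameters are recoverable,
forecasts calibrated, and orderings (dual > no-filter, average ≥ best
single) hold under the stated conditions — not that any model matches a
particular human.

## Validation studies and their conditions

`glucoda.studies` fixes the in-silico study designs in one place:

* **Parameter recovery**: 20 seeds × 28-day typical-regime ultradian
  patients, noise sd 10 mg/dl, estimated parameters mis-initialized 30% from
  truth, dual filter. Reported per seed: the relative parameter error of the
  final-quarter mean estimate, and first-week vs final-week out-of-sample
  forecast MSE. The 30% offset uses mixed directions (E ×1.3, Vp ×1.3,
  tp ×0.7) because scaling all three parameters by a common factor is a
  near-compensating direction of the ultradian model — it shifts fasting
  glucose by under 1 mg/dl — and a study initialized along a direction the
  data cannot see would measure nothing.
* **Ablation**: one 14-day stationary patient with the same mis-specified
  initialization, comparing no-filter / state-filter / dual-filter MSE.
* **Averaging**: both filters run over a 14-day patient; a measurement
  stream is constructed as a fixed convex mix (w₁ = 0.65) of the two models'
  forecasts plus 5 mg/dl noise, and sequential MSE-based averaging is
  compared with each single model on the terminal third.

Problem sizes (days, seed counts) are the package's chosen study sizes;
they keep each study in the minutes range on one core while leaving the
trends far from the noise floor.

## Numerical choices and degenerate inputs

Covariances are symmetrized and eigenvalue-floored (1e-10) on every
construction. A zero-covariance belief collapses all sigma points onto the
mean (the matrix square root of the floored covariance is ~1e-5, visible
only below solver tolerance). Innovation variance ≤ 0 raises a numeric
error which the runner logs and skips. Measurements at identical times are
processed in file order. Constant samples defeat a Pearson correlation and
return NaN rather than a value; empty HbA1c windows return NaN, not 0.
Integration failures surface as flagged trajectories or dropped sigma
points, never exceptions escaping the online loop.

## Known limitations

* Parameter estimates are point trajectories with covariances; no smoothing,
  MCMC refinement, or ensemble/particle alternatives are provided.
* R and the forgetting factor are static; no online noise adaptation.
* The positivity rule plus real-part square root can cause premature
  parameter-covariance collapse (underfitting) when much of the covariance
  square root is complex; this is the accepted price of robustness.
* The parameter count of the canonical sources is a bookkeeping convention
  (it can include initial conditions and derived constants); this package
  exposes the independent constants of each model, all configurable.
* Only two-model averaging is exercised end to end, though the types admit
  M models.
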