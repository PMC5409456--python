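"""Modified dual unscented Kalman filter for online state and parameter
estimation from sparse, irregular glucose self-monitoring data.

The construction differs from a textbook dual UKF in three ways, all aimed
at robustness in an online clinical setting:

* **Covariance-proportional augmentation.**  Posterior state sigma points are
  spread using the posterior covariance inflated by a configurable fraction,
  instead of adding an assumed additive process-noise term.

* **Forgetting-factor parameter filter.**  The prior parameter covariance is
  inflated by ``1/lambda`` each step, letting tracked parameters drift with
  changing behavior and physiology.

* **Sigma-point positivity constraint.**  Negative elements of state and
  parameter sigma points are replaced by the smallest positive value that
  element takes across the sigma set (or by zero if none is positive), and
  only the real part of the covariance square root is used when placing
  points.

Three filtering modes support ablation studies: ``none`` (reset glucose to
the latest measurement and integrate forward), ``state`` (state filter
only), and ``dual`` (state and parameter filters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .exceptions import NumericError, ValidationError
from .models import get_model
from .timeline import PatientTimeline

__all__ = [
    "GaussianBelief",
    "SigmaPointSet",
    "NoiseConfig",
    "FilterRun",
    "Prediction",
    "PredictionFailure",
    "make_sigma_points",
    "enforce_positivity",
    "state_predict",
    "state_update",
    "param_step",
    "run_filter",
]

log = logging.getLogger(__name__)

EIG_FLOOR = 1e-10


class PredictionFailure(NumericError):
    """All sigma-point propagations failed; the caller carries the belief forward."""


def _repair_cov(cov: np.ndarray) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the matrix is PSD."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        log.debug("covariance eigenvalue floor applied (min eig %.3e)", w.min())
    w = np.maximum(w, EIG_FLOOR)
    return (v * w) @ v.T


@dataclass
class GaussianBelief:
    """Mean and covariance of a state or parameter estimate at a given time.

    The covariance is symmetrized and eigenvalue-floored on construction.
    """

    mean: np.ndarray
    cov: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = _repair_cov(self.cov)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValidationError(
                f"covariance shape {self.cov.shape} inconsistent with mean size {self.mean.size}"
            )

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class SigmaScaling:
    """Unscented transform scaling triple (alpha, beta, kappa).

    ``kappa=None`` resolves to the standard ``3 - n``.
    """

    alpha: float = 1.0
    beta: float = 2.0
    kappa: float | None = None

    def resolve_kappa(self, n: int) -> float:
        return (3.0 - n) if self.kappa is None else self.kappa


@dataclass
class SigmaPointSet:
    """2n+1 deterministically placed points with their UT weights."""

    points: np.ndarray  # (2n+1, n); row 0 is the central point chi_0
    mean_weights: np.ndarray
    cov_weights: np.ndarray
    scaling: SigmaScaling

    @property
    def n(self) -> int:
        return self.points.shape[1]


@dataclass
class NoiseConfig:
    """Filter noise/robustness knobs.

    R: glucose measurement variance, (mg/dl)^2; default (15 mg/dl)^2,
    approximately the error of a self-monitoring glucometer.
    q_state: additive process-noise scale (default 0; covariance-proportional
    augmentation replaces it).
    state_augmentation_fraction: posterior covariance is inflated by
    (1 + fraction) before sigma-point placement.
    forgetting_factor: lambda in (0, 1]; prior parameter covariance is
    inflated by 1/lambda each parameter-filter step.
    """

    R: float = 225.0
    q_state: float = 0.0
    state_augmentation_fraction: float = 0.1
    forgetting_factor: float = 0.985
    scaling: SigmaScaling = field(default_factory=SigmaScaling)

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValidationError("R must be > 0")
        if not (0 < self.forgetting_factor <= 1):
            raise ValidationError("forgetting_factor must lie in (0, 1]")
        if self.q_state < 0 or self.state_augmentation_fraction < 0:
            raise ValidationError("noise fractions must be >= 0")


def make_sigma_points(belief: GaussianBelief, scaling: SigmaScaling | None = None) -> SigmaPointSet:
    """Standard unscented placement around a Gaussian belief.

    chi_0 is the mean; chi_i = mean +/- sqrt((n + lambda) P) columns.  Only
    the real part of the matrix square root is used, matching the filter's
    robustness modification for near-degenerate covariances.
    """
    scaling = scaling or SigmaScaling()
    n = belief.dim
    kappa = scaling.resolve_kappa(n)
    lam = scaling.alpha**2 * (n + kappa) - n
    if n + lam <= 0:
        raise ValidationError("scaling yields n + lambda <= 0")
    sqrt_mat = scipy.linalg.sqrtm((n + lam) * belief.cov)
    sqrt_mat = np.real(np.atleast_2d(sqrt_mat))
    points = np.empty((2 * n + 1, n))
    points[0] = belief.mean
    for i in range(n):
        points[1 + i] = belief.mean + sqrt_mat[:, i]
        points[1 + n + i] = belief.mean - sqrt_mat[:, i]
    wm = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = wm[0] + (1.0 - scaling.alpha**2 + scaling.beta)
    return SigmaPointSet(points, wm, wc, scaling)


def enforce_positivity(sigma: SigmaPointSet) -> SigmaPointSet:
    """Replace negative sigma-point elements, coordinate by coordinate, with
    the smallest positive value that coordinate takes across the set; if no
    positive value exists, with zero.  Non-negative entries are unchanged."""
    pts = sigma.points.copy()
    for j in range(pts.shape[1]):
        col = pts[:, j]
        neg = col < 0
        if not np.any(neg):
            continue
        pos = col[col > 0]
        fill = pos.min() if pos.size else 0.0
        col[neg] = fill
        pts[:, j] = col
    return replace(sigma, points=pts)


def _weighted_stats(points, wm, wc):
    mean = wm @ points
    dev = points - mean
    cov = (dev * wc[:, None]).T @ dev
    return mean, dev, cov


@dataclass
class Prediction:
    """Output of the state-prediction step, consumed by :func:`state_update`."""

    belief: GaussianBelief        # predicted state (prior at t_next)
    y_hat: float                  # predicted glucose observation, mg/dl
    cross_cov: np.ndarray         # P_xy between state and observation
    obs_var: float                # observation variance from sigma spread (no R)


def _drop_failed(points, wm, wc, n_min):
    ok = np.all(np.isfinite(points), axis=1)
    if ok.sum() < n_min:
        raise PredictionFailure(
            f"only {int(ok.sum())} of {len(points)} sigma propagations survived"
        )
    if ok.all():
        return points, wm, wc
    points, wm, wc = points[ok], wm[ok].copy(), wc[ok].copy()
    total = wm.sum()
    if abs(total) < 1e-12:
        raise PredictionFailure("surviving sigma weights degenerate")
    wm = wm / total
    wc = wc / total
    return points, wm, wc


def state_predict(model, state_belief: GaussianBelief, params: dict, t_next: float,
                  meals, noise: NoiseConfig) -> Prediction:
    """Propagate the state belief to ``t_next`` through the model flow.

    Sigma points are placed from the posterior covariance inflated by
    ``(1 + state_augmentation_fraction)`` (plus any additive ``q_state``),
    positivity-constrained, and each propagated through the ODE flow with
    meal forcing.  Individual propagation failures drop the point and
    renormalize the weights if at least n+1 points survive.
    """
    if t_next < state_belief.time:
        raise ValidationError("t_next must be >= belief time")
    n = state_belief.dim
    cov = state_belief.cov * (1.0 + noise.state_augmentation_fraction)
    if noise.q_state > 0:
        cov = cov + noise.q_state * np.eye(n)
    inflated = GaussianBelief(state_belief.mean, cov, state_belief.time)
    sigma = enforce_positivity(make_sigma_points(inflated, noise.scaling))
    props = model.flow(sigma.points, params, state_belief.time, t_next, meals)
    props, wm, wc = _drop_failed(props, sigma.mean_weights, sigma.cov_weights, n + 1)
    mean, dev, cov_pred = _weighted_stats(props, wm, wc)
    y = model.observe(props, params)
    y_hat = float(wm @ y)
    y_dev = y - y_hat
    cross = (dev * wc[:, None]).T @ y_dev
    obs_var = float(wc @ (y_dev**2))
    return Prediction(GaussianBelief(mean, cov_pred, t_next), y_hat, cross, obs_var)


def state_update(predicted: Prediction, y: float, R: float) -> GaussianBelief:
    """Kalman correction of a predicted belief against a glucose measurement."""
    S = predicted.obs_var + R
    if S <= 0 or not np.isfinite(S):
        raise NumericError(f"innovation variance degenerate: S={S}")
    K = predicted.cross_cov / S
    innovation = y - predicted.y_hat
    mean = predicted.belief.mean + K * innovation
    cov = predicted.belief.cov - S * np.outer(K, K)
    return GaussianBelief(mean, cov, predicted.belief.time)


def param_step(model, param_belief: GaussianBelief, state_belief: GaussianBelief,
               y: float, t_k: float, meals, noise: NoiseConfig,
               fixed_params: dict) -> GaussianBelief:
    """One forgetting-factor parameter-filter step.

    The prior parameter covariance is inflated by ``1/lambda``; each
    positivity-constrained parameter sigma point is mapped to a predicted
    measurement by integrating the last corrected state to ``t_k`` under that
    parameter value, and the parameter mean/covariance receive a
    Kalman-style correction against the measurement ``y``.
    """
    names = model.estimated
    if param_belief.dim != len(names):
        raise ValidationError("parameter belief must cover the estimated subset")
    lam = noise.forgetting_factor
    prior = GaussianBelief(param_belief.mean, param_belief.cov / lam, param_belief.time)
    sigma = enforce_positivity(make_sigma_points(prior, noise.scaling))
    x0 = np.maximum(state_belief.mean, 0.0)
    # one stacked solve: row i carries parameter sigma point i
    batch_params = dict(fixed_params)
    batch_params.update({
        name: np.maximum(sigma.points[:, j], 1e-9) for j, name in enumerate(names)
    })
    x0s = np.tile(x0, (len(sigma.points), 1))
    try:
        xT = model.flow(x0s, batch_params, state_belief.time, t_k, meals)
    except NumericError as e:
        raise PredictionFailure(str(e)) from None
    y_preds = np.asarray(model.observe(xT, batch_params), dtype=float)
    y_preds[~np.all(np.isfinite(xT), axis=1)] = np.nan
    pts = np.column_stack([sigma.points, y_preds])  # reuse row-dropping machinery
    pts, wm, wc = _drop_failed(pts, sigma.mean_weights, sigma.cov_weights, len(names) + 1)
    w_pts, y_preds = pts[:, :-1], pts[:, -1]
    w_mean, w_dev, w_cov = _weighted_stats(w_pts, wm, wc)
    y_hat = float(wm @ y_preds)
    y_dev = y_preds - y_hat
    S = float(wc @ (y_dev**2)) + noise.R
    if S <= 0 or not np.isfinite(S):
        raise NumericError(f"parameter innovation variance degenerate: S={S}")
    K = ((w_dev * wc[:, None]).T @ y_dev) / S
    mean = w_mean + K * (y - y_hat)
    cov = w_cov - S * np.outer(K, K)
    return GaussianBelief(np.maximum(mean, 1e-9), cov, t_k)


@dataclass
class FilterRun:
    """Per-measurement filter records plus the continuous central-sigma-point
    (chi_0) glucose trace between measurements."""

    model_id: str
    mode: str
    times: np.ndarray            # measurement times consumed, in order
    measured: np.ndarray         # y_k, mg/dl
    forecasts: np.ndarray        # y_hat_{k|k-1}, made before correction
    innovations: np.ndarray      # y_k - y_hat_{k|k-1}
    gains: list                  # Kalman gain vectors (None where no update)
    state_means: np.ndarray      # posterior state means, (n_meas, dim)
    param_means: np.ndarray      # posterior estimated-parameter means, (n_meas, p)
    param_names: tuple
    chi0_times: np.ndarray       # dense minute grid
    chi0_glucose: np.ndarray     # chi_0 glucose, mg/dl
    n_failures: int = 0

    @property
    def mse(self) -> float:
        ok = np.isfinite(self.forecasts)
        return float(np.mean((self.forecasts[ok] - self.measured[ok]) ** 2))


def _initial_beliefs(model, params, frac=0.1):
    x0 = model.fasting_equilibrium(params)
    var = np.maximum((frac * x0) ** 2, 1.0)
    state = GaussianBelief(x0, np.diag(var), 0.0)
    w0 = np.array([params[name] for name in model.estimated], dtype=float)
    wvar = np.maximum((frac * w0) ** 2, 1e-8)
    param = GaussianBelief(w0, np.diag(wvar), 0.0)
    return state, param


def run_filter(timeline: PatientTimeline, model_id: str, mode: str = "dual",
               noise: NoiseConfig | None = None, seed: int | None = None,
               init_params: dict | None = None, init_cov_fraction: float = 0.1,
               grid_step: float = 1.0, trace_tail_min: float = 180.0) -> FilterRun:
    """Process a patient timeline online, one measurement at a time.

    mode 'none' resets plasma glucose to the latest measurement and runs the
    model forward with fixed parameters; 'state' runs the state filter only;
    'dual' runs the state filter then the parameter filter per measurement.
    Every recorded forecast is made before the corresponding correction, so
    all forecasts are out of sample.  Mid-run numerical failures are logged
    and skipped; the run continues.  The filter itself is deterministic;
    ``seed`` is accepted for interface uniformity.
    """
    if mode not in {"none", "state", "dual"}:
        raise ValidationError(f"unknown mode {mode!r}")
    if timeline.n_measurements < 1:
        raise ValidationError("timeline must contain at least one measurement")
    # model_id may be a registered id or any object implementing the model
    # interface (flow/observe/fasting_equilibrium/...), e.g. a test system
    model = get_model(model_id) if isinstance(model_id, str) else model_id
    model_id = model.model_id
    noise = noise or NoiseConfig()
    params = model.check_params(dict(init_params or {}))
    meals = timeline.meal_array()
    state_belief, param_belief = _initial_beliefs(model, params, init_cov_fraction)

    times = timeline.measurements["time_min"].to_numpy(float)
    ys = timeline.measurements["glucose_mgdl"].to_numpy(float)
    t_first = min(0.0, times[0])
    state_belief.time = t_first
    n_meas = len(times)

    forecasts = np.full(n_meas, np.nan)
    innovations = np.full(n_meas, np.nan)
    gains: list = [None] * n_meas
    state_means = np.empty((n_meas, model.dim))
    param_means = np.empty((n_meas, len(model.estimated)))
    chi0_t: list = []
    chi0_g: list = []
    n_failures = 0

    def extend_trace(x_from, t_from, t_to, p):
        if t_to <= t_from:
            return
        traj = model.integrate(np.maximum(x_from, 0.0), p, t_from, t_to,
                               meals=meals, grid_step=grid_step)
        sl = 1 if (chi0_t and traj.times.size and traj.times[0] <= chi0_t[-1][-1] + 1e-9) else 0
        chi0_t.append(traj.times[sl:])
        chi0_g.append(traj.glucose[sl:])
        if not traj.ok:
            log.warning("chi0 trace truncated at t=%.1f (%s)", traj.times[-1], traj.message)

    for k in range(n_meas):
        t_k, y_k = float(times[k]), float(ys[k])
        current = {**params, **dict(zip(model.estimated, param_belief.mean))} \
            if mode == "dual" else params
        prev_state = state_belief

        # continuous off-data forecast from the last corrected state
        extend_trace(state_belief.mean, state_belief.time, t_k, current)

        if mode == "none":
            x0 = model.set_glucose(state_belief.mean, ys[k - 1], params) if k > 0 \
                else state_belief.mean
            t0 = float(times[k - 1]) if k > 0 else state_belief.time
            try:
                xT = model.flow(np.maximum(x0, 0.0), params, t0, t_k, meals)
                if not np.all(np.isfinite(xT)):
                    raise PredictionFailure("flow returned non-finite state")
                forecasts[k] = model.observe(xT, params)
                innovations[k] = y_k - forecasts[k]
                state_belief = GaussianBelief(xT, state_belief.cov, t_k)
            except NumericError as e:
                n_failures += 1
                log.warning("no-filter forecast failed at t=%.1f: %s", t_k, e)
                state_belief = GaussianBelief(state_belief.mean, state_belief.cov, t_k)
        else:
            try:
                pred = state_predict(model, state_belief, current, t_k, meals, noise)
                forecasts[k] = pred.y_hat
                innovations[k] = y_k - pred.y_hat
                gains[k] = pred.cross_cov / (pred.obs_var + noise.R)
                state_belief = state_update(pred, y_k, noise.R)
            except NumericError as e:
                n_failures += 1
                log.warning("state filter skipped at t=%.1f: %s", t_k, e)
                state_belief = GaussianBelief(state_belief.mean, state_belief.cov, t_k)
            if mode == "dual":
                try:
                    param_belief = param_step(model, param_belief, prev_state, y_k,
                                              t_k, meals, noise, params)
                except NumericError as e:
                    n_failures += 1
                    log.warning("parameter filter skipped at t=%.1f: %s", t_k, e)
                    param_belief = GaussianBelief(param_belief.mean, param_belief.cov, t_k)

        state_means[k] = state_belief.mean
        param_means[k] = param_belief.mean

    # extend the chi0 trace past the last measurement to cover the span
    final_params = {**params, **dict(zip(model.estimated, param_belief.mean))} \
        if mode == "dual" else params
    t_end = max(timeline.span[1] + trace_tail_min, state_belief.time)
    extend_trace(state_belief.mean, state_belief.time, t_end, final_params)

    chi0_times = np.concatenate(chi0_t) if chi0_t else np.array([t_first])
    chi0_glucose = np.concatenate(chi0_g) if chi0_g else np.atleast_1d(
        model.observe(state_means[0], params))
    return FilterRun(model_id, mode, times.copy(), ys.copy(), forecasts, innovations,
                     gains, state_means, param_means, tuple(model.estimated),
                     chi0_times, chi0_glucose, n_failures)
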