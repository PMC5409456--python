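"""Gaussian-process regression baseline for post-meal glucose.

A non-mechanistic comparator: regression from (pre-meal glucose,
carbohydrate grams) to the first qualifying post-meal glucose.  Pairs are
extracted with strict timing rules (pre-meal reading within 15 minutes of
the meal; first post-meal reading 45-180 minutes after), the kernel is a
squared exponential on standardized inputs with fixed hyperparameters --
deliberately not optimized -- and evaluation is sequential with a growing
training set: warm-start on the first 50 meals, then forecast each new meal
before absorbing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .exceptions import ValidationError
from .timeline import PatientTimeline

__all__ = [
    "MealPair",
    "KernelConfig",
    "InsufficientDataError",
    "extract_meal_pairs",
    "fit",
    "predict",
    "sequential_evaluate",
    "SequentialGPResult",
]

PRE_WINDOW_MIN = 15.0          # |measurement - meal| <= 15 min qualifies as pre-meal
POST_WINDOW = (45.0, 180.0)    # first measurement in this window is the post-meal value
DEFAULT_TRAIN_N = 50


@dataclass(frozen=True)
class MealPair:
    """One (pre-meal glucose, carbs) -> post-meal glucose training example."""

    meal_time: float
    pre_glucose: float   # mg/dl
    carbs: float         # g
    post_glucose: float  # mg/dl
    post_time: float

    def __post_init__(self) -> None:
        if min(self.pre_glucose, self.post_glucose) <= 0 or self.carbs < 0:
            raise ValidationError("meal pair values must be positive")
        if self.post_time <= self.meal_time:
            raise ValidationError("post measurement must be strictly after the meal")


@dataclass(frozen=True)
class KernelConfig:
    """Fixed GP hyperparameters (no optimization, by design).

    length_scale applies on standardized inputs; signal_variance None means
    "use the sample variance of the training outputs"; noise_sd defaults to
    glucometer-scale error (15 mg/dl).
    """

    length_scale: float = 1.0
    signal_variance: float | None = None
    noise_sd: float = 15.0


class InsufficientDataError(ValidationError):
    """Too few qualifying meal pairs to run the sequential evaluation."""


def extract_meal_pairs(timeline: PatientTimeline) -> list:
    """One pair per meal having both a qualifying pre- and post-measurement.

    Pre: any glucose reading within 15 min of the meal start (nearest wins);
    post: the FIRST reading 45-180 min after.  Meals lacking either are
    skipped.
    """
    t = timeline.measurements["time_min"].to_numpy(float)
    g = timeline.measurements["glucose_mgdl"].to_numpy(float)
    pairs = []
    for _, meal in timeline.meals.iterrows():
        tm, carbs = float(meal.time_min), float(meal.carbs_g)
        near = np.abs(t - tm) <= PRE_WINDOW_MIN
        if not near.any():
            continue
        idx_pre = np.argmin(np.where(near, np.abs(t - tm), np.inf))
        post_mask = (t - tm >= POST_WINDOW[0]) & (t - tm <= POST_WINDOW[1])
        if not post_mask.any():
            continue
        idx_post = int(np.flatnonzero(post_mask)[0])
        pairs.append(MealPair(tm, float(g[idx_pre]), carbs,
                              float(g[idx_post]), float(t[idx_post])))
    return pairs


def _design(pairs) -> tuple:
    X = np.array([[p.pre_glucose, p.carbs] for p in pairs], dtype=float)
    y = np.array([p.post_glucose for p in pairs], dtype=float)
    return X, y


@dataclass
class _TrainedGP:
    gp: GaussianProcessRegressor
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float

    def predict(self, X, return_std=False):
        Z = (np.atleast_2d(X) - self.x_mean) / self.x_sd
        out = self.gp.predict(Z, return_std=return_std)
        if return_std:
            return out[0] + self.y_mean, out[1]
        return out + self.y_mean


def fit(pairs, kernel_config: KernelConfig | None = None) -> _TrainedGP:
    """Standard GP regression with a squared-exponential kernel on
    standardized 2-D inputs and a fixed observation-noise term."""
    cfg = kernel_config or KernelConfig()
    if len(pairs) < 2:
        raise ValidationError("GP fit needs at least 2 meal pairs")
    X, y = _design(pairs)
    x_mean = X.mean(axis=0)
    x_sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    y_mean = float(y.mean())
    sig = cfg.signal_variance if cfg.signal_variance is not None else max(float(y.var()), 1.0)
    kernel = ConstantKernel(sig, constant_value_bounds="fixed") * RBF(
        cfg.length_scale, length_scale_bounds="fixed")
    gp = GaussianProcessRegressor(kernel=kernel, alpha=cfg.noise_sd**2,
                                  optimizer=None, normalize_y=False)
    gp.fit((X - x_mean) / x_sd, y - y_mean)
    return _TrainedGP(gp, x_mean, x_sd, y_mean)


def predict(model: _TrainedGP, pre_glucose, carbs, return_std=False):
    """Post-meal glucose forecast (optionally with predictive sd)."""
    X = np.column_stack([np.atleast_1d(pre_glucose), np.atleast_1d(carbs)])
    return model.predict(X, return_std=return_std)


@dataclass
class SequentialGPResult:
    """Out-of-sample forecasts from the growing-training-set evaluation."""

    meal_times: np.ndarray
    forecasts: np.ndarray
    measured: np.ndarray   # realized post-meal glucose

    @property
    def mse(self) -> float:
        return float(np.mean((self.forecasts - self.measured) ** 2))


def sequential_evaluate(pairs, initial_train_n: int = DEFAULT_TRAIN_N,
                        kernel_config: KernelConfig | None = None) -> SequentialGPResult:
    """Warm-start on the first ``initial_train_n`` meals, then forecast each
    subsequent meal from all strictly earlier meals before absorbing it.

    Raises :class:`InsufficientDataError` when there is nothing to forecast
    (at most ``initial_train_n`` pairs) -- sparse self-monitoring often
    cannot feed this baseline at all.
    """
    pairs = sorted(pairs, key=lambda p: p.meal_time)
    if len(pairs) <= initial_train_n:
        raise InsufficientDataError(
            f"{len(pairs)} qualifying meal pairs; need more than {initial_train_n}"
        )
    cfg = kernel_config or KernelConfig()
    times, preds, actual = [], [], []
    for k in range(initial_train_n, len(pairs)):
        model = fit(pairs[:k], cfg)
        yhat = float(predict(model, pairs[k].pre_glucose, pairs[k].carbs)[0])
        times.append(pairs[k].meal_time)
        preds.append(yhat)
        actual.append(pairs[k].post_glucose)
    return SequentialGPResult(np.array(times), np.array(preds), np.array(actual))
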