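"""Model averaging: convex combination of forecasters with weights chosen to
optimize a quality metric on past data.

Weights live on the simplex (non-negative, summing to one); with two models
a single weight ``w1`` determines the combination.  Retrospective
optimization grid-searches ``w1`` over [0, 1]; the sequential scheme refits
the weights at every forecasting step using strictly past pairs only, so the
combined forecast remains out of sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import kl_between_samples, linear_correlation, mse
from .exceptions import ValidationError
from .ukf import FilterRun

__all__ = [
    "AveragingWeights",
    "averaged_forecast",
    "optimize_weights",
    "sequential_average",
    "SequentialAverageResult",
]

METRICS = ("mse", "lc", "kl")
GRID_STEP = 0.01


@dataclass(frozen=True)
class AveragingWeights:
    """Length-M non-negative weight vector summing to one."""

    w: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "w", tuple(float(x) for x in w))

    @classmethod
    def from_w1(cls, w1: float) -> "AveragingWeights":
        return cls((w1, 1.0 - w1))

    @property
    def w1(self) -> float:
        return self.w[0]


def averaged_forecast(per_model_forecasts, weights: AveragingWeights) -> np.ndarray:
    """Element-wise weighted sum of M aligned forecast sequences."""
    arrs = [np.asarray(f, dtype=float) for f in per_model_forecasts]
    if len(arrs) != len(weights.w):
        raise ValidationError("one weight per model required")
    if len({a.shape for a in arrs}) != 1:
        raise ValidationError("forecast sequences must be aligned (equal shapes)")
    return sum(w * a for w, a in zip(weights.w, arrs))


def _metric_value(metric, combined, y):
    if metric == "mse":
        return mse(combined, y)
    if metric == "lc":
        r, _ = linear_correlation(combined, y)
        return float("nan") if np.isnan(r) else -r  # maximize r == minimize -r
    if metric == "kl":
        return kl_between_samples(combined, y)
    raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")


def optimize_weights(forecasts_1, forecasts_2, measurements, metric: str = "mse",
                     grid_step: float = GRID_STEP) -> AveragingWeights:
    """Grid-search w1 in [0, 1] minimizing MSE or KL, or maximizing correlation.

    Ties are broken toward 0.5 to avoid degenerate single-model lock-in.
    Degenerate histories (e.g. constant measurements under the correlation
    metric) raise a ValidationError -- the missing-value outcome.
    """
    x1 = np.asarray(forecasts_1, dtype=float)
    x2 = np.asarray(forecasts_2, dtype=float)
    y = np.asarray(measurements, dtype=float)
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    x1, x2, y = x1[ok], x2[ok], y[ok]
    if y.size < 3:
        raise ValidationError("need at least 3 history pairs to optimize weights")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    values = np.array([_metric_value(metric, w1 * x1 + (1 - w1) * x2, y) for w1 in grid])
    if np.all(np.isnan(values)):
        raise ValidationError(f"metric {metric!r} undefined on this history (degenerate)")
    best = np.nanmin(values)
    candidates = grid[np.isclose(values, best, rtol=0, atol=1e-12)]
    w1 = float(candidates[np.argmin(np.abs(candidates - 0.5))])
    return AveragingWeights.from_w1(w1)


@dataclass
class SequentialAverageResult:
    """Online model-averaged forecasts with the weight trajectory."""

    times: np.ndarray
    measured: np.ndarray
    forecasts: np.ndarray      # combined, strictly causal
    weights: np.ndarray        # w1 used at each step
    metric: str

    @property
    def mse(self) -> float:
        ok = np.isfinite(self.forecasts)
        return float(np.mean((self.forecasts[ok] - self.measured[ok]) ** 2))


def sequential_average(run1: FilterRun, run2: FilterRun, metric: str = "mse",
                       warmup_n: int = 10) -> SequentialAverageResult:
    """Sequential (online) model averaging over two filter runs.

    At each measurement k > warmup_n the weights are refit on pairs
    1..k-1 only, then applied to forecast k; before warmup w1 = 0.5.
    Strictly causal: data at or after step k never influence forecast k.
    """
    if warmup_n < 2:
        raise ValidationError("warmup_n must be >= 2")
    if run1.times.shape != run2.times.shape or not np.allclose(run1.times, run2.times):
        raise ValidationError("runs must share the same measurement timeline")
    if not np.allclose(run1.measured, run2.measured):
        raise ValidationError("runs must share the same measurements")
    n = len(run1.times)
    combined = np.full(n, np.nan)
    weights = np.full(n, 0.5)
    for k in range(n):
        if k >= warmup_n:
            try:
                weights[k] = optimize_weights(
                    run1.forecasts[:k], run2.forecasts[:k], run1.measured[:k], metric
                ).w1
            except ValidationError:
                weights[k] = weights[k - 1] if k else 0.5
        combined[k] = weights[k] * run1.forecasts[k] + (1 - weights[k]) * run2.forecasts[k]
    return SequentialAverageResult(run1.times.copy(), run1.measured.copy(),
                                   combined, weights, metric)
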