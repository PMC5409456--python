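"""Model-selection metrics: pointwise MSE, (lagged) linear correlation, and
KDE-based Kullback-Leibler divergence between forecast and measurement
distributions.

All three metrics score a forecaster against paired glucose measurements;
none of them alone picks the "best" model, which is why reports carry the
full triple.  The KL divergence compares kernel density estimates on a fixed
glucose grid (20-400 mg/dl, 1 mg/dl step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "GLUCOSE_GRID",
    "mse",
    "linear_correlation",
    "kde",
    "kl_divergence",
    "kl_between_samples",
    "lag_pairs",
    "EvaluationReport",
    "evaluate_forecaster",
]

GLUCOSE_GRID = np.arange(20.0, 400.0 + 1e-9, 1.0)
_DENSITY_FLOOR = 1e-12

# a "1h" pair is a measurement 45-75 min post-meal; "2h" is 105-135 min
LAG_WINDOWS = {"1h": (45.0, 75.0), "2h": (105.0, 135.0)}


def mse(forecasts, measurements) -> float:
    """Mean squared error between paired forecasts and measurements, (mg/dl)^2."""
    f = np.asarray(forecasts, dtype=float)
    y = np.asarray(measurements, dtype=float)
    if f.shape != y.shape or f.size == 0:
        raise ValidationError("forecasts and measurements must be equal-length, non-empty")
    return float(np.mean((f - y) ** 2))


def lag_pairs(times, meal_times, lag: str):
    """Boolean mask of measurement times falling in the given post-meal window.

    A time qualifies if it lies ``LAG_WINDOWS[lag]`` minutes after any meal.
    """
    lo, hi = LAG_WINDOWS[lag]
    times = np.asarray(times, dtype=float)
    meal_times = np.asarray(meal_times, dtype=float)
    if meal_times.size == 0:
        return np.zeros(times.shape, dtype=bool)
    dt = times[:, None] - meal_times[None, :]
    return np.any((dt >= lo) & (dt <= hi), axis=1)


def linear_correlation(forecasts, measurements, times=None, meal_times=None,
                       lag_selector: str = "all"):
    """Pearson correlation (r, p) between forecasts and measurements.

    ``lag_selector`` 'all' uses every pair; '1h'/'2h' restrict to pairs whose
    measurement falls in the corresponding post-meal window.  Fewer than 3
    pairs after filtering (or constant inputs) yield (nan, nan) -- the
    missing-value outcome for unresolvable correlations.
    """
    f = np.asarray(forecasts, dtype=float)
    y = np.asarray(measurements, dtype=float)
    if f.shape != y.shape:
        raise ValidationError("forecasts and measurements must be equal length")
    if lag_selector != "all":
        if times is None or meal_times is None:
            raise ValidationError("lagged correlation needs measurement and meal times")
        mask = lag_pairs(times, meal_times, lag_selector)
        f, y = f[mask], y[mask]
    ok = np.isfinite(f) & np.isfinite(y)
    f, y = f[ok], y[ok]
    if f.size < 3 or np.std(f) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(f, y)
    return (float(r), float(p))


def kde(samples, bandwidth=None, grid=GLUCOSE_GRID) -> np.ndarray:
    """Gaussian-kernel density of glucose samples on the fixed grid.

    Bandwidth follows Silverman's rule unless overridden (mg/dl).  The
    result is renormalized to integrate to 1 on the grid.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("kde needs at least 2 samples")
    if np.std(x) == 0:
        # degenerate sample: narrow kernel around the common value
        dens = stats.norm.pdf(grid, loc=x[0], scale=1.0)
    else:
        k = stats.gaussian_kde(x, bw_method="silverman" if bandwidth is None else
                               bandwidth / x.std(ddof=1))
        dens = k(grid)
    step = grid[1] - grid[0]
    total = dens.sum() * step
    if total <= 0:
        raise ValidationError("all sample mass lies outside the glucose grid")
    return dens / total


def kl_divergence(p_density, q_density, grid=GLUCOSE_GRID) -> float:
    """Grid quadrature of p log(p/q) in nats.

    q is floored at 1e-12 before the log, and the integrand is restricted to
    grid points where p exceeds the same floor (KDE tails underflow).
    """
    p = np.asarray(p_density, dtype=float)
    q = np.asarray(q_density, dtype=float)
    if p.shape != q.shape or p.shape != grid.shape:
        raise ValidationError("densities must live on the same grid")
    step = grid[1] - grid[0]
    q = np.maximum(q, _DENSITY_FLOOR)
    mask = p > _DENSITY_FLOOR
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])) * step)


def kl_between_samples(forecast_samples, measurement_samples, direction: str = "pq") -> float:
    """KL divergence between the KDEs of two glucose sample sets.

    Default direction 'pq' takes p = forecasts, q = measurements; 'qp'
    reverses it (both orderings appear in practice).
    """
    p = kde(forecast_samples)
    q = kde(measurement_samples)
    if direction == "qp":
        p, q = q, p
    elif direction != "pq":
        raise ValidationError("direction must be 'pq' or 'qp'")
    return kl_divergence(p, q)


@dataclass
class EvaluationReport:
    """MSE / correlation / KL triple for one forecaster, plus summary stats."""

    forecaster: str
    mse: float
    lc: tuple              # (r, p) over all pairs
    lc_1h: tuple
    lc_2h: tuple
    kl: float
    forecast_mean: float
    forecast_sd: float
    measured_mean: float
    measured_sd: float

    def as_dict(self) -> dict:
        return {
            "forecaster": self.forecaster,
            "mse": self.mse,
            "lc_r": self.lc[0], "lc_p": self.lc[1],
            "lc_1h_r": self.lc_1h[0], "lc_1h_p": self.lc_1h[1],
            "lc_2h_r": self.lc_2h[0], "lc_2h_p": self.lc_2h[1],
            "kl": self.kl,
            "forecast_mean": self.forecast_mean, "forecast_sd": self.forecast_sd,
            "measured_mean": self.measured_mean, "measured_sd": self.measured_sd,
        }


def evaluate_forecaster(name, forecasts, measurements, times=None, meal_times=None,
                        kl_direction: str = "pq") -> EvaluationReport:
    """Full metric triple for one forecaster against paired measurements."""
    f = np.asarray(forecasts, dtype=float)
    y = np.asarray(measurements, dtype=float)
    ok = np.isfinite(f) & np.isfinite(y)
    f_ok, y_ok = f[ok], y[ok]
    t_ok = np.asarray(times, dtype=float)[ok] if times is not None else None
    lagged = t_ok is not None and meal_times is not None
    return EvaluationReport(
        forecaster=name,
        mse=mse(f_ok, y_ok),
        lc=linear_correlation(f_ok, y_ok),
        lc_1h=linear_correlation(f_ok, y_ok, t_ok, meal_times, "1h") if lagged else (float("nan"),) * 2,
        lc_2h=linear_correlation(f_ok, y_ok, t_ok, meal_times, "2h") if lagged else (float("nan"),) * 2,
        kl=kl_between_samples(f_ok, y_ok, kl_direction),
        forecast_mean=float(np.mean(f_ok)), forecast_sd=float(np.std(f_ok, ddof=1)),
        measured_mean=float(np.mean(y_ok)), measured_sd=float(np.std(y_ok, ddof=1)),
    )
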