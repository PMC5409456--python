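"""Clinically framed products derived from the continuous filter forecast:
point post-meal forecasts, moving-window HbA1c estimates, and dynamic
post-meal forecast ranges with capture-fraction scoring.

HbA1c is mapped to mean glucose through the linear ADAG relation

    mean glucose [mg/dl] = 28.7 * HbA1c [%] - 46.7

so a sustained mean of 126 mg/dl corresponds to 6.0%.  "Daily" HbA1c
estimates answer the question: what HbA1c would result if the patient
maintained that day's mean glucose for ~90 days?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ukf import FilterRun

__all__ = [
    "ForecastTrace",
    "ForecastInterval",
    "postmeal_forecast",
    "hba1c_from_mean_glucose",
    "mean_glucose_from_hba1c",
    "hba1c_series",
    "forecast_band",
    "capture_fraction",
    "pair_measurements_to_meals",
]

ADAG_SLOPE = 28.7   # mg/dl per % HbA1c
ADAG_OFFSET = -46.7  # mg/dl

BAND_KINDS = ("sd", "var", "range")
MINUTES_PER_DAY = 1440.0


@dataclass
class ForecastTrace:
    """Dense central-sigma-point (chi_0) glucose curve from a filter run."""

    times: np.ndarray     # strictly increasing minute grid
    chi0: np.ndarray      # glucose mg/dl
    source: str = ""      # model_id + mode

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.chi0 = np.asarray(self.chi0, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.chi0.shape:
            raise ValidationError("times and chi0 must be equal-length 1-D arrays")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.chi0)):
            raise ValidationError("trace glucose must be finite")

    @classmethod
    def from_run(cls, run: FilterRun) -> "ForecastTrace":
        return cls(run.chi0_times, run.chi0_glucose, source=f"{run.model_id}:{run.mode}")

    def at(self, t: float) -> float:
        """chi_0 value at the nearest grid point; NaN outside the span."""
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            return float("nan")
        return float(self.chi0[np.argmin(np.abs(self.times - t))])

    def window(self, lo: float, hi: float) -> np.ndarray:
        mask = (self.times >= lo) & (self.times <= hi)
        return self.chi0[mask]


def postmeal_forecast(trace: ForecastTrace, meal, lag_min: float) -> float:
    """chi_0 glucose at meal time + lag (nearest grid point).

    Returns NaN (the no-forecast signal) when the target time lies outside
    the trace span.
    """
    return trace.at(meal.time + lag_min)


def hba1c_from_mean_glucose(mean_mgdl):
    """Invert the ADAG linear relation: HbA1c % for a sustained mean glucose."""
    return (np.asarray(mean_mgdl, dtype=float) - ADAG_OFFSET) / ADAG_SLOPE


def mean_glucose_from_hba1c(hba1c_pct):
    return ADAG_SLOPE * np.asarray(hba1c_pct, dtype=float) + ADAG_OFFSET


def hba1c_series(trace: ForecastTrace, window_days: float = 1.0) -> pd.DataFrame:
    """Daily HbA1c estimates from trailing-window means of the chi_0 trace.

    For each calendar day d (days since timeline origin) the mean of chi_0
    over the trailing ``window_days`` ending at the end of day d is mapped
    through the ADAG relation.  Days whose window contains no trace samples
    get NaN, not 0.  Columns: day, mean_glucose, hba1c.
    """
    if window_days < 1:
        raise ValidationError("window_days must be >= 1")
    first_day = int(np.floor(trace.times[0] / MINUTES_PER_DAY))
    last_day = int(np.ceil(trace.times[-1] / MINUTES_PER_DAY))
    rows = []
    for day in range(first_day, last_day):
        end = (day + 1) * MINUTES_PER_DAY
        vals = trace.window(end - window_days * MINUTES_PER_DAY, end)
        mean = float(np.mean(vals)) if vals.size else float("nan")
        rows.append((day, mean, hba1c_from_mean_glucose(mean) if vals.size else float("nan")))
    return pd.DataFrame(rows, columns=["day", "mean_glucose", "hba1c"])


def hba1c_from_measurements(measurements: pd.DataFrame, window_days: float = 1.0) -> pd.DataFrame:
    """Same daily estimate computed from raw measurements, for comparison."""
    t = measurements["time_min"].to_numpy(float)
    g = measurements["glucose_mgdl"].to_numpy(float)
    first_day = int(np.floor(t.min() / MINUTES_PER_DAY)) if t.size else 0
    last_day = int(np.ceil(t.max() / MINUTES_PER_DAY)) if t.size else 0
    rows = []
    for day in range(first_day, last_day):
        end = (day + 1) * MINUTES_PER_DAY
        mask = (t >= end - window_days * MINUTES_PER_DAY) & (t <= end)
        mean = float(np.mean(g[mask])) if mask.any() else float("nan")
        rows.append((day, mean, hba1c_from_mean_glucose(mean) if mask.any() else float("nan")))
    return pd.DataFrame(rows, columns=["day", "mean_glucose", "hba1c"])


@dataclass
class ForecastInterval:
    """A dynamic post-meal forecast range derived from the chi_0 curve."""

    meal_time: float
    kind: str            # 'sd', 'var' or 'range'
    center: float        # mg/dl
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in BAND_KINDS:
            raise ValidationError(f"kind must be one of {BAND_KINDS}")
        if self.lo > self.hi:
            raise ValidationError("interval lo must be <= hi")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, value) -> np.ndarray:
        v = np.asarray(value, dtype=float)
        return (v >= self.lo) & (v <= self.hi)


def forecast_band(trace: ForecastTrace, meal, kind: str,
                  window=(30.0, 120.0)) -> ForecastInterval | None:
    """Forecast interval from chi_0 restricted to [meal+30, meal+120] min.

    kind 'sd': mean +/- standard deviation; 'var': mean +/- variance;
    'range': [min, max].  Returns None (no-interval signal) when the window
    contains no trace samples.
    """
    if kind not in BAND_KINDS:
        raise ValidationError(f"kind must be one of {BAND_KINDS}")
    vals = trace.window(meal.time + window[0], meal.time + window[1])
    if vals.size == 0:
        return None
    center = float(np.mean(vals))
    if kind == "sd":
        half = float(np.std(vals))
        lo, hi = center - half, center + half
    elif kind == "var":
        half = float(np.var(vals))
        lo, hi = center - half, center + half
    else:
        lo, hi = float(np.min(vals)), float(np.max(vals))
    return ForecastInterval(meal.time, kind, center, lo, hi)


def pair_measurements_to_meals(measurements: pd.DataFrame, meal_times,
                               window=(30.0, 180.0)) -> dict:
    """Map each meal time to the measurement values 30-180 min after it."""
    t = measurements["time_min"].to_numpy(float)
    g = measurements["glucose_mgdl"].to_numpy(float)
    out = {}
    for tm in np.asarray(meal_times, dtype=float):
        mask = (t >= tm + window[0]) & (t <= tm + window[1])
        out[float(tm)] = g[mask]
    return out


def capture_fraction(intervals, paired_measurements: dict) -> float:
    """Percentage of paired post-meal measurements falling inside their
    meal's interval.  NaN (missing value) when no measurements are paired."""
    inside = total = 0
    for iv in intervals:
        if iv is None:
            continue
        vals = paired_measurements.get(iv.meal_time, np.array([]))
        total += len(vals)
        inside += int(np.sum(iv.contains(vals)))
    if total == 0:
        return float("nan")
    return 100.0 * inside / total
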