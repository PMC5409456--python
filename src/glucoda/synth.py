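"""Virtual-patient generator.

Simulates ground-truth glucose physiology from either mechanistic model with
known parameters, then overlays a self-monitoring schedule and glucometer
noise.  Three regimes emulate observed real-world monitoring patterns:

* ``dense``   -- one pre-meal reading and 2-3 post-meal readings per meal
  (defaults: 27 days), the upper bound of common self-monitoring;
* ``typical`` -- pre-meal and 2h-post-meal readings (defaults: 28 days), the
  standard clinical recommendation;
* ``sparse``  -- a thin Poisson stream of readings at random clock times
  (defaults: 15 days, about 1.6/day), tagged ``random``.

Because truth is known exactly, every downstream component (filter,
averaging, baseline, clinical derivations) can be tested for recovery and
calibration without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .models import Trajectory, get_model
from .timeline import PatientTimeline

__all__ = ["CohortConfig", "SimulatedPatient", "simulate_patient", "behavior_drift_scenario"]

REGIMES = ("dense", "typical", "sparse")
MEAL_CLOCK = (7.5 * 60, 12.5 * 60, 18.5 * 60)  # nominal meal times, min after midnight
GLUCOSE_FLOOR = 20.0  # mg/dl, meter reporting floor


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one virtual patient."""

    model_id: str = "ultradian"
    true_params: dict = field(default_factory=dict)
    regime: str = "typical"
    n_days: int = 28
    meals_per_day: int = 3
    carb_mean: float = 50.0        # g
    carb_sd: float = 15.0          # g
    carb_drift_per_day: float = 0.0  # g/day change of the mean (behavior drift)
    measurement_noise_sd: float = 10.0  # mg/dl
    sparse_rate_per_day: float = 1.6
    extra_post_prob: float = 0.3   # dense regime: chance of a +180 min reading
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"regime must be one of {REGIMES}")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.measurement_noise_sd < 0:
            raise ValidationError("measurement noise sd must be >= 0")


@dataclass
class SimulatedPatient:
    """A simulated timeline with its known ground truth."""

    timeline: PatientTimeline
    truth: Trajectory          # dense ground-truth glucose, 1-min grid
    true_params: dict          # constant generating parameters
    config: CohortConfig

    def truth_at(self, t) -> np.ndarray:
        """Ground-truth glucose (mg/dl) interpolated at time(s) t."""
        return np.interp(t, self.truth.times, self.truth.glucose)


def _draw_meals(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    rows = []
    for day in range(cfg.n_days):
        mean = max(cfg.carb_mean + cfg.carb_drift_per_day * day, 0.0)
        for j in range(cfg.meals_per_day):
            clock = MEAL_CLOCK[j % len(MEAL_CLOCK)] + (1440 * (j // len(MEAL_CLOCK)))
            t = day * 1440 + clock + rng.uniform(-45, 45)
            carbs = max(rng.normal(mean, cfg.carb_sd), 0.0)
            rows.append((t, carbs))
    arr = np.array(rows).reshape(-1, 2)
    return arr[np.argsort(arr[:, 0])]


def _draw_schedule(cfg: CohortConfig, meals: np.ndarray, t_end: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    times, tags = [], []
    if cfg.regime == "sparse":
        n = rng.poisson(cfg.sparse_rate_per_day * cfg.n_days)
        times = list(np.sort(rng.uniform(300.0, t_end - 30.0, size=n)))
        tags = ["random"] * len(times)
    else:
        for tm, _ in meals:
            times.append(tm - 5.0)
            tags.append("pre")
            if cfg.regime == "typical":
                posts = [120.0]
            else:  # dense
                posts = [60.0, 120.0] + ([180.0] if rng.random() < cfg.extra_post_prob else [])
            for lag in posts:
                times.append(tm + lag)
                tags.append("post")
    df = pd.DataFrame({"time_min": times, "tag": tags})
    return df[(df.time_min > 0) & (df.time_min <= t_end)].sort_values(
        "time_min", kind="stable").reset_index(drop=True)


def simulate_patient(config: CohortConfig) -> SimulatedPatient:
    """Generate one virtual patient: meals, ground truth, noisy measurements.

    Fully reproducible from ``config.seed``.  The truth trajectory is
    integrated from the model's fasting equilibrium and is independent of the
    measurement schedule (measurement is non-invasive in the simulator).
    """
    rng = np.random.default_rng(config.seed)
    model = get_model(config.model_id)
    params = model.check_params(dict(config.true_params))
    meals = _draw_meals(config, rng)
    t_end = config.n_days * 1440.0 + 240.0
    x0 = model.fasting_equilibrium(params)
    truth = model.integrate(x0, params, 0.0, t_end, meals=meals, grid_step=1.0)
    if not truth.ok:
        raise ValidationError("ground-truth integration failed for this configuration")

    sched = _draw_schedule(config, meals, truth.times[-1], rng)
    g_true = np.interp(sched["time_min"].to_numpy(float), truth.times, truth.glucose)
    noise = rng.normal(0.0, config.measurement_noise_sd, size=len(sched)) \
        if config.measurement_noise_sd > 0 else np.zeros(len(sched))
    glucose = np.maximum(g_true + noise, GLUCOSE_FLOOR)
    measurements = pd.DataFrame({
        "time_min": sched["time_min"].to_numpy(float),
        "glucose_mgdl": glucose,
        "tag": sched["tag"],
    })
    meals_df = pd.DataFrame({"time_min": meals[:, 0], "carbs_g": meals[:, 1]})
    timeline = PatientTimeline(measurements, meals_df, origin=f"synthetic:{config.model_id}")
    return SimulatedPatient(timeline, truth, params, config)


def behavior_drift_scenario(config: CohortConfig, carb_drop_fraction: float,
                            over_days: int | None = None) -> CohortConfig:
    """Variant of a config whose mean carbohydrate intake declines linearly,
    reaching the stated fractional drop by ``over_days`` (default: full span).

    Emulates a patient who gradually reduces carbohydrate consumption.
    """
    if not (0.0 <= carb_drop_fraction <= 1.0):
        raise ValidationError("carb_drop_fraction must lie in [0, 1]")
    days = over_days or config.n_days
    if days < 1:
        raise ValidationError("over_days must be >= 1")
    slope = -config.carb_mean * carb_drop_fraction / days
    return replace(config, carb_drift_per_day=slope)
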