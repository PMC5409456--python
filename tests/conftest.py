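"""Shared fixtures: small virtual patients and a linear-Gaussian test system.

The linear system implements the same model interface as the mechanistic
models (flow / observe / fasting_equilibrium / ...) so the filter can be
checked against an exact Kalman filter oracle.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from glucoda.models import _ModelBase
from glucoda.synth import CohortConfig, simulate_patient
from glucoda.timeline import PatientTimeline


class LinearModel(_ModelBase):
    """dx/dt = A x, observed through H x; exact flow via the matrix exponential."""

    model_id = "linear2"
    state_names = ("x1", "x2")
    estimated = ("a",)

    def __init__(self, A=None, H=(1.0, 0.0)):
        self.A = np.array(A if A is not None else [[-0.002, 0.001], [0.0, -0.003]])
        self.H = np.asarray(H, dtype=float)

    def default_params(self):
        return {"a": 1.0}

    def flow(self, states, params, t0, t1, meals=None):
        arr = np.atleast_2d(np.asarray(states, dtype=float))
        out = arr @ expm(self.A * (t1 - t0)).T
        return out if np.asarray(states).ndim == 2 else out[0]

    def observe(self, states, params):
        return np.asarray(states, dtype=float) @ self.H

    def integrate(self, state, params, t0, t1, meals=None, grid_step=1.0):
        from glucoda.models import Trajectory
        n = max(int(np.floor((t1 - t0) / grid_step)), 0)
        times = t0 + grid_step * np.arange(n + 1)
        if times[-1] < t1 - 1e-9:
            times = np.append(times, t1)
        states = np.array([self.flow(state, params, t0, t) for t in times])
        return Trajectory(times, states, self.observe(states, params))

    def set_glucose(self, state, glucose_mgdl, params):
        out = np.array(state, dtype=float)
        out[0] = glucose_mgdl
        return out

    def fasting_equilibrium(self, params=None):
        return np.array([100.0, 50.0])

    def check_params(self, params):
        full = self.default_params()
        full.update(params or {})
        return full


@pytest.fixture(scope="session")
def linear_model():
    return LinearModel()


@pytest.fixture(scope="session")
def typical_patient():
    """A 10-day typical-regime ultradian virtual patient (noise sd 10)."""
    return simulate_patient(CohortConfig(model_id="ultradian", regime="typical",
                                         n_days=10, seed=11))


@pytest.fixture(scope="session")
def noiseless_patient():
    """A short noiseless patient: measurements equal ground truth exactly."""
    return simulate_patient(CohortConfig(model_id="ultradian", regime="dense",
                                         n_days=5, measurement_noise_sd=0.0, seed=7))


def make_timeline(times, glucose, meal_times=(), carbs=(), tags=None):
    """Hand-build a PatientTimeline from plain sequences."""
    tags = tags if tags is not None else [""] * len(times)
    meas = pd.DataFrame({"time_min": list(times), "glucose_mgdl": list(glucose),
                         "tag": list(tags)})
    meals = pd.DataFrame({"time_min": list(meal_times), "carbs_g": list(carbs)})
    return PatientTimeline(meas, meals)


@pytest.fixture
def tiny_timeline():
    return make_timeline([10, 130, 250], [95, 140, 110],
                         meal_times=[15], carbs=[60], tags=["pre", "post", ""])
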