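"""Unscented-filter contracts: sigma placement, positivity rule, prediction,
correction, the forgetting-factor parameter filter, and oracle equivalence
with an exact Kalman filter on a linear-Gaussian system."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from glucoda.exceptions import NumericError, ValidationError
from glucoda.timeline import PatientTimeline
from glucoda.ukf import (
    GaussianBelief,
    NoiseConfig,
    SigmaScaling,
    enforce_positivity,
    make_sigma_points,
    param_step,
    run_filter,
    state_predict,
    state_update,
)
from conftest import make_timeline


class TestSigmaPoints:
    def test_scalar_closed_form_placement(self):
        # n=1, mean 0, cov 1, (alpha=1, beta=0, kappa=2): lambda=2, spread sqrt(3)
        belief = GaussianBelief(np.array([0.0]), np.array([[1.0]]))
        sp = make_sigma_points(belief, SigmaScaling(alpha=1.0, beta=0.0, kappa=2.0))
        assert np.allclose(np.sort(sp.points.ravel()), [-np.sqrt(3), 0.0, np.sqrt(3)])

    def test_mean_weights_sum_to_one(self):
        belief = GaussianBelief(np.arange(1.0, 5.0), np.diag([1.0, 2.0, 3.0, 4.0]))
        sp = make_sigma_points(belief)
        assert sp.mean_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_cov_collapses_to_mean(self):
        belief = GaussianBelief(np.array([3.0, 4.0]), np.zeros((2, 2)))
        sp = make_sigma_points(belief)
        assert np.allclose(sp.points, belief.mean, atol=2e-5)

    def test_points_symmetric_about_mean(self):
        belief = GaussianBelief(np.array([10.0, -2.0]), np.array([[4.0, 1.0], [1.0, 2.0]]))
        sp = make_sigma_points(belief)
        n = belief.dim
        assert np.allclose(sp.points[1:1 + n] + sp.points[1 + n:], 2 * belief.mean)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            GaussianBelief(np.array([1.0, 2.0]), np.eye(3))

    def test_sigma_statistics_reproduce_belief(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        mean = rng.normal(size=3)
        sp = make_sigma_points(GaussianBelief(mean, cov))
        m = sp.mean_weights @ sp.points
        dev = sp.points - m
        c = (dev * sp.cov_weights[:, None]).T @ dev
        assert np.allclose(m, mean, atol=1e-8)
        assert np.allclose(c, cov, atol=1e-7)


class TestPositivityConstraint:
    def test_negative_replaced_by_smallest_positive(self):
        sp = make_sigma_points(GaussianBelief(np.array([0.0]), np.array([[1.0]])))
        sp.points[:, 0] = [-1.0, 2.0, 3.0]
        out = enforce_positivity(sp)
        assert list(out.points[:, 0]) == [2.0, 2.0, 3.0]

    def test_all_nonpositive_replaced_by_zero(self):
        sp = make_sigma_points(GaussianBelief(np.array([0.0]), np.array([[1.0]])))
        sp.points[:, 0] = [-1.0, -5.0, 0.0]
        out = enforce_positivity(sp)
        assert list(out.points[:, 0]) == [0.0, 0.0, 0.0]

    def test_all_positive_unchanged(self):
        sp = make_sigma_points(GaussianBelief(np.array([5.0, 2.0]), np.eye(2) * 0.01))
        out = enforce_positivity(sp)
        assert np.array_equal(out.points, sp.points)

    def test_per_coordinate_independence(self):
        sp = make_sigma_points(GaussianBelief(np.zeros(2), np.eye(2)))
        sp.points[:] = [[-1.0, 4.0], [2.0, -3.0], [3.0, 5.0], [1.0, 1.0], [0.5, 2.0]]
        out = enforce_positivity(sp)
        assert list(out.points[:, 0]) == [0.5, 2.0, 3.0, 1.0, 0.5]
        assert list(out.points[:, 1]) == [4.0, 1.0, 5.0, 1.0, 2.0]


class TestStatePredictUpdate:
    def test_linear_gaussian_propagation_matches_closed_form(self, linear_model):
        A = linear_model.A
        mean0 = np.array([100.0, 50.0])
        cov0 = np.array([[25.0, 5.0], [5.0, 16.0]])
        belief = GaussianBelief(mean0, cov0, 0.0)
        noise = NoiseConfig(state_augmentation_fraction=0.0)
        pred = state_predict(linear_model, belief, {}, 30.0, None, noise)
        Phi = expm(A * 30.0)
        assert np.allclose(pred.belief.mean, Phi @ mean0, atol=1e-6)
        assert np.allclose(pred.belief.cov, Phi @ cov0 @ Phi.T, atol=1e-6)

    def test_zero_span_prediction_is_inflated_prior(self, linear_model):
        belief = GaussianBelief(np.array([100.0, 50.0]), np.diag([4.0, 9.0]), 10.0)
        noise = NoiseConfig(state_augmentation_fraction=0.2)
        pred = state_predict(linear_model, belief, {}, 10.0, None, noise)
        assert np.allclose(pred.belief.mean, belief.mean, atol=1e-8)
        assert np.allclose(pred.belief.cov, belief.cov * 1.2, atol=1e-6)
        assert pred.y_hat == pytest.approx(100.0, abs=1e-8)

    def test_zero_cov_prior_predicts_deterministically(self, linear_model):
        belief = GaussianBelief(np.array([80.0, 10.0]), np.zeros((2, 2)), 0.0)
        pred = state_predict(linear_model, belief, {}, 60.0, None,
                             NoiseConfig(state_augmentation_fraction=0.0))
        exact = linear_model.flow(belief.mean, {}, 0.0, 60.0)
        assert np.allclose(pred.belief.mean, exact, atol=1e-4)

    def test_infinite_R_limit_keeps_prediction(self, linear_model):
        belief = GaussianBelief(np.array([100.0, 50.0]), np.eye(2) * 9.0, 0.0)
        pred = state_predict(linear_model, belief, {}, 30.0, None, NoiseConfig())
        corrected = state_update(pred, y=150.0, R=1e12)
        assert np.allclose(corrected.mean, pred.belief.mean, atol=1e-6)

    def test_equal_weight_fusion_is_midpoint(self):
        # scalar fully-observed state: R equal to prediction variance
        class Scalar1D:
            model_id = "scalar"
            estimated = ()

            def flow(self, states, params, t0, t1, meals=None):
                return np.atleast_2d(states).copy()

            def observe(self, states, params):
                return np.asarray(states)[..., 0]

        belief = GaussianBelief(np.array([100.0]), np.array([[50.0]]), 0.0)
        pred = state_predict(Scalar1D(), belief, {}, 0.0, None,
                             NoiseConfig(state_augmentation_fraction=0.0))
        corrected = state_update(pred, y=120.0, R=pred.obs_var)
        assert corrected.mean[0] == pytest.approx(110.0, abs=1e-6)

    def test_covariance_stays_psd_through_updates(self, linear_model):
        rng = np.random.default_rng(0)
        belief = GaussianBelief(np.array([100.0, 50.0]), np.eye(2) * 100.0, 0.0)
        for k in range(30):
            pred = state_predict(linear_model, belief, {}, belief.time + 20.0, None, NoiseConfig())
            belief = state_update(pred, y=90 + 10 * rng.normal(), R=225.0)
            eigs = np.linalg.eigvalsh(belief.cov)
            assert eigs.min() >= -1e-8
            assert np.allclose(belief.cov, belief.cov.T, atol=1e-10)


def exact_kalman(A, H, R, times, ys, mean0, cov0):
    """Textbook continuous-discrete Kalman filter (zero process noise)."""
    means = []
    mean, cov, t = mean0.copy(), cov0.copy(), times[0] * 0.0
    H = np.asarray(H, dtype=float)
    for tk, yk in zip(times, ys):
        Phi = expm(A * (tk - t))
        mean = Phi @ mean
        cov = Phi @ cov @ Phi.T
        S = H @ cov @ H + R
        K = cov @ H / S
        mean = mean + K * (yk - H @ mean)
        cov = cov - np.outer(K, K) * S
        means.append(mean.copy())
        t = tk
    return np.array(means)


class TestKalmanOracle:
    def test_state_mode_matches_exact_kf_over_50_steps(self, linear_model):
        rng = np.random.default_rng(42)
        times = np.cumsum(rng.uniform(4.0, 10.0, size=50))
        truth = np.array([200.0, 100.0])
        ys = []
        for tk in times:
            x = linear_model.flow(truth, {}, 0.0, tk)
            ys.append(x[0] + rng.normal(0, 3))
        timeline = make_timeline(times, ys)
        noise = NoiseConfig(R=25.0, state_augmentation_fraction=0.0)
        run = run_filter(timeline, linear_model, mode="state", noise=noise,
                         init_cov_fraction=0.1)
        mean0 = linear_model.fasting_equilibrium()
        cov0 = np.diag(np.maximum((0.1 * mean0) ** 2, 1.0))
        oracle = exact_kalman(linear_model.A, linear_model.H, 25.0, times, ys, mean0, cov0)
        assert np.max(np.abs(run.state_means - oracle)) < 1e-6


class TestParamStep:
    def test_zero_innovation_keeps_mean(self, linear_model):
        # y chosen equal to every sigma prediction: flow is parameter-free here
        state = GaussianBelief(np.array([100.0, 50.0]), np.zeros((2, 2)), 0.0)
        params = GaussianBelief(np.array([1.0]), np.array([[0.0]]), 0.0)
        y = float(linear_model.observe(linear_model.flow(state.mean, {}, 0.0, 30.0), {}))
        out = param_step(linear_model, params, state, y, 30.0, None,
                         NoiseConfig(forgetting_factor=1.0), {"a": 1.0})
        assert out.mean[0] == pytest.approx(1.0, abs=1e-9)

    def test_forgetting_factor_inflates_covariance(self, linear_model):
        # parameter does not influence the flow -> zero gain; covariance must
        # grow by exactly 1/lambda per step
        state = GaussianBelief(np.array([100.0, 50.0]), np.zeros((2, 2)), 0.0)
        params = GaussianBelief(np.array([1.0]), np.array([[0.04]]), 0.0)
        y = float(linear_model.observe(linear_model.flow(state.mean, {}, 0.0, 30.0), {}))
        out = param_step(linear_model, params, state, y, 30.0, None,
                         NoiseConfig(forgetting_factor=0.98), {"a": 1.0})
        assert out.cov[0, 0] == pytest.approx(0.04 / 0.98, rel=1e-6)


class TestRunFilter:
    def test_empty_timeline_rejected(self):
        empty = pd.DataFrame({"time_min": [], "glucose_mgdl": [], "tag": []})
        meals = pd.DataFrame({"time_min": [], "carbs_g": []})
        with pytest.raises(ValidationError):
            run_filter(PatientTimeline(empty, meals), "ultradian")

    def test_single_measurement_forecast_from_initial_belief(self):
        timeline = make_timeline([60.0], [110.0])
        run = run_filter(timeline, "ultradian", mode="state")
        assert len(run.times) == 1
        assert np.isfinite(run.forecasts[0])
        # initial belief sits at fasting equilibrium; forecast must be near it
        assert 60 < run.forecasts[0] < 200

    def test_rerun_is_bit_identical(self, tiny_timeline):
        r1 = run_filter(tiny_timeline, "ultradian", mode="dual", seed=1)
        r2 = run_filter(tiny_timeline, "ultradian", mode="dual", seed=1)
        assert np.array_equal(r1.forecasts, r2.forecasts)
        assert np.array_equal(r1.state_means, r2.state_means)
        assert np.array_equal(r1.param_means, r2.param_means)
        assert np.array_equal(r1.chi0_glucose, r2.chi0_glucose)

    def test_forecasts_are_strictly_causal(self, tiny_timeline):
        full = run_filter(tiny_timeline, "ultradian", mode="dual")
        perturbed = make_timeline([10, 130, 250], [95, 140, 250],
                                  meal_times=[15], carbs=[60])
        other = run_filter(perturbed, "ultradian", mode="dual")
        # records before the perturbed measurement are unchanged
        assert np.allclose(full.forecasts[:2], other.forecasts[:2])
        assert np.allclose(full.state_means[0], other.state_means[0])

    def test_chi0_trace_covers_span_and_is_finite(self, tiny_timeline):
        run = run_filter(tiny_timeline, "ultradian", mode="state")
        assert run.chi0_times[0] <= 10.0
        assert run.chi0_times[-1] >= 250.0
        assert np.all(np.isfinite(run.chi0_glucose))
        assert np.all(np.diff(run.chi0_times) > 0)

    def test_mode_none_resets_to_last_measurement(self, tiny_timeline):
        run = run_filter(tiny_timeline, "ultradian", mode="none")
        assert len(run.times) == 3
        assert np.all(np.isfinite(run.forecasts))

    def test_posterior_covariances_all_psd(self, typical_patient):
        sub = typical_patient.timeline.measurements.iloc[:12]
        timeline = PatientTimeline(sub, typical_patient.timeline.meals)
        run = run_filter(timeline, "ultradian", mode="dual")
        assert run.n_failures == 0
        assert np.all(np.isfinite(run.state_means))
        assert np.all(run.param_means > 0)
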