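"""Mechanistic-model contracts: equilibria, meal responses, forcing, integration."""

import numpy as np
import pytest
from scipy.integrate import quad

from glucoda.exceptions import ConfigurationError, ValidationError
from glucoda.models import MealRecord, get_model, nutrition_forcing

MODELS = ["ultradian", "meal"]


@pytest.fixture(scope="module")
def equilibria():
    out = {}
    for mid in MODELS:
        model = get_model(mid)
        params = model.check_params({})
        out[mid] = (model, params, model.fasting_equilibrium())
    return out


class TestRhsContracts:
    @pytest.mark.parametrize("model_id", MODELS)
    def test_equilibrium_is_a_fixed_point(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        deriv = model.rhs(0.0, eq[None, :], params, np.empty((0, 2)))
        assert np.max(np.abs(deriv)) < 1e-6

    @pytest.mark.parametrize("model_id", MODELS)
    def test_equilibrium_glucose_physiologic(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        g = model.observe(eq, params)
        assert 60.0 < g < 200.0

    @pytest.mark.parametrize("model_id", MODELS)
    def test_equilibrium_idempotent(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        again = model.fasting_equilibrium()
        assert np.allclose(eq, again, rtol=1e-9, atol=1e-9)

    def test_ultradian_exchange_vanishes_at_equal_concentration(self, equilibria):
        model, params, _ = equilibria["ultradian"]
        # Ip/Vp == Ii/Vi -> E does not enter dIp/dt
        state = np.array([[30.0, 110.0, 10000.0, 30.0, 30.0, 30.0]])
        base = model.rhs(0.0, state, params, np.empty((0, 2)))[0, 0]
        doubled = model.rhs(0.0, state, {**params, "E": 2 * params["E"]}, np.empty((0, 2)))[0, 0]
        assert base == pytest.approx(doubled, abs=1e-10)

    def test_ultradian_nutrition_adds_exactly_to_dG(self, equilibria):
        model, params, eq = equilibria["ultradian"]
        meals = np.array([[0.0, 60.0]])
        t = 30.0
        r = nutrition_forcing(meals, t, params["k_decay"], params["carb_to_mg"])
        d0 = model.rhs(t, eq[None, :], params, np.empty((0, 2)))[0, 2]
        d1 = model.rhs(t, eq[None, :], params, meals)[0, 2]
        assert d1 - d0 == pytest.approx(r, rel=1e-12)
        assert r > 0

    def test_meal_gi_compartments_stay_empty_without_food(self, equilibria):
        model, params, eq = equilibria["meal"]
        traj = model.integrate(eq, params, 0, 720, meals=None, grid_step=5.0)
        assert np.max(np.abs(traj.states[:, 4:7])) == 0.0

    def test_meal_gut_peaks_after_stomach(self, equilibria):
        model, params, eq = equilibria["meal"]
        traj = model.integrate(eq, params, 0, 420, meals=np.array([[0.0, 50.0]]))
        stomach = traj.states[:, 4] + traj.states[:, 5]
        gut = traj.states[:, 6]
        assert traj.times[np.argmax(gut)] > traj.times[np.argmax(stomach)]

    def test_missing_parameter_name_rejected(self):
        model = get_model("ultradian")
        with pytest.raises(ConfigurationError):
            model.check_params({"not_a_param": 1.0})

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ConfigurationError):
            get_model("bergman")


class TestNutritionForcing:
    def test_no_meals_zero(self):
        assert nutrition_forcing([], 123.0) == 0.0

    def test_causality_zero_at_meal_time(self):
        meals = [MealRecord(60.0, 60.0)]
        assert nutrition_forcing(meals, 60.0) == 0.0
        assert nutrition_forcing(meals, 59.0) == 0.0
        assert nutrition_forcing(meals, 61.0) > 0.0

    def test_kernel_integrates_to_carbs_times_conversion(self):
        k = 1.0 / 120.0
        meals = [MealRecord(0.0, 60.0)]
        total, _ = quad(lambda t: nutrition_forcing(meals, t, k), 0, 1440, limit=200)
        assert total == pytest.approx(60.0 * 1000.0, rel=1e-3)

    def test_negative_carbs_rejected(self):
        with pytest.raises(ValidationError):
            nutrition_forcing([MealRecord(0.0, -5.0)], 10.0)

    def test_overlapping_meals_superpose(self):
        a = nutrition_forcing([MealRecord(0.0, 30.0)], 50.0)
        b = nutrition_forcing([MealRecord(10.0, 40.0)], 50.0)
        both = nutrition_forcing([MealRecord(0.0, 30.0), MealRecord(10.0, 40.0)], 50.0)
        assert both == pytest.approx(a + b, rel=1e-12)


class TestIntegration:
    @pytest.mark.parametrize("model_id", MODELS)
    def test_zero_span_returns_initial_state(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        traj = model.integrate(eq, params, 100.0, 100.0)
        assert len(traj.times) == 1
        assert np.allclose(traj.states[0], eq)

    @pytest.mark.parametrize("model_id", MODELS)
    def test_first_point_equals_input_state(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        x0 = eq * 1.05
        traj = model.integrate(x0, params, 0, 60)
        assert np.allclose(traj.states[0], x0)

    @pytest.mark.parametrize("model_id", MODELS)
    def test_equilibrium_stays_put_48h(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        traj = model.integrate(eq, params, 0, 2880, grid_step=10.0)
        drift = np.max(np.abs(traj.glucose - traj.glucose[0])) / traj.glucose[0]
        assert drift < 0.005

    @pytest.mark.parametrize("model_id", MODELS)
    def test_bolus_raises_glucose(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        fed = model.integrate(eq, params, 0, 180, meals=np.array([[10.0, 60.0]]))
        fasted = model.integrate(eq, params, 0, 180)
        assert fed.glucose.max() > fasted.glucose.max() + 5.0

    @pytest.mark.parametrize("model_id", MODELS)
    def test_peak_monotone_in_dose(self, equilibria, model_id):
        model, params, eq = equilibria[model_id]
        peaks = [model.integrate(eq, params, 0, 240,
                                 meals=np.array([[10.0, d]])).glucose.max()
                 for d in (30.0, 60.0, 90.0)]
        assert peaks[0] <= peaks[1] <= peaks[2]

    def test_grid_refinement_converges(self, equilibria):
        model, params, eq = equilibria["ultradian"]
        meals = np.array([[30.0, 50.0]])
        g1 = model.integrate(eq, params, 0, 240, meals=meals, grid_step=1.0).glucose[-1]
        g2 = model.integrate(eq, params, 0, 240, meals=meals, grid_step=0.5).glucose[-1]
        assert abs(g1 - g2) / g1 < 1e-6

    def test_estimated_parameter_sensitivity_finite_and_sign_stable(self, equilibria):
        model, params, eq = equilibria["ultradian"]
        meals = np.array([[0.0, 60.0]])

        def g2h(scale):
            p = dict(params)
            p["E"] = params["E"] * scale
            x0 = model.fasting_equilibrium(p)
            return model.integrate(x0, p, 0, 120, meals=meals).glucose[-1]

        d1 = (g2h(1.01) - g2h(1.0)) / 0.01
        d2 = (g2h(1.02) - g2h(1.01)) / 0.01
        assert np.isfinite(d1) and np.isfinite(d2)
        assert np.sign(d1) == np.sign(d2)
        assert abs(d1 - d2) < 0.5 * max(abs(d1), abs(d2)) + 1e-6

    def test_batched_flow_matches_individual(self, equilibria):
        model, params, eq = equilibria["ultradian"]
        states = np.vstack([eq * s for s in (0.95, 1.0, 1.05)])
        meals = np.array([[20.0, 40.0]])
        batch = model.flow(states, params, 0, 120, meals)
        for i in range(3):
            single = model.flow(states[i], params, 0, 120, meals)
            # stacked rows share adaptive step control, so agreement is at
            # the solver-tolerance scale, not bitwise
            assert np.allclose(batch[i], single, rtol=1e-3, atol=1e-3)
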