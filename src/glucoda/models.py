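"""Mechanistic glucose-insulin ODE models and their flow-map integrators.

Two models are provided, chosen to span a range of mechanistic complexity:

* :class:`UltradianModel` -- the 6-state ultradian oscillator of Sturis and
  colleagues.  Plasma and interstitial insulin exchange across a membrane,
  glucose is produced by the liver through a three-stage delay chain and
  consumed by insulin-independent and insulin-dependent utilization.
  Nutrition enters as an exogenous glucose-appearance rate built from meal
  records with a single-exponential absorption kernel.

* :class:`MealModel` -- the 12-state meal-simulation model of Dalla Man and
  colleagues, which adds explicit digestive mechanics: a two-compartment
  stomach and a gut compartment feed a glucose rate of appearance, glucose
  distributes between plasma and tissue, and insulin secretion/action are
  carried by auxiliary delay states.  Meal carbohydrate is injected as an
  impulse into the solid-stomach compartment.

Both expose the same interface used by the filtering machinery: a vectorized
right-hand side, a batched flow map ``flow`` (many initial states propagated
in one ODE solve), a dense-output ``integrate``, a scalar glucose observation
in mg/dl, and a fasting equilibrium used for initialization.

Units: time in minutes, carbohydrate in grams, reported glucose in mg/dl.
Internal glucose variables are masses (mg for the ultradian model, mg/kg for
the meal model) converted through distribution volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .exceptions import ConfigurationError, NumericError, ValidationError

__all__ = [
    "MealRecord",
    "Trajectory",
    "UltradianModel",
    "MealModel",
    "get_model",
    "MODELS",
    "nutrition_forcing",
]

# grams of carbohydrate -> mg of glucose appearing in plasma
CARB_TO_MG = 1000.0


@dataclass(frozen=True)
class MealRecord:
    """One meal: minutes from timeline origin and grams of carbohydrate."""

    time: float
    carbs: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time):
            raise ValidationError("meal time must be finite")
        if self.carbs < 0:
            raise ValidationError("meal carbs must be >= 0")


def _meal_array(meals) -> np.ndarray:
    """Normalize a meal sequence to a time-sorted (k, 2) float array."""
    if meals is None:
        return np.empty((0, 2))
    if isinstance(meals, np.ndarray):
        arr = np.asarray(meals, dtype=float).reshape(-1, 2)
    else:
        arr = np.array([(m.time, m.carbs) for m in meals], dtype=float).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] < 0):
        raise ValidationError("meal carbs must be >= 0")
    return arr[np.argsort(arr[:, 0], kind="stable")] if arr.size else arr


def nutrition_forcing(meals, t, decay_rate: float = 1.0 / 120.0, carb_to_mg: float = CARB_TO_MG):
    """Exogenous glucose appearance rate (mg/min) at time ``t``.

    Each past meal contributes ``carbs * carb_to_mg * k * exp(-k (t - t_meal))``
    so that the appearance integrated over all time after the meal equals the
    meal's carbohydrate mass.  Causal: meals at or after ``t`` contribute 0.
    Overlapping meals superpose additively.
    """
    arr = meals if isinstance(meals, np.ndarray) else _meal_array(meals)
    arr = arr.reshape(-1, 2)
    t = np.asarray(t, dtype=float)
    if arr.size == 0:
        return np.zeros(t.shape) if t.shape else 0.0
    dt = t[..., None] - arr[:, 0]
    amp = arr[:, 1] * carb_to_mg * decay_rate
    contrib = np.where(dt > 0, amp * np.exp(-decay_rate * np.maximum(dt, 0.0)), 0.0)
    out = contrib.sum(axis=-1)
    return out if out.shape else float(out)


@dataclass
class Trajectory:
    """Dense model trajectory on a regular time grid.

    ``ok`` is False when the integrator failed; callers in the online filter
    must treat that as a forecast failure, not a crash.
    """

    times: np.ndarray
    states: np.ndarray  # (len(times), dim)
    glucose: np.ndarray  # mg/dl at each grid time
    ok: bool = True
    message: str = ""


class _ModelBase:
    """Shared flow-map / integration plumbing for both mechanistic models."""

    model_id: str = ""
    state_names: tuple = ()
    estimated: tuple = ()

    @property
    def dim(self) -> int:
        return len(self.state_names)

    # -- interface implemented by subclasses ---------------------------------
    def default_params(self) -> dict:
        raise NotImplementedError

    def rhs(self, t, states, params, meals):  # (m, dim) -> (m, dim)
        raise NotImplementedError

    def observe(self, states, params):
        """Plasma glucose concentration in mg/dl for states of shape (..., dim)."""
        raise NotImplementedError

    def set_glucose(self, state, glucose_mgdl, params):
        """Return a copy of ``state`` with plasma glucose set to ``glucose_mgdl``."""
        raise NotImplementedError

    def _segment_times(self, t0, t1, meals):
        """Breakpoints in (t0, t1) where the dynamics must be restarted."""
        return []

    def _apply_meal_impulse(self, states, meal_time, meals):
        return states

    # -- shared machinery ----------------------------------------------------
    def check_params(self, params: dict) -> dict:
        """Merge overrides into the full parameter set and validate.

        Values may be scalars or per-batch-row arrays (the parameter filter
        propagates one parameter sigma point per state row in a single solve).
        """
        full = self.default_params()
        unknown = set(params) - set(full)
        if unknown:
            raise ConfigurationError(f"unknown parameter(s) for {self.model_id}: {sorted(unknown)}")
        full.update(params)
        for name, value in full.items():
            value = np.asarray(value, dtype=float)
            if not np.all(np.isfinite(value)):
                raise ConfigurationError(f"parameter {name} is not finite")
            if np.any(value < 0):
                raise ConfigurationError(f"parameter {name} must be >= 0")
            full[name] = value if value.ndim else float(value)
        return full

    def flow(self, states, params, t0, t1, meals=None):
        """Propagate a batch of states from t0 to t1 in a single stacked solve.

        ``states`` has shape (m, dim) (or (dim,) for a single state).  Rows
        whose propagation fails are returned as NaN; the caller decides how to
        handle partial failure.
        """
        params = self.check_params(dict(params or {}))
        arr = np.atleast_2d(np.asarray(states, dtype=float))
        if arr.shape[1] != self.dim:
            raise ValidationError(f"state dimension {arr.shape[1]} != {self.dim} for {self.model_id}")
        if not np.all(np.isfinite(arr)):
            raise NumericError("non-finite state passed to flow")
        if t1 < t0:
            raise ValidationError("t1 must be >= t0")
        meals = _meal_array(meals)
        if t1 == t0:
            return arr if np.asarray(states).ndim == 2 else arr[0]

        out = self._flow_batch(arr, params, t0, t1, meals)
        if np.any(~np.isfinite(out)):
            # retry failed rows individually so one bad sigma point does not
            # sink the whole prediction step
            for i in range(arr.shape[0]):
                if not np.all(np.isfinite(out[i])):
                    p_i = {k: (float(v[i]) if isinstance(v, np.ndarray) and v.ndim else v)
                           for k, v in params.items()}
                    out[i] = self._flow_batch(arr[i : i + 1], p_i, t0, t1, meals)[0]
        return out if np.asarray(states).ndim == 2 else out[0]

    def _flow_batch(self, arr, params, t0, t1, meals):
        m = arr.shape[0]
        breaks = [t0] + self._segment_times(t0, t1, meals) + [t1]
        cur = arr.copy()
        for a, b in zip(breaks[:-1], breaks[1:]):
            cur = self._apply_meal_impulse(cur, a, meals)
            if b == a:
                continue

            def f(t, y):
                return self.rhs(t, y.reshape(m, self.dim), params, meals).ravel()

            try:
                sol = solve_ivp(
                    f, (a, b), cur.ravel(), method="RK45", rtol=1e-6, atol=1e-6,
                    max_step=max((b - a) / 2.0, 5.0),
                )
            except (FloatingPointError, ValueError):
                return np.full_like(arr, np.nan)
            if not sol.success:
                return np.full_like(arr, np.nan)
            cur = sol.y[:, -1].reshape(m, self.dim)
        return cur

    def integrate(self, state, params, t0, t1, meals=None, grid_step: float = 1.0) -> Trajectory:
        """Dense-output IVP solve on a regular grid (default 1 min).

        The first grid point equals the input state.  Integration failure is
        reported through ``Trajectory.ok`` rather than raised, because the
        online filter must survive it.
        """
        params = self.check_params(dict(params or {}))
        y0 = np.asarray(state, dtype=float).ravel()
        if y0.size != self.dim:
            raise ValidationError(f"state dimension {y0.size} != {self.dim}")
        if t1 < t0:
            raise ValidationError("t1 must be >= t0")
        meals = _meal_array(meals)
        if t1 == t0:
            states = y0[None, :]
            return Trajectory(np.array([t0]), states, self.observe(states, params))

        n = int(np.floor((t1 - t0) / grid_step))
        times = t0 + grid_step * np.arange(n + 1)
        if times[-1] < t1 - 1e-9:
            times = np.append(times, t1)
        breaks = [t0] + self._segment_times(t0, t1, meals) + [t1]
        states = np.empty((len(times), self.dim))
        states[0] = y0
        cur = y0[None, :].copy()
        filled = 1
        for a, b in zip(breaks[:-1], breaks[1:]):
            cur = self._apply_meal_impulse(cur, a, meals)
            if b == a:
                continue
            seg_mask = (times > a + 1e-12) & (times <= b + 1e-12)
            t_eval = times[seg_mask]

            def f(t, y):
                return self.rhs(t, y.reshape(1, self.dim), params, meals).ravel()

            try:
                sol = solve_ivp(
                    f, (a, b), cur.ravel(), method="RK45", rtol=1e-6, atol=1e-6,
                    t_eval=np.unique(np.concatenate([t_eval, [b]])),
                    max_step=max((b - a) / 2.0, 5.0),
                )
            except (FloatingPointError, ValueError):
                sol = None
            if sol is None or not sol.success or np.any(~np.isfinite(sol.y)):
                return Trajectory(times[:filled], states[:filled],
                                  self.observe(states[:filled], params),
                                  ok=False, message="integrator failure")
            take = np.isin(sol.t, t_eval, assume_unique=False)
            states[filled : filled + int(take.sum())] = sol.y[:, take].T
            filled += int(take.sum())
            cur = sol.y[:, -1][None, :]
        states = states[:filled]
        return Trajectory(times[:filled], states, self.observe(states, params))

    def fasting_equilibrium(self, params=None) -> np.ndarray:
        """State at which the meal-free right-hand side vanishes.

        Located by root-finding from a physiologic initial guess; if the
        root-finder fails, falls back to the terminal state of a long
        meal-free integration.
        """
        params = self.check_params(dict(params or {}))
        guess = self._equilibrium_guess(params)

        def f(y):
            return self.rhs(0.0, y[None, :], params, np.empty((0, 2)))[0]

        sol = root(f, guess, method="hybr", tol=1e-12)
        if sol.success and np.all(sol.x > -1e-8) and np.max(np.abs(f(sol.x))) < 1e-6:
            return np.maximum(sol.x, 0.0)
        traj = self.integrate(guess, params, 0.0, 5000.0, meals=None, grid_step=10.0)
        sol2 = root(f, traj.states[-1], method="hybr", tol=1e-12)
        if sol2.success and np.all(sol2.x >= -1e-8):
            return np.maximum(sol2.x, 0.0)
        return np.maximum(traj.states[-1], 0.0)

    def _equilibrium_guess(self, params):
        raise NotImplementedError


class UltradianModel(_ModelBase):
    """Six-state ultradian glucose-insulin oscillator.

    States: plasma insulin Ip (mU), interstitial insulin Ii (mU), glucose
    mass G (mg), and the three-stage hepatic delay chain h1, h2, h3 (mU).
    Nutrition enters ``dG/dt`` as an exogenous appearance rate from
    :func:`nutrition_forcing`.
    """

    model_id = "ultradian"
    state_names = ("Ip", "Ii", "G", "h1", "h2", "h3")
    # insulin exchange rate, plasma insulin volume, plasma insulin time constant
    estimated = ("E", "Vp", "tp")

    def default_params(self) -> dict:
        return {
            "Vp": 3.0,       # plasma insulin distribution volume (l)
            "Vi": 11.0,      # interstitial insulin volume (l)
            "Vg": 10.0,      # glucose distribution volume (l)
            "E": 0.2,        # insulin exchange rate plasma<->interstitial (l/min)
            "tp": 6.0,       # plasma insulin degradation time constant (min)
            "ti": 100.0,     # interstitial insulin degradation time constant (min)
            "td": 36.0,      # total hepatic delay (min, three stages)
            "Rm": 210.0,     # maximal insulin secretion rate (mU/min)
            "a1": 300.0,     # secretion sigmoid width (mg/l)
            "C1": 2000.0,    # secretion sigmoid center (mg/l)
            "C2": 144.0,     # insulin-independent utilization scale (mg/l)
            "C3": 1000.0,    # insulin-dependent utilization scale (mg/l)
            "C4": 80.0,      # interstitial insulin scale (mU/l)
            "C5": 26.0,      # hepatic production insulin scale (mU/l)
            "Ub": 72.0,      # max insulin-independent utilization (mg/min)
            "U0": 40.0,      # insulin-dependent utilization floor (mg/min)
            "Um": 940.0,     # insulin-dependent utilization ceiling (mg/min)
            "Rg": 180.0,     # maximal hepatic glucose production (mg/min)
            "alpha_g": 7.5,  # hepatic production sigmoid steepness
            "beta_u": 1.77,  # utilization Hill exponent
            "k_decay": 1.0 / 120.0,  # meal absorption kernel decay (1/min)
            "carb_to_mg": CARB_TO_MG,
        }

    def rhs(self, t, states, params, meals):
        p = params
        Ip, Ii, G, h1, h2, h3 = (states[:, i] for i in range(6))
        G = np.maximum(G, 0.0)
        f1 = p["Rm"] / (1.0 + np.exp(np.clip((p["C1"] - G / p["Vg"]) / p["a1"], -60.0, 60.0)))
        f2 = p["Ub"] * (1.0 - np.exp(-G / (p["C2"] * p["Vg"])))
        kappa = (1.0 / p["Vi"] + 1.0 / (p["E"] * p["ti"])) / p["C4"]
        with np.errstate(over="ignore"):
            f3 = (p["U0"] + p["Um"] / (1.0 + np.power(np.maximum(kappa * Ii, 1e-12), -p["beta_u"]))) / (
                p["C3"] * p["Vg"]
            )
        f4 = p["Rg"] / (1.0 + np.exp(np.clip(p["alpha_g"] * (h3 / (p["C5"] * p["Vp"]) - 1.0), -60.0, 60.0)))
        exchange = p["E"] * (Ip / p["Vp"] - Ii / p["Vi"])
        ig = nutrition_forcing(meals, t, p["k_decay"], p["carb_to_mg"])
        out = np.empty_like(states)
        out[:, 0] = f1 - exchange - Ip / p["tp"]
        out[:, 1] = exchange - Ii / p["ti"]
        out[:, 2] = f4 + ig - f2 - f3 * G
        out[:, 3] = 3.0 * (Ip - h1) / p["td"]
        out[:, 4] = 3.0 * (h1 - h2) / p["td"]
        out[:, 5] = 3.0 * (h2 - h3) / p["td"]
        return out

    def observe(self, states, params):
        states = np.asarray(states, dtype=float)
        return states[..., 2] / (10.0 * params.get("Vg", 10.0))

    def set_glucose(self, state, glucose_mgdl, params):
        out = np.array(state, dtype=float)
        out[2] = glucose_mgdl * 10.0 * params.get("Vg", 10.0)
        return out

    def _equilibrium_guess(self, params):
        vg = params["Vg"]
        return np.array([100.0, 150.0, 90.0 * 10.0 * vg, 100.0, 100.0, 100.0])


class MealModel(_ModelBase):
    """Twelve-state meal-simulation model with gastro-intestinal transit.

    States (masses per kg body weight unless noted): plasma glucose Gp and
    tissue glucose Gt (mg/kg); liver insulin Il and plasma insulin Ip
    (pmol/kg); solid stomach Qsto1, liquid stomach Qsto2 and gut Qgut (mg);
    delayed insulin signals I1, Id (pmol/l); insulin action X (pmol/l);
    portal insulin Ipo (pmol/kg); secretion provision Y (pmol/kg/min).

    Meal carbohydrate enters Qsto1 as an impulse at meal time; the gastric
    emptying rate is the standard dose-dependent tanh form.
    """

    model_id = "meal"
    state_names = ("Gp", "Gt", "Il", "Ip", "Qsto1", "Qsto2", "Qgut",
                   "I1", "Id", "X", "Ipo", "Y")
    # insulin distribution volume and the two glucose kinetics rates
    estimated = ("VI", "k1", "k2")

    def default_params(self) -> dict:
        return {
            "BW": 78.0,      # body weight (kg)
            "VG": 1.88,      # glucose distribution volume (dl/kg)
            "k1": 0.065,     # glucose plasma->tissue rate (1/min)
            "k2": 0.079,     # glucose tissue->plasma rate (1/min)
            "VI": 0.05,      # insulin distribution volume (l/kg)
            "m1": 0.190,     # liver insulin outflow (1/min)
            "m2": 0.484,     # plasma->liver insulin rate (1/min)
            "m4": 0.194,     # peripheral insulin degradation (1/min)
            "HEb": 0.6,      # basal hepatic insulin extraction (held constant)
            "kp1": 2.70,     # endogenous production at zero glucose/insulin (mg/kg/min)
            "kp2": 0.0021,   # liver glucose effectiveness (1/min)
            "kp3": 0.009,    # amplitude of insulin action on production
            "kp4": 0.0618,   # amplitude of portal insulin action
            "ki": 0.0079,    # delayed insulin signal rate (1/min)
            "Fcns": 1.0,     # insulin-independent utilization (mg/kg/min)
            "Vm0": 2.50,     # basal insulin-dependent utilization Vmax (mg/kg/min)
            "Vmx": 0.047,    # insulin sensitivity of Vmax
            "Km0": 225.59,   # utilization Michaelis constant (mg/kg)
            "p2U": 0.0331,   # insulin action rate constant (1/min)
            "K": 2.30,       # secretion response to glucose rate of change
            "alpha_s": 0.050,  # secretion provision rate (1/min)
            "beta_s": 0.11,  # secretion response to glucose level
            "gamma": 0.5,    # portal insulin transfer rate (1/min)
            "ke1": 0.0005,   # renal extraction rate (1/min)
            "ke2": 339.0,    # renal extraction threshold (mg/kg)
            "kmax": 0.0558,  # max gastric emptying rate (1/min)
            "kmin": 0.0080,  # min gastric emptying rate (1/min)
            "kabs": 0.057,   # intestinal absorption rate (1/min)
            "kgri": 0.0558,  # grinding rate solid->liquid stomach (1/min)
            "f_abs": 0.90,   # fraction of absorbed glucose reaching plasma
            "b_empt": 0.82,  # emptying-curve dose fraction (descending)
            "d_empt": 0.010, # emptying-curve dose fraction (ascending)
            # reference basal values, chosen self-consistently so that the
            # fasting equilibrium sits at X = 0, Y = 0 exactly
            "Gb": 90.48596799993355,   # basal glucose (mg/dl)
            "Ib": 26.424442609413713,  # basal plasma insulin (pmol/l)
            "Sb": 1.6,                 # basal insulin secretion (pmol/kg/min)
        }

    # -- meal bookkeeping ----------------------------------------------------
    def _segment_times(self, t0, t1, meals):
        if meals.size == 0:
            return []
        ts = meals[:, 0]
        return sorted(float(t) for t in ts[(ts > t0) & (ts < t1)])

    def _apply_meal_impulse(self, states, seg_start, meals):
        if meals.size == 0:
            return states
        hit = np.isclose(meals[:, 0], seg_start)
        if not np.any(hit):
            return states
        dose = float(meals[hit, 1].sum()) * CARB_TO_MG
        out = states.copy()
        out[:, 4] = out[:, 4] + dose
        return out

    @staticmethod
    def _last_dose(t, meals):
        """Dose (mg) of the most recent meal at or before time t; 0 if none."""
        if meals.size == 0:
            return 0.0
        past = meals[meals[:, 0] <= t + 1e-9]
        return float(past[-1, 1]) * CARB_TO_MG if past.size else 0.0

    def rhs(self, t, states, params, meals):
        p = params
        Gp, Gt, Il, Ip, Q1, Q2, Qg, I1, Id, X, Ipo, Y = (states[:, i] for i in range(12))
        Gp = np.maximum(Gp, 1e-6)
        G = Gp / p["VG"]
        I = np.maximum(Ip, 0.0) / p["VI"]
        m3 = p["m1"] * p["HEb"] / max(1.0 - p["HEb"], 1e-6)

        # gastro-intestinal transit
        D = self._last_dose(t, meals)
        Qsto = np.maximum(Q1, 0.0) + np.maximum(Q2, 0.0)
        if D > 0:
            aa = 5.0 / (2.0 * D * (1.0 - p["b_empt"]))
            cc = 5.0 / (2.0 * D * p["d_empt"])
            kempt = p["kmin"] + (p["kmax"] - p["kmin"]) / 2.0 * (
                np.tanh(aa * (Qsto - p["b_empt"] * D)) - np.tanh(cc * (Qsto - p["d_empt"] * D)) + 2.0
            )
        else:
            kempt = np.full_like(Qsto, p["kmax"])
        Ra = p["f_abs"] * p["kabs"] * np.maximum(Qg, 0.0) / p["BW"]

        # glucose subsystem
        EGP = np.maximum(p["kp1"] - p["kp2"] * Gp - p["kp3"] * Id - p["kp4"] * np.maximum(Ipo, 0.0), 0.0)
        Uid = (p["Vm0"] + p["Vmx"] * np.maximum(X, 0.0)) * np.maximum(Gt, 0.0) / (p["Km0"] + np.maximum(Gt, 0.0))
        ren = p["ke1"] * np.maximum(Gp - p["ke2"], 0.0)
        dGp = EGP + Ra - p["Fcns"] - ren - p["k1"] * Gp + p["k2"] * Gt
        dGt = -Uid + p["k1"] * Gp - p["k2"] * Gt

        # insulin secretion and kinetics
        dG = dGp / p["VG"]
        Spo = Y + p["K"] * np.maximum(dG, 0.0) + p["Sb"]
        S = p["gamma"] * np.maximum(Ipo, 0.0)
        dIl = -(p["m1"] + m3) * Il + p["m2"] * Ip + S
        dIp = p["m1"] * Il - (p["m2"] + p["m4"]) * Ip
        target = p["beta_s"] * (G - p["Gb"])
        target = np.maximum(target, -p["Sb"])
        dY = p["alpha_s"] * (target - Y)
        dIpo = -p["gamma"] * np.maximum(Ipo, 0.0) + Spo

        out = np.empty_like(states)
        out[:, 0] = dGp
        out[:, 1] = dGt
        out[:, 2] = dIl
        out[:, 3] = dIp
        out[:, 4] = -p["kgri"] * np.maximum(Q1, 0.0)
        out[:, 5] = p["kgri"] * np.maximum(Q1, 0.0) - kempt * np.maximum(Q2, 0.0)
        out[:, 6] = kempt * np.maximum(Q2, 0.0) - p["kabs"] * np.maximum(Qg, 0.0)
        out[:, 7] = -p["ki"] * (I1 - I)
        out[:, 8] = -p["ki"] * (Id - I1)
        out[:, 9] = -p["p2U"] * X + p["p2U"] * (I - p["Ib"])
        out[:, 10] = dIpo
        out[:, 11] = dY
        return out

    def observe(self, states, params):
        states = np.asarray(states, dtype=float)
        return states[..., 0] / params.get("VG", 1.88)

    def set_glucose(self, state, glucose_mgdl, params):
        out = np.array(state, dtype=float)
        out[0] = glucose_mgdl * params.get("VG", 1.88)
        return out

    def _equilibrium_guess(self, params):
        p = params
        gb = p["Gb"]
        Gp = gb * p["VG"]
        m3 = p["m1"] * p["HEb"] / max(1.0 - p["HEb"], 1e-6)
        Ipo = p["Sb"] / max(p["gamma"], 1e-9)
        denom = (p["m1"] + m3) * (p["m2"] + p["m4"]) - p["m1"] * p["m2"]
        Ip = p["m1"] * p["Sb"] / max(denom, 1e-9)
        Il = (p["m2"] * Ip + p["Sb"]) / (p["m1"] + m3)
        I = Ip / p["VI"]
        Gt = Gp * p["k1"] / p["k2"] * 0.8
        return np.array([Gp, Gt, Il, Ip, 0.0, 0.0, 0.0, I, I, 0.0, Ipo, 0.0])


MODELS = {"ultradian": UltradianModel(), "meal": MealModel()}


def get_model(model_id: str) -> _ModelBase:
    """Look up a registered model by id ('ultradian' or 'meal')."""
    try:
        return MODELS[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {model_id!r}; choose from {sorted(MODELS)}"
        ) from None
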