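"""Minimal model of glucose-insulin dynamics after a mixed meal in type 1 diabetes.

The model couples three sub-systems, all built from first-order compartments:

* an insulin sub-system: a subcutaneous depot (pump basal infusion plus meal
  bolus) draining with rate ``1/mtt_ins`` into a single plasma compartment of
  volume ``V_I`` cleared at ``CL_I``;
* a glucose sub-system: one accessible pool of volume ``V_G`` whose mass ``Q``
  is raised by oral absorption and a constant basal input, and lowered by a
  fixed (brain-dominated) utilization ``F_b`` and by a clearance ``S_G + X``,
  where ``X`` is the classic remote insulin action driven by the excursion of
  plasma insulin above basal with rate constant ``p_2`` and gain ``S_I``;
* an oral absorption sub-system: two parallel Erlang chains (fast and slow)
  fed by the ingested glucose equivalents; the summed efflux of their terminal
  compartments is the oral glucose input (OGI) flux into the accessible pool.

Because there is no endogenous insulin secretion (C-peptide-negative type 1
diabetes), insulin appears only through the pump.  A constant basal glucose
input exactly balancing ``F_b + S_G * G_b`` closes the pre-meal steady state.

Units: glucose concentration mmol/l, glucose mass mmol, insulin pmol/l,
volumes ml (glucose) and l (insulin), fluxes mmol/min, time min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernel

__all__ = [
    "MW_GLUCOSE",
    "PMOL_PER_UNIT",
    "FixedConstants",
    "GIParameters",
    "MealProtocol",
    "SimulationResult",
    "PARAM_NAMES",
    "OGI_PARAM_NAMES",
    "erlang_density",
    "ogi_flux",
    "basal_input",
    "system_rhs",
    "initial_state",
    "simulate",
    "glucose_mtt",
    "insulin_mtt",
]

#: molar mass of glucose [g/mol]
MW_GLUCOSE = 180.156
#: insulin unit conversion [pmol per U]
PMOL_PER_UNIT = 6000.0


class InvalidParameterError(ValueError):
    """A structural or physiological parameter violates its domain."""


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a trajectory within tolerances."""


@dataclass(frozen=True)
class FixedConstants:
    """Structural constants that are fixed, not estimated.

    Parameters
    ----------
    F_b_rate
        Fixed glucose utilization per body mass [mg/kg/min]; primarily brain
        uptake, insulin-independent.
    n_fast, n_slow
        Compartment counts of the fast and slow absorption chains.  With equal
        rates a shorter chain peaks earlier, so ``n_fast < n_slow``.
    f_bio
        Fraction of ingested glucose equivalents that reaches the accessible
        pool (net of splanchnic extraction and malabsorption).
    c_ge
        Grams of glucose equivalents per gram of meal carbohydrate.
    MW_glucose
        Molar mass of glucose [g/mol].
    """

    F_b_rate: float = 1.0
    n_fast: int = 2
    n_slow: int = 4
    f_bio: float = 0.9
    c_ge: float = 1.0
    MW_glucose: float = MW_GLUCOSE

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise InvalidParameterError("chain orders must be >= 1")
        if not 0.0 < self.f_bio <= 1.0:
            raise InvalidParameterError("f_bio must be in (0, 1]")
        if self.F_b_rate <= 0:
            raise InvalidParameterError("F_b_rate must be positive")
        if self.c_ge <= 0:
            raise InvalidParameterError("c_ge must be positive")


#: canonical ordering of the 16-entry estimation vector
PARAM_NAMES: tuple[str, ...] = (
    "mtt_ins",
    "V_I",
    "CL_I",
    "D_0",
    "I_b",
    "V_G",
    "S_G",
    "S_I",
    "p_2",
    "G_b",
    "G_0",
    "X_0",
    "phi",
    "k_fast",
    "k_slow",
    "t_lag",
)

#: the free parameters of the oral glucose input function
OGI_PARAM_NAMES: tuple[str, ...] = ("phi", "k_fast", "k_slow")

#: display units for reporting, in PARAM_NAMES order
PARAM_UNITS: dict[str, str] = {
    "mtt_ins": "min",
    "V_I": "l",
    "CL_I": "l/min",
    "D_0": "pmol",
    "I_b": "pmol/l",
    "V_G": "ml",
    "S_G": "ml/min",
    "S_I": "(ml/min)/(pmol/l)",
    "p_2": "1/min",
    "G_b": "mmol/l",
    "G_0": "mmol/l",
    "X_0": "ml/min",
    "phi": "",
    "k_fast": "1/min",
    "k_slow": "1/min",
    "t_lag": "min",
}


@dataclass(frozen=True)
class GIParameters:
    """The 16-entry estimation vector of the meal model.

    ``mtt_ins`` is the mean transit time of insulin in the subcutaneous depot
    (the depot rate constant is ``1/mtt_ins``); ``S_I`` is the net insulin
    sensitivity, combining the effects of insulin on glucose utilization and
    production; ``S_G`` is glucose effectiveness expressed as a clearance.
    ``phi``, ``k_fast`` and ``k_slow`` are the three free parameters of the
    oral glucose input; ``t_lag`` delays absorption onset after ingestion
    start.  ``G_0``, ``X_0`` and ``D_0`` are initial conditions, estimated
    because a patient need not be at steady state when the meal starts.
    """

    mtt_ins: float   # [min] s.c. depot mean transit time
    V_I: float       # [l] insulin distribution volume
    CL_I: float      # [l/min] insulin plasma clearance
    D_0: float       # [pmol] initial s.c. depot mass
    I_b: float       # [pmol/l] basal plasma insulin
    V_G: float       # [ml] glucose distribution volume
    S_G: float       # [ml/min] glucose effectiveness
    S_I: float       # [(ml/min)/(pmol/l)] insulin sensitivity
    p_2: float       # [1/min] insulin-action rate constant
    G_b: float       # [mmol/l] basal (target steady-state) glucose
    G_0: float       # [mmol/l] glucose at simulation start
    X_0: float       # [ml/min] insulin action at simulation start
    phi: float       # [-] fraction routed to the fast chain
    k_fast: float    # [1/min] fast-chain rate
    k_slow: float    # [1/min] slow-chain rate
    t_lag: float     # [min] ingestion-to-absorption delay

    def __post_init__(self) -> None:
        for name in ("mtt_ins", "V_I", "CL_I", "I_b", "V_G", "S_G", "S_I",
                     "p_2", "G_b", "G_0", "k_fast", "k_slow"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v}")
        for name in ("D_0", "X_0", "t_lag"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.phi <= 1.0:
            raise InvalidParameterError(f"phi must be in [0, 1], got {self.phi}")

    def to_array(self) -> np.ndarray:
        """Return the estimation vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "GIParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(
                f"expected {len(PARAM_NAMES)} parameters, got shape {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def replace(self, **kwargs) -> "GIParameters":
        return replace(self, **kwargs)


# sanity: the dataclass and the name tuple must stay in sync
assert tuple(f.name for f in fields(GIParameters)) == PARAM_NAMES


@dataclass(frozen=True)
class MealProtocol:
    """Meal composition and insulin delivery of one mixed-meal test.

    The insulin bolus is delivered as a square pulse of ``bolus_duration``
    minutes starting at t = 0 (meal ingestion start); the basal infusion runs
    at ``basal_rate`` throughout.  ``carb_g`` may be zero for a meal-free
    (basal) run.
    """

    carb_g: float          # [g] meal carbohydrate
    kcal: float            # [kcal] meal energy
    T_ing: float           # [min] ingestion duration
    bolus_pmol: float      # [pmol] s.c. bolus at t = 0
    basal_rate: float      # [pmol/min] continuous s.c. infusion
    weight_kg: float       # [kg]
    BSA_m2: float          # [m^2]
    bolus_duration: float = 1.0  # [min] square-pulse bolus delivery time

    def __post_init__(self) -> None:
        if self.carb_g < 0:
            raise InvalidParameterError("carb_g must be >= 0")
        if self.T_ing <= 0 or self.bolus_duration <= 0:
            raise InvalidParameterError("durations must be > 0")
        if self.bolus_pmol < 0 or self.basal_rate < 0:
            raise InvalidParameterError("insulin inputs must be >= 0")
        if self.weight_kg <= 0 or self.BSA_m2 <= 0:
            raise InvalidParameterError("body size must be > 0")

    @property
    def dose_mmol(self) -> float:
        """Ingested carbohydrate in mmol glucose equivalents (before f_bio)."""
        return self.carb_g * 1000.0 / MW_GLUCOSE


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of one forward simulation on a reporting grid."""

    times: np.ndarray          # [min]
    glucose: np.ndarray        # [mmol/l]
    insulin: np.ndarray        # [pmol/l]
    ogi_mmol_min: np.ndarray   # [mmol/min]
    ogi_mg_kg_min: np.ndarray  # [mg/kg/min]
    states: np.ndarray         # (n_times, n_states) full trajectory
    diagnostics: dict

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")


def erlang_density(t, n: int, k: float):
    """Erlang(n, k) probability density, the impulse response of a chain of
    ``n`` identical first-order compartments with rate ``k``.

    Returns ``k^n t^(n-1) e^(-kt) / (n-1)!`` for t >= 0 and 0 for t < 0;
    integrates to 1 over [0, inf).  Accepts scalar or array ``t``.
    """
    if n < 1 or int(n) != n:
        raise InvalidParameterError(f"order n must be a positive integer, got {n}")
    if k <= 0:
        raise InvalidParameterError(f"rate k must be > 0, got {k}")
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        dens = np.where(
            t_arr >= 0,
            k**n * np.maximum(t_arr, 0.0) ** (n - 1)
            * np.exp(-k * np.maximum(t_arr, 0.0)) / math.factorial(n - 1),
            0.0,
        )
    return dens if dens.shape else float(dens)


def _chain_slices(consts: FixedConstants) -> tuple[slice, slice]:
    nf, ns = consts.n_fast, consts.n_slow
    return slice(4, 4 + nf), slice(4 + nf, 4 + nf + ns)


def n_states(consts: FixedConstants) -> int:
    return 4 + consts.n_fast + consts.n_slow


def ogi_flux(state: np.ndarray, params: GIParameters, consts: FixedConstants) -> float:
    """Instantaneous oral glucose input [mmol/min]: summed efflux of the
    terminal compartments of the fast and slow absorption chains."""
    state = np.asarray(state, dtype=float)
    sf, ss = _chain_slices(consts)
    return params.k_fast * state[sf][-1] + params.k_slow * state[ss][-1]


def fixed_utilization(protocol: MealProtocol, consts: FixedConstants) -> float:
    """Insulin-independent fixed glucose utilization F_b [mmol/min]."""
    return consts.F_b_rate * protocol.weight_kg / consts.MW_glucose


def basal_input(params: GIParameters, consts: FixedConstants,
                protocol: MealProtocol) -> float:
    """Constant basal glucose input [mmol/min] that closes the pre-meal
    steady state: it exactly matches the fixed utilization plus the
    glucose-effectiveness drain at basal glucose, ``F_b + S_G * G_b / 1000``.
    """
    return fixed_utilization(protocol, consts) + params.S_G * params.G_b / 1000.0


def _insulin_rate(t: float, protocol: MealProtocol) -> float:
    """Subcutaneous insulin delivery rate u(t) [pmol/min]."""
    u = protocol.basal_rate
    if 0.0 <= t < protocol.bolus_duration:
        u += protocol.bolus_pmol / protocol.bolus_duration
    return u


def _ingestion_rate(t: float, params: GIParameters, protocol: MealProtocol,
                    consts: FixedConstants) -> float:
    """Rate of glucose equivalents entering the absorption chains [mmol/min]."""
    if protocol.carb_g == 0:
        return 0.0
    t0 = params.t_lag
    if t0 <= t < t0 + protocol.T_ing:
        return consts.f_bio * consts.c_ge * protocol.dose_mmol / protocol.T_ing
    return 0.0


def system_rhs(t: float, state: np.ndarray, params: GIParameters,
               protocol: MealProtocol, consts: FixedConstants) -> np.ndarray:
    """Time derivative of the full state vector.

    State layout: ``[D, I, X, Q, C_f[1..n_fast], C_s[1..n_slow]]`` with D the
    s.c. depot mass [pmol], I plasma insulin [pmol/l], X remote insulin action
    [ml/min], Q glucose mass in the accessible pool [mmol] and the chain
    compartments in mmol.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (n_states(consts),):
        raise InvalidParameterError(
            f"state must have {n_states(consts)} components, got {state.shape}")
    nf, ns = consts.n_fast, consts.n_slow
    D, I, X, Q = state[:4]
    G = 1000.0 * Q / params.V_G
    dy = np.empty_like(state)

    u = _insulin_rate(t, protocol)
    r = _ingestion_rate(t, params, protocol, consts)
    k_sc = 1.0 / params.mtt_ins

    dy[0] = u - k_sc * D
    dy[1] = k_sc * D / params.V_I - (params.CL_I / params.V_I) * I
    dy[2] = params.p_2 * (params.S_I * (I - params.I_b) - X)
    F_b = fixed_utilization(protocol, consts)
    egb = basal_input(params, consts, protocol)
    ogi = ogi_flux(state, params, consts)
    dy[3] = ogi + egb - F_b - (params.S_G + X) * G / 1000.0

    cf = state[4:4 + nf]
    dy[4] = params.phi * r - params.k_fast * cf[0]
    for j in range(1, nf):
        dy[4 + j] = params.k_fast * (cf[j - 1] - cf[j])
    cs = state[4 + nf:4 + nf + ns]
    dy[4 + nf] = (1.0 - params.phi) * r - params.k_slow * cs[0]
    for j in range(1, ns):
        dy[4 + nf + j] = params.k_slow * (cs[j - 1] - cs[j])
    return dy


def initial_state(params: GIParameters, protocol: MealProtocol,
                  consts: FixedConstants, I_0: float | None = None) -> np.ndarray:
    """Initial state at simulation start: depot at ``D_0``, plasma insulin at
    the value implied by the basal infusion and clearance (``basal_rate /
    CL_I``) unless ``I_0`` overrides it, glucose at ``G_0``, action at
    ``X_0``, absorption chains empty."""
    y0 = np.zeros(n_states(consts))
    y0[0] = params.D_0
    y0[1] = protocol.basal_rate / params.CL_I if I_0 is None else I_0
    y0[2] = params.X_0
    y0[3] = params.G_0 * params.V_G / 1000.0
    return y0


def _breakpoints(params: GIParameters, protocol: MealProtocol,
                 t0: float, t1: float) -> np.ndarray:
    """Times where an input square pulse switches on or off."""
    pts = {t0, t1, 0.0, protocol.bolus_duration,
           params.t_lag, params.t_lag + protocol.T_ing}
    return np.array(sorted(p for p in pts if t0 <= p <= t1))


def _result_from_path(times: np.ndarray, states: np.ndarray,
                      params: GIParameters, protocol: MealProtocol,
                      consts: FixedConstants, diagnostics: dict) -> SimulationResult:
    sf, ss = _chain_slices(consts)
    ogi = (params.k_fast * states[:, sf.stop - 1]
           + params.k_slow * states[:, ss.stop - 1])
    glucose = 1000.0 * states[:, 3] / params.V_G
    insulin = states[:, 1]
    ogi_mg = ogi * consts.MW_glucose / protocol.weight_kg  # mmol/min -> mg/kg/min
    return SimulationResult(
        times=times, glucose=glucose, insulin=insulin,
        ogi_mmol_min=ogi, ogi_mg_kg_min=ogi_mg,
        states=states, diagnostics=diagnostics,
    )


def _kernel_inputs(params: GIParameters, protocol: MealProtocol,
                   consts: FixedConstants, grid: np.ndarray):
    """Knot sequence and per-interval constant inputs for the fixed-step path."""
    t0, t1 = float(grid[0]), float(grid[-1])
    knots = np.unique(np.concatenate([grid, _breakpoints(params, protocol, t0, t1)]))
    mid = 0.5 * (knots[:-1] + knots[1:])
    u_arr = np.array([_insulin_rate(t, protocol) for t in mid])
    r_arr = np.array([_ingestion_rate(t, params, protocol, consts) for t in mid])
    p = np.array([
        1.0 / params.mtt_ins, params.V_I, params.CL_I, params.p_2,
        params.S_I, params.I_b, params.V_G, params.S_G,
        basal_input(params, consts, protocol),
        fixed_utilization(protocol, consts),
        params.phi, params.k_fast, params.k_slow,
    ])
    return knots, u_arr, r_arr, p


def simulate_path(params: GIParameters, protocol: MealProtocol,
                  consts: FixedConstants, grid: np.ndarray,
                  h_max: float = 0.25, I_0: float | None = None) -> np.ndarray:
    """Fast fixed-step (classic Runge-Kutta 4) trajectory evaluated exactly at
    ``grid``; input discontinuities are knots of the integration, so each
    sub-interval has smooth dynamics.  Returns the (n_grid, n_states) path.

    This is the workhorse of the estimation loop; :func:`simulate` with
    ``method='adaptive'`` is the independent tightly-tolerated reference.
    """
    grid = np.asarray(grid, dtype=float)
    knots, u_arr, r_arr, p = _kernel_inputs(params, protocol, consts, grid)
    y0 = initial_state(params, protocol, consts, I_0=I_0)
    path = _kernel.rk4_path(y0, knots, u_arr, r_arr, p,
                            consts.n_fast, consts.n_slow, h_max)
    idx = np.searchsorted(knots, grid)
    return path[idx]


def simulate(params: GIParameters, protocol: MealProtocol,
             consts: FixedConstants | None = None,
             grid: Sequence[float] | None = None,
             method: str = "adaptive",
             rtol: float = 1e-8, atol: float = 1e-10,
             h_max: float = 0.25,
             I_0: float | None = None) -> SimulationResult:
    """Forward-simulate the meal model on a reporting grid.

    Parameters
    ----------
    grid
        Strictly increasing report times [min]; default -20..300 every minute.
    method
        ``'adaptive'`` uses an adaptive explicit Runge-Kutta pair (RK45)
        integrated piecewise between input discontinuities at ``rtol``/
        ``atol``; ``'fixed'`` uses the fast fixed-step RK4 path with step
        ``h_max``.
    """
    consts = consts or FixedConstants()
    if grid is None:
        grid = np.arange(-20.0, 301.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("grid must be strictly increasing with >= 2 points")

    if method == "fixed":
        states = simulate_path(params, protocol, consts, grid, h_max=h_max, I_0=I_0)
        diag = {"method": "rk4-fixed", "h_max": h_max}
        return _result_from_path(grid, states, params, protocol, consts, diag)
    if method != "adaptive":
        raise InvalidParameterError(f"unknown method {method!r}")

    y0 = initial_state(params, protocol, consts, I_0=I_0)
    t0, t1 = float(grid[0]), float(grid[-1])
    brk = _breakpoints(params, protocol, t0, t1)
    states = np.empty((grid.size, y0.size))
    filled = 0
    if grid[0] == t0:
        states[0] = y0
        filled = 1
    n_steps = 0
    y = y0
    for a, b in zip(brk[:-1], brk[1:]):
        in_seg = grid[(grid > a) & (grid <= b)]
        t_eval = np.unique(np.append(in_seg, b))  # always land on the knot
        sol = solve_ivp(
            system_rhs, (a, b), y, method="RK45", rtol=rtol, atol=atol,
            t_eval=t_eval, args=(params, protocol, consts),
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a}, {b}]: {sol.message}")
        n_steps += sol.nfev
        if in_seg.size:
            states[filled:filled + in_seg.size] = sol.y.T[:in_seg.size] \
                if in_seg[-1] < b else sol.y.T[-in_seg.size:]
            filled += in_seg.size
        y = sol.y[:, -1]
    if filled != grid.size:
        raise IntegrationError("internal grid bookkeeping failed")
    diag = {"method": "rk45-adaptive", "rtol": rtol, "atol": atol, "nfev": n_steps}
    return _result_from_path(grid, states, params, protocol, consts, diag)


def glucose_mtt(params: GIParameters, protocol: MealProtocol,
                consts: FixedConstants) -> float:
    """Apparent mean transit time [min] of the oral glucose load from
    ingestion start to appearance in the accessible pool: lag, half the
    ingestion duration, and the probability-weighted chain transit times."""
    return (params.t_lag + protocol.T_ing / 2.0
            + params.phi * consts.n_fast / params.k_fast
            + (1.0 - params.phi) * consts.n_slow / params.k_slow)


def insulin_mtt(params: GIParameters) -> float:
    """Mean transit time [min] of insulin in the subcutaneous depot; equal to
    ``mtt_ins`` for the single-compartment depot."""
    if params.mtt_ins <= 0:
        raise InvalidParameterError("mtt_ins must be > 0")
    return params.mtt_ins
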