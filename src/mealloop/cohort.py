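"""Virtual T1D-on-pump patients, meal protocols, noisy observations,
day-to-day variability and a simulated hyperinsulinemic euglycemic clamp.

The generator exists so that the whole identification pipeline can be
exercised end-to-end without clinical data: draw a patient, simulate a meal
study with realistic measurement noise, fit, and compare estimates with the
known truth.  The canonical virtual patient carries the population-mean
values of the four key physiological parameters (S_I 0.78 (ml/min)/(pmol/l),
S_G 20.8 ml/min, oral-glucose mean transit time 117 min, s.c. insulin mean
transit time 112 min) with the remaining constants at documented typical
values for adult pump-treated T1D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .estimation import DEFAULT_CV_GLUCOSE, DEFAULT_CV_INSULIN, ObservationSeries
from .model import (
    PARAM_NAMES,
    PMOL_PER_UNIT,
    FixedConstants,
    GIParameters,
    MealProtocol,
    basal_input,
    fixed_utilization,
    glucose_mtt,
    simulate,
)

__all__ = [
    "DEFAULT_SCHEDULE",
    "PopulationSpec",
    "ClampProtocol",
    "ClampResult",
    "canonical_patient",
    "canonical_protocol",
    "make_meal_protocol",
    "with_glucose_mtt",
    "draw_virtual_patient",
    "simulate_observations",
    "day2day_variation",
    "simulate_hec",
]

#: default MMT sampling schedule [min]: denser around the excursion onset,
#: 300-min monitoring, three pre-meal baseline samples
DEFAULT_SCHEDULE = np.array([-20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 45.0, 60.0,
                             90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0,
                             300.0])

#: calibration factor: with day-to-day perturbation scale s, the two-point CV
#: estimator |d1-d2|/sqrt(2)/mean has expectation s/sqrt(pi); scaling s by
#: sqrt(pi) makes the estimator unbiased for the nominal within-subject CV
_TWO_POINT_CALIBRATION = math.sqrt(math.pi)


def canonical_protocol(kcal: float = 292.0, *, T_ing: float = 10.0,
                       icr: float = 10.0, weight_kg: float = 70.0,
                       BSA_m2: float = 1.8,
                       basal_rate: float = 100.0) -> MealProtocol:
    """Standardized mixed meal scaled from the 292 kcal / 38.9 g-carbohydrate
    reference composition; the bolus follows the insulin-to-carbohydrate
    ratio.  ``kcal=600`` gives the double-size meal (79.9 g carbohydrate)."""
    carb_g = 38.9 * kcal / 292.0
    return make_meal_protocol(kcal=kcal, carb_g=carb_g, T_ing=T_ing, icr=icr,
                              weight_kg=weight_kg, BSA_m2=BSA_m2,
                              basal_rate=basal_rate)


def make_meal_protocol(kcal: float, carb_g: float, T_ing: float, icr: float,
                       weight_kg: float, BSA_m2: float,
                       basal_rate: float) -> MealProtocol:
    """Build a meal protocol; the pre-meal bolus is ``carb_g / icr`` units of
    fast analogue, converted at 6000 pmol/U.  ``carb_g = 0`` gives a basal
    (meal-free, bolus-free) run; negative meals are invalid."""
    if carb_g < 0 or kcal < 0:
        raise ValueError("meal size must be >= 0")
    if icr <= 0:
        raise ValueError("insulin-to-carbohydrate ratio must be > 0")
    bolus_pmol = carb_g / icr * PMOL_PER_UNIT if np.isfinite(icr) else 0.0
    return MealProtocol(carb_g=carb_g, kcal=kcal, T_ing=T_ing,
                        bolus_pmol=bolus_pmol, basal_rate=basal_rate,
                        weight_kg=weight_kg, BSA_m2=BSA_m2)


def canonical_patient(protocol: MealProtocol | None = None,
                      consts: FixedConstants | None = None) -> GIParameters:
    """The canonical virtual patient: population-mean key parameters, typical
    values elsewhere, at basal steady state before the meal (depot mass and
    basal insulin consistent with the pump basal rate)."""
    protocol = protocol or canonical_protocol()
    consts = consts or FixedConstants()
    mtt_ins = 112.0
    CL_I = 1.1
    base = GIParameters(
        mtt_ins=mtt_ins, V_I=9.0, CL_I=CL_I,
        D_0=protocol.basal_rate * mtt_ins,
        I_b=protocol.basal_rate / CL_I,
        V_G=11200.0, S_G=20.8, S_I=0.78, p_2=0.02,
        G_b=7.0, G_0=7.0, X_0=0.0,
        phi=0.7, k_fast=0.04, k_slow=0.02, t_lag=10.0,
    )
    return with_glucose_mtt(base, 117.0, protocol, consts)


def with_glucose_mtt(params: GIParameters, target: float,
                     protocol: MealProtocol,
                     consts: FixedConstants | None = None) -> GIParameters:
    """Rescale both absorption-chain rates by a common factor so that the
    oral-glucose mean transit time equals ``target`` minutes."""
    consts = consts or FixedConstants()
    chain_target = target - params.t_lag - protocol.T_ing / 2.0
    if chain_target <= 0:
        raise ValueError("target MTT must exceed the lag plus half ingestion")
    chain_now = (params.phi * consts.n_fast / params.k_fast
                 + (1.0 - params.phi) * consts.n_slow / params.k_slow)
    s = chain_now / chain_target
    out = params.replace(k_fast=params.k_fast * s, k_slow=params.k_slow * s)
    assert abs(glucose_mtt(out, protocol, consts) - target) < 1e-9 * target
    return out


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions for virtual-patient generation.

    Parameters are drawn independently and mean-preserving log-normally with
    the stated coefficients of variation (``phi`` on the logit scale so it
    stays in (0, 1)); ``day_cv`` holds the day-to-day within-subject CVs;
    noise CVs describe multiplicative measurement error on the two analytes.
    """

    mean: GIParameters = field(default_factory=canonical_patient)
    cv: Mapping[str, float] = field(default_factory=lambda: {
        "mtt_ins": 0.32, "V_I": 0.15, "CL_I": 0.15, "D_0": 0.20, "I_b": 0.20,
        "V_G": 0.15, "S_G": 0.60, "S_I": 0.40, "p_2": 0.20,
        "G_b": 0.15, "G_0": 0.15, "X_0": 0.0,
        "phi": 0.15, "k_fast": 0.30, "k_slow": 0.30, "t_lag": 0.30,
    })
    day_cv: Mapping[str, float] = field(default_factory=lambda: {
        "mtt_ins": 0.28, "V_I": 0.05, "CL_I": 0.05, "D_0": 0.05, "I_b": 0.05,
        "V_G": 0.05, "S_G": 0.23, "S_I": 0.12, "p_2": 0.05,
        "G_b": 0.05, "G_0": 0.05, "X_0": 0.0,
        "phi": 0.05, "k_fast": 0.11, "k_slow": 0.11, "t_lag": 0.11,
    })
    noise_cv_glucose: float = DEFAULT_CV_GLUCOSE
    noise_cv_insulin: float = DEFAULT_CV_INSULIN
    schedule: np.ndarray = field(default_factory=lambda: DEFAULT_SCHEDULE.copy())

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", np.asarray(self.schedule, float))
        if self.noise_cv_glucose < 0 or self.noise_cv_insulin < 0:
            raise ValueError("noise CVs must be >= 0")
        if np.any(self.schedule < -30) or np.any(self.schedule > 300):
            raise ValueError("schedule must lie within [-30, 300] min")
        for table in (self.cv, self.day_cv):
            if any(v < 0 for v in table.values()):
                raise ValueError("CVs must be >= 0")


def _lognormal_factor(cv: float, rng: np.random.Generator) -> float:
    """Mean-one multiplicative log-normal factor with coefficient of
    variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.exp(rng.standard_normal() * sigma - 0.5 * sigma * sigma)


def draw_virtual_patient(spec: PopulationSpec,
                         rng: np.random.Generator) -> GIParameters:
    """Draw one virtual patient from the population distributions."""
    vals = {}
    for name in PARAM_NAMES:
        mu = getattr(spec.mean, name)
        cv = float(spec.cv.get(name, 0.0))
        if name == "phi":
            if cv == 0 or mu in (0.0, 1.0):
                vals[name] = mu
            else:
                sigma = cv / (1.0 - mu)  # logit-scale SD giving sd(phi)~cv*phi
                z = math.log(mu / (1.0 - mu)) + sigma * rng.standard_normal()
                vals[name] = 1.0 / (1.0 + math.exp(-z))
        elif mu == 0.0:
            vals[name] = 0.0
        else:
            vals[name] = mu * _lognormal_factor(cv, rng)
    return GIParameters(**vals)


def day2day_variation(patient: GIParameters, spec: PopulationSpec,
                      rng: np.random.Generator) -> GIParameters:
    """Second-day parameter set: independent log-normal within-subject
    perturbations, with the scale calibrated (factor sqrt(pi)) so that the
    two-point CV estimator reproduces the nominal within-subject CV on
    average."""
    vals = {}
    for name in PARAM_NAMES:
        v = getattr(patient, name)
        cv = float(spec.day_cv.get(name, 0.0)) * _TWO_POINT_CALIBRATION
        if v == 0.0 or cv == 0.0:
            vals[name] = v
        elif name == "phi":
            sigma = cv / (1.0 - v)
            z = math.log(v / (1.0 - v)) + sigma * rng.standard_normal()
            vals[name] = 1.0 / (1.0 + math.exp(-z))
        else:
            vals[name] = v * math.exp(cv * rng.standard_normal())
    return GIParameters(**vals)


def simulate_observations(patient: GIParameters, protocol: MealProtocol,
                          spec: PopulationSpec,
                          rng: np.random.Generator,
                          consts: FixedConstants | None = None) -> ObservationSeries:
    """Noise-free simulation sampled at the schedule, with multiplicative
    Gaussian measurement noise at the analyte CVs; negative draws are
    truncated at one tenth of the noise-free value.  The SD columns reflect
    the noise actually applied (``cv * noise-free value``); with zero noise
    the default assay CVs populate the SD columns so weights stay defined."""
    consts = consts or FixedConstants()
    sim = simulate(patient, protocol, consts, grid=spec.schedule, method="fixed",
                   h_max=0.1)
    cv_g, cv_i = spec.noise_cv_glucose, spec.noise_cv_insulin
    sd_g = (cv_g if cv_g > 0 else DEFAULT_CV_GLUCOSE) * sim.glucose
    sd_i = (cv_i if cv_i > 0 else DEFAULT_CV_INSULIN) * sim.insulin
    g_obs = sim.glucose * (1.0 + cv_g * rng.standard_normal(sim.glucose.size))
    i_obs = sim.insulin * (1.0 + cv_i * rng.standard_normal(sim.insulin.size))
    g_obs = np.maximum(g_obs, 0.1 * sim.glucose)
    i_obs = np.maximum(i_obs, 0.1 * sim.insulin)
    return ObservationSeries(times=spec.schedule, glucose=g_obs,
                             glucose_sd=sd_g, insulin=i_obs, insulin_sd=sd_i,
                             protocol=protocol)


@dataclass(frozen=True)
class ClampProtocol:
    """Hyperinsulinemic euglycemic clamp: an intravenous insulin prime plus
    constant infusion while a variable dextrose infusion, adjusted every
    ``update_interval`` minutes by a proportional-integral controller, holds
    glucose at the target."""

    prime_U_m2: float = 0.8          # [U/m^2 BSA] i.v. prime
    infusion_mU_min_m2: float = 40.0  # [mU/min/m^2 BSA] constant infusion
    target_mmol_l: float = 5.0       # [mmol/l] clamped glucose
    duration_min: float = 240.0      # [min]
    update_interval: float = 5.0     # [min] controller update period
    Kp: float = 3.0                  # [mmol/min per mmol/l]
    Ki: float = 0.20                 # [mmol/min per mmol/l/min]
    prime_duration: float = 5.0      # [min] prime delivery window
    dextrose_pct: float = 20.0       # [%] infusate concentration (metadata)

    def __post_init__(self) -> None:
        if self.target_mmol_l <= 0:
            raise ValueError("clamp target must be > 0")
        if self.duration_min < 120:
            raise ValueError("clamp must run at least 120 min")


@dataclass(frozen=True)
class ClampResult:
    """Clamp trajectory and readouts; ``M_value`` is the mean dextrose
    infusion over the final 60 min [umol/min/m^2 BSA], valid only if glucose
    stayed within 5% of target over that window."""

    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    gir_mmol_min: np.ndarray
    M_value: float
    I_ss: float
    I_b: float
    valid: bool


def simulate_hec(patient: GIParameters, clamp: ClampProtocol,
                 consts: FixedConstants | None = None, *,
                 weight_kg: float = 70.0, BSA_m2: float = 1.8,
                 basal_rate: float = 100.0) -> ClampResult:
    """Simulate a hyperinsulinemic euglycemic clamp on a virtual patient.

    Insulin is delivered intravenously (prime then constant infusion)
    directly into the plasma compartment; the subcutaneous basal analogue is
    assumed to keep contributing its baseline influx throughout, so the depot
    term is held at the basal rate.  A discrete proportional-integral
    controller updates the dextrose infusion every ``update_interval``
    minutes from the current glucose reading.
    """
    consts = consts or FixedConstants()
    # reuse the meal plumbing for the basal-closure fluxes (no meal)
    carrier = MealProtocol(carb_g=0.0, kcal=0.0, T_ing=1.0, bolus_pmol=0.0,
                           basal_rate=basal_rate, weight_kg=weight_kg,
                           BSA_m2=BSA_m2)
    F_b = fixed_utilization(carrier, consts)
    egb = basal_input(patient, consts, carrier)
    iv_inf = clamp.infusion_mU_min_m2 * 6.0 * BSA_m2   # pmol/min (1 mU = 6 pmol)
    prime_rate = (clamp.prime_U_m2 * PMOL_PER_UNIT * BSA_m2
                  / clamp.prime_duration)               # pmol/min over the window
    I_b_measured = basal_rate / patient.CL_I

    def rhs(t, y, gir):
        I, X, Q = y
        G = 1000.0 * Q / patient.V_G
        u = basal_rate + iv_inf + (prime_rate if t < clamp.prime_duration else 0.0)
        dI = u / patient.V_I - (patient.CL_I / patient.V_I) * I
        dX = patient.p_2 * (patient.S_I * (I - patient.I_b) - X)
        dQ = gir + egb - F_b - (patient.S_G + X) * G / 1000.0
        return [dI, dX, dQ]

    y = np.array([I_b_measured, patient.X_0,
                  patient.G_b * patient.V_G / 1000.0])
    n_seg = int(round(clamp.duration_min / clamp.update_interval))
    times = [0.0]
    glucose = [1000.0 * y[2] / patient.V_G]
    insulin = [y[0]]
    gir_trace = [0.0]
    gir = 0.0
    integral = 0.0
    for k in range(n_seg):
        t0 = k * clamp.update_interval
        t1 = t0 + clamp.update_interval
        G = 1000.0 * y[2] / patient.V_G
        err = clamp.target_mmol_l - G
        raw = clamp.Kp * err + clamp.Ki * (integral + err * clamp.update_interval)
        if raw > 0 or err > 0:          # anti-windup: freeze integral when pinned
            integral += err * clamp.update_interval
        gir = max(0.0, clamp.Kp * err + clamp.Ki * integral)
        sol = solve_ivp(rhs, (t0, t1), y, args=(gir,), method="RK45",
                        rtol=1e-8, atol=1e-10)
        y = sol.y[:, -1]
        times.append(t1)
        glucose.append(1000.0 * y[2] / patient.V_G)
        insulin.append(y[0])
        gir_trace.append(gir)

    times = np.array(times)
    glucose = np.array(glucose)
    insulin = np.array(insulin)
    gir_trace = np.array(gir_trace)
    window = times >= clamp.duration_min - 60.0
    g_win = glucose[window]
    valid = bool(np.all(np.abs(g_win - clamp.target_mmol_l)
                        <= 0.05 * clamp.target_mmol_l))
    mean_gir = float(np.mean(gir_trace[window]))  # piecewise-constant, equal spans
    M = mean_gir * 1000.0 / BSA_m2                 # mmol/min -> umol/min/m^2
    I_ss = float(np.mean(insulin[window]))
    return ClampResult(times=times, glucose=glucose, insulin=insulin,
                       gir_mmol_min=gir_trace, M_value=M, I_ss=I_ss,
                       I_b=I_b_measured, valid=valid)
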