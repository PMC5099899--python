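"""Prior-penalized weighted least-squares identification of the meal model.

The objective is the squared norm of the stacked residual vector

* data block: ``(model - observation) / SD`` for every glucose and insulin
  sample (glucose block first, then insulin, time-ascending), so that a
  correctly specified fit yields weighted residuals with mean 0 and SD 1;
* prior block: ``w_j * (theta_j - mu_j) / mu_j`` for every parameter with a
  prior (clamp-derived for insulin sensitivity, literature-based for the
  poorly identifiable kinetic constants), a quadratic penalty on the relative
  distance from the prior mean.

Minimization uses the bound-constrained trust-region-reflective algorithm
(:func:`scipy.optimize.least_squares`) from multiple starts: a data-informed
central start plus a scrambled Sobol dispersion over the bounds, screened by
initial cost so that only the most promising starts receive a full local
optimization.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline
from scipy.stats import qmc

from .model import (
    FixedConstants,
    GIParameters,
    MealProtocol,
    SimulationResult,
    PARAM_NAMES,
    glucose_mtt,
    insulin_mtt,
    simulate_path,
)

__all__ = [
    "ObservationSeries",
    "PriorSpec",
    "FitConfig",
    "FitResult",
    "DEFAULT_CV_GLUCOSE",
    "DEFAULT_CV_INSULIN",
    "TYPICAL_VALUES",
    "default_bounds",
    "weighted_residuals",
    "prior_residuals",
    "si_prior_from_clamp",
    "fit",
    "multistart_fit",
    "residual_diagnostics",
    "reproducibility_cv",
    "cohort_cv_summary",
]

#: default assay coefficients of variation used when a series carries no SDs
#: (duplicate glucose-oxidase measurement; insulin ELISA precision scale)
DEFAULT_CV_GLUCOSE = 0.02
DEFAULT_CV_INSULIN = 0.06

#: typical magnitudes used for bound construction, start dispersion and
#: optimizer scaling; order-of-magnitude physiology of adult pump-treated T1D
TYPICAL_VALUES: dict[str, float] = {
    "mtt_ins": 100.0,
    "V_I": 9.0,
    "CL_I": 1.1,
    "D_0": 1.0e4,
    "I_b": 90.0,
    "V_G": 11200.0,
    "S_G": 20.0,
    "S_I": 0.7,
    "p_2": 0.02,
    "G_b": 7.0,
    "G_0": 7.0,
    "X_0": 0.0,
    "phi": 0.5,
    "k_fast": 0.04,
    "k_slow": 0.02,
    "t_lag": 10.0,
}


logger = logging.getLogger("mealloop")


class CoverageError(ValueError):
    """Simulation grid does not cover the observation times."""


class InvalidWeightError(ValueError):
    """A residual weight (SD) is zero or negative."""


class InvalidPriorError(ValueError):
    """A prior specification is degenerate."""


class DegenerateClampError(ValueError):
    """Clamp steady-state insulin does not exceed basal insulin."""


@dataclass(frozen=True)
class ObservationSeries:
    """Timed plasma glucose/insulin samples with per-point SDs.

    Missing values are allowed per analyte as NaN; the matching SD entry is
    then ignored.  At least 6 observed points per analyte are required.
    """

    times: np.ndarray        # [min], strictly increasing
    glucose: np.ndarray      # [mmol/l]
    glucose_sd: np.ndarray   # [mmol/l]
    insulin: np.ndarray      # [pmol/l]
    insulin_sd: np.ndarray   # [pmol/l]
    protocol: MealProtocol

    def __post_init__(self) -> None:
        for name in ("times", "glucose", "glucose_sd", "insulin", "insulin_sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.times.size
        if any(getattr(self, a).size != n for a in
               ("glucose", "glucose_sd", "insulin", "insulin_sd")):
            raise ValueError("all observation columns must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        for values, sds, label in ((self.glucose, self.glucose_sd, "glucose"),
                                   (self.insulin, self.insulin_sd, "insulin")):
            mask = ~np.isnan(values)
            if mask.sum() < 6:
                raise ValueError(f"need at least 6 {label} observations")
            if np.any(~(sds[mask] > 0)):
                raise InvalidWeightError(f"{label} SDs must be > 0 where observed")

    @property
    def glucose_mask(self) -> np.ndarray:
        return ~np.isnan(self.glucose)

    @property
    def insulin_mask(self) -> np.ndarray:
        return ~np.isnan(self.insulin)


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior means, penalty weights and provenance tags.

    A weight of zero (or an absent entry) means no prior; provenance is one
    of ``clamp``, ``literature`` or ``none`` and is reporting metadata only.
    """

    means: Mapping[str, float] = field(default_factory=dict)
    weights: Mapping[str, float] = field(default_factory=dict)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if name not in PARAM_NAMES:
                raise InvalidPriorError(f"unknown parameter {name!r}")
            if w < 0:
                raise InvalidPriorError(f"prior weight for {name} must be >= 0")
            if w > 0:
                mu = self.means.get(name)
                if mu is None or mu <= 0:
                    raise InvalidPriorError(
                        f"penalized parameter {name} needs a positive prior mean")

    @property
    def active(self) -> tuple[str, ...]:
        """Penalized parameters in canonical order."""
        return tuple(n for n in PARAM_NAMES if self.weights.get(n, 0.0) > 0)

    @classmethod
    def none(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def default(cls, si_prior: float | None = None,
                si_weight: float = 10.0) -> "PriorSpec":
        """Literature priors on the weakly identifiable kinetic constants,
        plus (optionally) a strong clamp-derived prior on S_I."""
        means = {"V_I": 9.0, "CL_I": 1.1, "V_G": 11200.0, "p_2": 0.02,
                 "S_G": 20.0, "k_fast": 0.04, "k_slow": 0.02}
        weights = {"V_I": 5.0, "CL_I": 5.0, "V_G": 5.0, "p_2": 5.0, "S_G": 2.0,
                   "k_fast": 2.0, "k_slow": 2.0}
        provenance = {k: "literature" for k in means}
        if si_prior is not None:
            means["S_I"] = float(si_prior)
            weights["S_I"] = si_weight
            provenance["S_I"] = "clamp"
        return cls(means=means, weights=weights, provenance=provenance)

    @classmethod
    def for_study(cls, obs: "ObservationSeries", si_prior: float | None = None,
                  si_weight: float = 10.0, basal_weight: float = 5.0) -> "PriorSpec":
        """Full prior set for one study: literature priors, the clamp S_I
        prior, and patient-specific basal priors (G_b, I_b) taken from the
        pre-meal samples, which anchor the basal closure of the model."""
        base = cls.default(si_prior=si_prior, si_weight=si_weight)
        means = dict(base.means)
        weights = dict(base.weights)
        provenance = dict(base.provenance)
        pre = obs.times <= 0
        g_pre = obs.glucose[pre & obs.glucose_mask]
        i_pre = obs.insulin[pre & obs.insulin_mask]
        if g_pre.size:
            means["G_b"] = float(np.mean(g_pre))
            weights["G_b"] = basal_weight
            provenance["G_b"] = "patient"
        if i_pre.size:
            means["I_b"] = float(np.mean(i_pre))
            weights["I_b"] = basal_weight
            provenance["I_b"] = "patient"
        return cls(means=means, weights=weights, provenance=provenance)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration.

    ``n_starts`` points are generated (a data-informed center plus a Sobol
    dispersion over the bounds); all are screened by initial cost and the best
    ``n_refine`` receive a full trust-region-reflective optimization capped at
    ``max_nfev`` objective evaluations.  ``h_fit`` is the fixed integration
    step of the forward model inside the objective.  Parameters listed in
    ``fixed`` are held at their start values (e.g. hard-fixing S_I to the
    clamp value instead of using it as a prior).
    """

    n_starts: int = 20
    n_refine: int = 6
    seed: int = 0
    tol: float = 1e-10
    max_nfev: int = 120
    h_fit: float = 0.5
    bounds: Mapping[str, tuple[float, float]] | None = None
    fixed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        for name in self.fixed:
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown fixed parameter {name!r}")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        b = default_bounds()
        if self.bounds:
            b.update({k: tuple(v) for k, v in self.bounds.items()})
        return b


def default_bounds() -> dict[str, tuple[float, float]]:
    """[0.1x, 10x] of the typical magnitude for scale parameters; natural
    ranges for the bounded/one-sided ones."""
    b = {n: (0.1 * v, 10.0 * v) for n, v in TYPICAL_VALUES.items() if v > 0}
    b["phi"] = (0.01, 0.99)
    b["t_lag"] = (0.0, 60.0)
    # near-basal start: a large initial remote action would mean the patient
    # was far from the overnight steady state the protocol prescribes
    b["X_0"] = (0.0, 10.0)
    b["G_b"] = (3.0, 20.0)
    b["G_0"] = (3.0, 20.0)
    # absorption of a mixed meal essentially completes within ~5.5 h: slow
    # chain transit n_slow/k_slow <= ~330 min, fast chain <= ~2.5 h
    b["k_fast"] = (0.013, 0.4)
    b["k_slow"] = (0.012, 0.1)
    return b


@dataclass(frozen=True)
class FitResult:
    """Outcome of one (possibly multi-start) fit."""

    params: GIParameters
    success: bool
    status: int
    message: str
    nfev: int
    residuals: np.ndarray        # data block only
    prior_resid: np.ndarray
    ssr_data: float
    ssr_prior: float
    ssr_total: float
    diagnostics: dict
    glucose_mtt: float
    insulin_mtt: float
    n_glucose: int
    n_insulin: int
    start_params: GIParameters
    start_log: tuple = ()
    #: effective number of data degrees of freedom absorbed by the fit,
    #: tr(J_d (J'J)^-1 J_d') of the prior-penalized least-squares problem;
    #: NaN when the Jacobian was not available
    effective_dof: float = float("nan")

    @property
    def n_obs(self) -> int:
        return self.n_glucose + self.n_insulin


def _model_at(theta: GIParameters, obs: ObservationSeries,
              consts: FixedConstants, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Model glucose/insulin evaluated exactly at the observation times."""
    path = simulate_path(theta, obs.protocol, consts, obs.times, h_max=h)
    glucose = 1000.0 * path[:, 3] / theta.V_G
    insulin = path[:, 1]
    return glucose, insulin


def _data_residuals(g_model: np.ndarray, i_model: np.ndarray,
                    obs: ObservationSeries) -> np.ndarray:
    gm, im = obs.glucose_mask, obs.insulin_mask
    rg = (g_model[gm] - obs.glucose[gm]) / obs.glucose_sd[gm]
    ri = (i_model[im] - obs.insulin[im]) / obs.insulin_sd[im]
    return np.concatenate([rg, ri])


def weighted_residuals(sim: SimulationResult, obs: ObservationSeries) -> np.ndarray:
    """SD-weighted residuals, glucose block then insulin block,
    time-ascending; model values interpolated onto the observation times
    (cubic) unless the simulation grid already contains them."""
    if obs.times[0] < sim.times[0] or obs.times[-1] > sim.times[-1]:
        raise CoverageError("simulation grid does not cover observation times")
    idx = np.searchsorted(sim.times, obs.times)
    idx = np.clip(idx, 0, sim.times.size - 1)
    if np.allclose(sim.times[idx], obs.times, rtol=0, atol=1e-9):
        g_model, i_model = sim.glucose[idx], sim.insulin[idx]
    else:
        g_model = CubicSpline(sim.times, sim.glucose)(obs.times)
        i_model = CubicSpline(sim.times, sim.insulin)(obs.times)
    return _data_residuals(g_model, i_model, obs)


def prior_residuals(theta: GIParameters, priors: PriorSpec) -> np.ndarray:
    """Penalty residuals ``w_j (theta_j - mu_j) / mu_j`` for the penalized
    parameters, in canonical parameter order."""
    out = []
    for name in priors.active:
        mu = priors.means[name]
        out.append(priors.weights[name] * (getattr(theta, name) - mu) / mu)
    return np.asarray(out, dtype=float)


def si_prior_from_clamp(M: float, BSA: float, G_clamp: float,
                        I_ss: float, I_b: float) -> float:
    """Insulin-sensitivity prior from a hyperinsulinemic euglycemic clamp.

    ``M`` is the glucose metabolized over the final steady hour
    [umol/min/m^2 BSA], ``G_clamp`` the clamped glucose [mmol/l == umol/ml],
    ``I_ss``/``I_b`` the steady-state and basal insulin [pmol/l].  The whole-
    body glucose clearance attributable to insulin, per unit of insulin
    excursion, is ``M * BSA / (G_clamp * (I_ss - I_b))`` in
    (ml/min)/(pmol/l).
    """
    if G_clamp <= 0:
        raise ValueError("G_clamp must be > 0")
    if I_ss <= I_b:
        raise DegenerateClampError("steady-state insulin must exceed basal")
    return M * BSA / (G_clamp * (I_ss - I_b))


def _free_names(config: FitConfig) -> tuple[str, ...]:
    return tuple(n for n in PARAM_NAMES if n not in config.fixed)


def _pack(theta: GIParameters, names: Sequence[str]) -> np.ndarray:
    return np.array([getattr(theta, n) for n in names])


def _unpack(x: np.ndarray, names: Sequence[str],
            template: GIParameters) -> GIParameters:
    return template.replace(**dict(zip(names, x)))


def _effective_dof(jac: np.ndarray, n_data: int) -> float:
    """Data degrees of freedom absorbed by the penalized fit: the trace of
    the hat matrix ``J_d (J'J)^-1 J_d'`` where ``J`` stacks the data and
    prior Jacobians.  Priors shrink this below the raw parameter count."""
    J = np.asarray(jac)
    Jd = J[:n_data]
    M = J.T @ J
    try:
        H = np.linalg.solve(M, Jd.T)
    except np.linalg.LinAlgError:
        H = np.linalg.lstsq(M, Jd.T, rcond=None)[0]
    return float(np.einsum("ij,ji->", Jd, H))


def _finish(res_x: GIParameters, obs: ObservationSeries, priors: PriorSpec,
            config: FitConfig, consts: FixedConstants, start: GIParameters,
            success: bool, status: int, message: str, nfev: int,
            start_log: tuple = (), effective_dof: float = float("nan")) -> FitResult:
    g_model, i_model = _model_at(res_x, obs, consts, config.h_fit)
    resid = _data_residuals(g_model, i_model, obs)
    prior = prior_residuals(res_x, priors)
    n_g = int(obs.glucose_mask.sum())
    result = FitResult(
        params=res_x, success=success, status=status, message=message,
        nfev=nfev, residuals=resid, prior_resid=prior,
        ssr_data=float(resid @ resid), ssr_prior=float(prior @ prior),
        ssr_total=float(resid @ resid + prior @ prior),
        diagnostics={}, glucose_mtt=glucose_mtt(res_x, obs.protocol, consts),
        insulin_mtt=insulin_mtt(res_x),
        n_glucose=n_g, n_insulin=resid.size - n_g,
        start_params=start, start_log=start_log, effective_dof=effective_dof,
    )
    object.__setattr__(result, "diagnostics", residual_diagnostics(result))
    return result


def fit(obs: ObservationSeries, priors: PriorSpec, config: FitConfig,
        start: GIParameters, consts: FixedConstants | None = None) -> FitResult:
    """Single bound-constrained trust-region-reflective fit from ``start``."""
    consts = consts or FixedConstants()
    names = _free_names(config)
    bounds = config.resolved_bounds()
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x0 = np.clip(_pack(start, names), lo, hi)
    template = start

    def objective(x: np.ndarray) -> np.ndarray:
        theta = _unpack(x, names, template)
        g_model, i_model = _model_at(theta, obs, consts, config.h_fit)
        return np.concatenate([_data_residuals(g_model, i_model, obs),
                               prior_residuals(theta, priors)])

    scale = np.array([TYPICAL_VALUES[n] if TYPICAL_VALUES[n] > 0 else 5.0
                      for n in names])
    sol = optimize.least_squares(
        objective, x0, bounds=(lo, hi), method="trf",
        xtol=config.tol, ftol=config.tol, gtol=config.tol,
        x_scale=scale, diff_step=1e-5, max_nfev=config.max_nfev,
    )
    theta_hat = _unpack(sol.x, names, template)
    n_data = int(obs.glucose_mask.sum() + obs.insulin_mask.sum())
    p_eff = _effective_dof(sol.jac, n_data)
    return _finish(theta_hat, obs, priors, config, consts, start,
                   bool(sol.status > 0), int(sol.status), str(sol.message),
                   int(sol.nfev), effective_dof=p_eff)


def _initial_guess(obs: ObservationSeries, priors: PriorSpec,
                   bounds: Mapping[str, tuple[float, float]]) -> GIParameters:
    """Data-informed central start: typical values, prior means where
    available, basal levels read off the pre-meal samples."""
    vals = dict(TYPICAL_VALUES)
    for name in priors.active:
        vals[name] = priors.means[name]
    pre = obs.times <= 0
    g_pre = obs.glucose[pre & obs.glucose_mask]
    if g_pre.size:
        vals["G_b"] = vals["G_0"] = float(np.mean(g_pre))
    vals["I_b"] = obs.protocol.basal_rate / vals["CL_I"]
    vals["D_0"] = obs.protocol.basal_rate * vals["mtt_ins"]
    for name, (lo, hi) in bounds.items():
        vals[name] = float(np.clip(vals[name], lo, hi))
    return GIParameters(**vals)


def _sobol_starts(n: int, names: Sequence[str],
                  bounds: Mapping[str, tuple[float, float]],
                  seed: int) -> np.ndarray:
    """Scrambled Sobol dispersion over the bounds, log-spaced for strictly
    positive scale parameters and linear for the naturally bounded ones."""
    if n == 0:
        return np.empty((0, len(names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        u = qmc.Sobol(d=len(names), scramble=True, seed=seed).random(n)
    cols = []
    for j, name in enumerate(names):
        lo, hi = bounds[name]
        if name in ("phi", "t_lag", "X_0", "G_b", "G_0"):
            cols.append(lo + u[:, j] * (hi - lo))
        else:
            cols.append(np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo))))
    return np.column_stack(cols)


def multistart_fit(obs: ObservationSeries, priors: PriorSpec,
                   config: FitConfig,
                   consts: FixedConstants | None = None) -> FitResult:
    """Multi-start global search: screen every start by its initial cost,
    locally optimize the most promising ones, return the best-SSR result.
    Deterministic given ``config.seed``."""
    consts = consts or FixedConstants()
    names = _free_names(config)
    bounds = config.resolved_bounds()
    logger.debug("multistart fit: constants=%s bounds=%s seed=%d starts=%d",
                 consts, bounds, config.seed, config.n_starts)
    center = _initial_guess(obs, priors, bounds)
    starts = [center]
    for row in _sobol_starts(config.n_starts - 1, names, bounds, config.seed):
        starts.append(_unpack(row, names, center))

    def cost(theta: GIParameters) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            g_model, i_model = _model_at(theta, obs, consts, config.h_fit)
            r = _data_residuals(g_model, i_model, obs)
            p = prior_residuals(theta, priors)
            total = float(r @ r + p @ p)
        return total if np.isfinite(total) else np.inf

    ssr0 = np.array([cost(s) for s in starts])
    order = np.argsort(ssr0, kind="stable")
    n_refine = min(max(config.n_refine, 1), len(starts))
    log = []
    best: FitResult | None = None
    refined = set(int(i) for i in order[:n_refine])
    for i, start in enumerate(starts):
        entry = {"start": i, "ssr_initial": float(ssr0[i]), "refined": i in refined}
        if i in refined:
            res = fit(obs, priors, config, start, consts)
            entry.update(ssr_final=res.ssr_total, status=res.status,
                         nfev=res.nfev)
            logger.debug("start %d: ssr %.4g -> %.4g, exit status %d",
                         i, ssr0[i], res.ssr_total, res.status)
            if best is None or res.ssr_total < best.ssr_total:
                best = res
        log.append(entry)
    if best is None or not any(e.get("status", 0) > 0 for e in log if e["refined"]):
        if best is None:
            raise RuntimeError("all starts failed; see log")
    return FitResult(**{**best.__dict__, "start_log": tuple(log)})


def residual_diagnostics(result: FitResult) -> dict:
    """Per-analyte and pooled mean/SD of the weighted data residuals
    (population SD; prior residuals excluded), with misfit warnings when
    |mean| > 0.5 or SD falls outside [0.5, 2]."""
    rg = result.residuals[:result.n_glucose]
    ri = result.residuals[result.n_glucose:]
    out = {}
    warnings_list = []
    for label, r in (("glucose", rg), ("insulin", ri), ("pooled", result.residuals)):
        mean = float(np.mean(r)) if r.size else float("nan")
        sd = float(np.std(r)) if r.size else float("nan")
        out[label] = {"mean": mean, "sd": sd}
        if label != "pooled" and r.size:
            if abs(mean) > 0.5:
                warnings_list.append(f"{label} residual mean {mean:.2f} outside +-0.5")
            if r.size > 1 and sd > 0 and not 0.5 <= sd <= 2.0:
                warnings_list.append(f"{label} residual SD {sd:.2f} outside [0.5, 2]")
    out["warnings"] = warnings_list
    return out


def pooled_residual_sd(results: Sequence[FitResult],
                       dof_corrected: bool = True) -> float:
    """Pooled SD of the weighted data residuals across replicate fits.

    With ``dof_corrected`` (the default) the pooled scale is the reduced
    residual SD ``sqrt(sum SSR_i / sum (N_i - p_eff_i))``: a least-squares
    fit absorbs about one unit of residual variance per effective free
    parameter, so the raw pooled SD of a correctly specified fit sits below
    the theoretical 1 by construction; the correction removes that bias.
    ``dof_corrected=False`` returns the raw population SD of the pooled
    residual vector.
    """
    if not results:
        raise ValueError("need at least one fit result")
    if not dof_corrected:
        return float(np.std(np.concatenate([r.residuals for r in results])))
    ssr = sum(r.ssr_data for r in results)
    dof = sum(r.n_obs - (r.effective_dof if np.isfinite(r.effective_dof) else 0.0)
              for r in results)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom left")
    return float(np.sqrt(ssr / dof))


def _two_point_cv(a: float, b: float) -> float:
    mean = 0.5 * (a + b)
    if mean <= 0:
        raise ValueError("two-point mean must be > 0 for a CV")
    return 100.0 * abs(a - b) / np.sqrt(2.0) / mean


def reproducibility_cv(fit_day1: FitResult, fit_day2: FitResult) -> dict[str, float]:
    """Day-to-day within-subject CV [%] per parameter and for the derived
    transit times, using the two-point SD convention ``|d1 - d2| / sqrt(2)``."""
    out = {}
    for name in PARAM_NAMES:
        a, b = getattr(fit_day1.params, name), getattr(fit_day2.params, name)
        if 0.5 * (a + b) > 0:
            out[name] = _two_point_cv(a, b)
    out["glucose_mtt"] = _two_point_cv(fit_day1.glucose_mtt, fit_day2.glucose_mtt)
    out["insulin_mtt"] = _two_point_cv(fit_day1.insulin_mtt, fit_day2.insulin_mtt)
    return out


def cohort_cv_summary(cv_tables: Sequence[Mapping[str, float]]) -> dict[str, tuple[float, float]]:
    """Cohort summary (mean, SD across subjects) of within-subject CVs."""
    keys = sorted(set().union(*cv_tables))
    return {k: (float(np.mean([t[k] for t in cv_tables if k in t])),
                float(np.std([t[k] for t in cv_tables if k in t])))
            for k in keys}
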