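"""File formats and run configuration.

Observation files are plain CSV with the fixed header ``time_min,
glucose_mmol_l, glucose_sd, insulin_pmol_l, insulin_sd``; SD columns may be
omitted, in which case default assay CVs populate them.  Run configurations
are YAML or JSON documents validated strictly (unknown keys rejected); fit
reports are schema-versioned JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort import PopulationSpec, DEFAULT_SCHEDULE, canonical_patient, make_meal_protocol, with_glucose_mtt
from .estimation import (
    DEFAULT_CV_GLUCOSE,
    DEFAULT_CV_INSULIN,
    FitConfig,
    FitResult,
    ObservationSeries,
    reproducibility_cv,
)
from .model import FixedConstants, GIParameters, MealProtocol, PARAM_NAMES, PARAM_UNITS

logger = logging.getLogger("mealloop")

OBS_COLUMNS = ["time_min", "glucose_mmol_l", "glucose_sd",
               "insulin_pmol_l", "insulin_sd"]
REPORT_SCHEMA_VERSION = 1


class ObservationFormatError(ValueError):
    """Malformed observation file."""


def write_observations(obs: ObservationSeries, path: str | Path) -> None:
    """Write a series as CSV with the canonical header, 6 significant
    digits."""
    df = pd.DataFrame({
        "time_min": obs.times,
        "glucose_mmol_l": obs.glucose,
        "glucose_sd": obs.glucose_sd,
        "insulin_pmol_l": obs.insulin,
        "insulin_sd": obs.insulin_sd,
    })
    df.to_csv(path, index=False, float_format="%.8g")


def read_observations(path: str | Path, protocol: MealProtocol) -> ObservationSeries:
    """Read and validate an observation CSV.

    SD columns are optional: missing ones are filled from the default assay
    CVs (glucose 2%, insulin 6% of the observed value) with a logged warning.
    Non-increasing times or malformed rows raise with the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - reported as format error
        raise ObservationFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ["time_min", "glucose_mmol_l", "insulin_pmol_l"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ObservationFormatError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in OBS_COLUMNS]
    if unknown:
        raise ObservationFormatError(f"{path}: unknown columns {unknown}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[(numeric.isna() | np.isinf(numeric.fillna(0.0)))
                       & df[col].notna()]
        if len(bad):
            raise ObservationFormatError(
                f"{path}: non-numeric value in column {col}, line {bad[0] + 2}")
        df[col] = numeric
    t = df["time_min"].to_numpy(float)
    if np.any(np.isnan(t)):
        line = int(np.flatnonzero(np.isnan(t))[0]) + 2
        raise ObservationFormatError(f"{path}: missing time, line {line}")
    if np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ObservationFormatError(
            f"{path}: times must be strictly increasing (line {line})")
    glucose = df["glucose_mmol_l"].to_numpy(float)
    insulin = df["insulin_pmol_l"].to_numpy(float)
    if "glucose_sd" in df.columns:
        g_sd = df["glucose_sd"].to_numpy(float)
    else:
        g_sd = DEFAULT_CV_GLUCOSE * glucose
        logger.warning("%s: no glucose_sd column; default %.0f%% CV applied",
                       path, 100 * DEFAULT_CV_GLUCOSE)
    if "insulin_sd" in df.columns:
        i_sd = df["insulin_sd"].to_numpy(float)
    else:
        i_sd = DEFAULT_CV_INSULIN * insulin
        logger.warning("%s: no insulin_sd column; default %.0f%% CV applied",
                       path, 100 * DEFAULT_CV_INSULIN)
    return ObservationSeries(times=t, glucose=glucose, glucose_sd=g_sd,
                             insulin=insulin, insulin_sd=i_sd,
                             protocol=protocol)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    """Overrides for the structural constants."""
    F_b_rate: float = 1.0
    n_fast: int = 2
    n_slow: int = 4
    f_bio: float = 0.9
    c_ge: float = 1.0


class ProtocolSection(_Strict):
    """Meal and insulin-delivery protocol."""
    kcal: float = 292.0
    carb_g: float | None = None     # default: scaled from 38.9 g at 292 kcal
    T_ing: float = 10.0
    icr: float = 10.0               # [g/U] insulin-to-carbohydrate ratio
    weight_kg: float = 70.0
    BSA_m2: float = 1.8
    basal_rate: float = 100.0       # [pmol/min]


class PriorsSection(_Strict):
    enabled: bool = True            # False = pure weighted least squares
    si_prior: float | None = None   # clamp-derived S_I; None = simulate a clamp
    si_weight: float = 10.0
    basal_weight: float = 5.0
    use_clamp: bool = True


class FitSection(_Strict):
    n_starts: int = 20
    n_refine: int = 6
    max_nfev: int = 120
    tol: float = 1e-10
    h_fit: float = 0.5


class CohortSection(_Strict):
    noise_cv_glucose: float = DEFAULT_CV_GLUCOSE
    noise_cv_insulin: float = DEFAULT_CV_INSULIN
    schedule: list[float] = Field(default_factory=lambda: DEFAULT_SCHEDULE.tolist())
    mean_overrides: dict[str, float] = Field(default_factory=dict)
    glucose_mtt_target: float | None = None
    n_patients: int = 1
    replicates: int = 5


class RunConfig(_Strict):
    """Full run configuration; every report echoes it."""
    model: ModelSection = Field(default_factory=ModelSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    priors: PriorsSection = Field(default_factory=PriorsSection)
    fit: FitSection = Field(default_factory=FitSection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    seed: int = 0


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON config; ``None`` gives the documented defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def build_constants(cfg: RunConfig) -> FixedConstants:
    m = cfg.model
    return FixedConstants(F_b_rate=m.F_b_rate, n_fast=m.n_fast, n_slow=m.n_slow,
                          f_bio=m.f_bio, c_ge=m.c_ge)


def build_protocol(cfg: RunConfig) -> MealProtocol:
    p = cfg.protocol
    carb = p.carb_g if p.carb_g is not None else 38.9 * p.kcal / 292.0
    return make_meal_protocol(kcal=p.kcal, carb_g=carb, T_ing=p.T_ing,
                              icr=p.icr, weight_kg=p.weight_kg,
                              BSA_m2=p.BSA_m2, basal_rate=p.basal_rate)


def build_patient(cfg: RunConfig) -> GIParameters:
    protocol = build_protocol(cfg)
    consts = build_constants(cfg)
    patient = canonical_patient(protocol, consts)
    if cfg.cohort.mean_overrides:
        patient = patient.replace(**cfg.cohort.mean_overrides)
    if cfg.cohort.glucose_mtt_target is not None:
        patient = with_glucose_mtt(patient, cfg.cohort.glucose_mtt_target,
                                   protocol, consts)
    return patient


def build_population(cfg: RunConfig) -> PopulationSpec:
    return PopulationSpec(mean=build_patient(cfg),
                          noise_cv_glucose=cfg.cohort.noise_cv_glucose,
                          noise_cv_insulin=cfg.cohort.noise_cv_insulin,
                          schedule=np.asarray(cfg.cohort.schedule, float))


def build_fit_config(cfg: RunConfig, seed: int | None = None) -> FitConfig:
    f = cfg.fit
    return FitConfig(n_starts=f.n_starts, n_refine=f.n_refine,
                     max_nfev=f.max_nfev, tol=f.tol, h_fit=f.h_fit,
                     seed=cfg.seed if seed is None else seed)


# --------------------------------------------------------------------------
# fit reports
# --------------------------------------------------------------------------

def fit_report(result: FitResult, cfg: RunConfig, seed: int,
               day2: FitResult | None = None) -> dict[str, Any]:
    """Machine-readable fit report; mirrors the population-table reporting
    (parameter estimates with units plus derived transit times)."""
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software": {"name": "mealloop", "version": __version__},
        "seed": seed,
        "config": cfg.model_dump(),
        "parameters": {
            name: {"value": getattr(result.params, name),
                   "units": PARAM_UNITS[name]}
            for name in PARAM_NAMES
        },
        "derived": {
            "glucose_mtt_min": result.glucose_mtt,
            "insulin_mtt_min": result.insulin_mtt,
        },
        "fit": {
            "success": result.success,
            "status": result.status,
            "message": result.message,
            "ssr_data": result.ssr_data,
            "ssr_prior": result.ssr_prior,
            "ssr_total": result.ssr_total,
            "n_obs": result.n_obs,
            "effective_dof": result.effective_dof,
        },
        "residual_diagnostics": result.diagnostics,
        "start_log": list(result.start_log),
    }
    if day2 is not None:
        report["reproducibility_cv_pct"] = reproducibility_cv(result, day2)
    return report


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
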