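"""Canned in-silico recovery experiments on the canonical virtual patient.

These are the package's reference validation studies: simulate noisy
mixed-meal tests from a patient with known parameters, run the full
identification pipeline (simulated clamp for the S_I prior, patient-specific
basal priors, multi-start prior-penalized weighted least squares) and
compare the estimates with the truth.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    ClampProtocol,
    PopulationSpec,
    canonical_patient,
    canonical_protocol,
    simulate_hec,
    simulate_observations,
    with_glucose_mtt,
)
from .estimation import (
    FitConfig,
    FitResult,
    PriorSpec,
    multistart_fit,
    si_prior_from_clamp,
)
from .model import FixedConstants, GIParameters, MealProtocol

__all__ = ["clamp_si_prior", "recovery_run", "RecoveryStudy"]


def clamp_si_prior(patient: GIParameters, protocol: MealProtocol,
                   consts: FixedConstants,
                   clamp: ClampProtocol | None = None) -> float:
    """Run the simulated hyperinsulinemic euglycemic clamp on a patient and
    convert its M-value into the S_I prior."""
    clamp = clamp or ClampProtocol()
    res = simulate_hec(patient, clamp, consts, weight_kg=protocol.weight_kg,
                       BSA_m2=protocol.BSA_m2, basal_rate=protocol.basal_rate)
    return si_prior_from_clamp(res.M_value, protocol.BSA_m2,
                               clamp.target_mmol_l, res.I_ss, res.I_b)


def recovery_run(patient: GIParameters, protocol: MealProtocol,
                 consts: FixedConstants, *, n_replicates: int, seed: int,
                 n_starts: int = 20, n_refine: int = 6,
                 si_prior: float | None = None,
                 noise_cv_glucose: float = 0.02,
                 noise_cv_insulin: float = 0.06) -> list[FitResult]:
    """Fit ``n_replicates`` independently noised replicates of one meal
    study; everything (noise and start dispersion) derives from ``seed``."""
    if si_prior is None:
        si_prior = clamp_si_prior(patient, protocol, consts)
    spec = PopulationSpec(mean=patient, noise_cv_glucose=noise_cv_glucose,
                          noise_cv_insulin=noise_cv_insulin)
    data_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    fits = []
    for i in range(n_replicates):
        rng = np.random.default_rng(data_seeds[i])
        obs = simulate_observations(patient, protocol, spec, rng, consts)
        priors = PriorSpec.for_study(obs, si_prior=si_prior)
        cfg = FitConfig(n_starts=n_starts, n_refine=n_refine,
                        seed=(seed * 1009 + i) % (2**31))
        fits.append(multistart_fit(obs, priors, cfg, consts))
    return fits


class RecoveryStudy:
    """The canonical recovery study: the virtual patient carrying the
    population-mean key parameters, a 292 kcal (or scaled) mixed meal, the
    default 16-point schedule and 2%/6% measurement noise.

    ``glucose_mtt_truth`` rescales the absorption chains to a different true
    oral-glucose transit time (e.g. 109 min for the double-size meal study).
    """

    def __init__(self, kcal: float = 292.0,
                 glucose_mtt_truth: float | None = None,
                 consts: FixedConstants | None = None) -> None:
        self.consts = consts or FixedConstants()
        self.protocol = canonical_protocol(kcal)
        patient = canonical_patient(canonical_protocol(), self.consts)
        if glucose_mtt_truth is not None:
            patient = with_glucose_mtt(patient, glucose_mtt_truth,
                                       self.protocol, self.consts)
        self.patient = patient

    def run(self, *, n_replicates: int, seed: int,
            n_starts: int = 20, n_refine: int = 6) -> list[FitResult]:
        return recovery_run(self.patient, self.protocol, self.consts,
                            n_replicates=n_replicates, seed=seed,
                            n_starts=n_starts, n_refine=n_refine)

    def mean_estimates(self, fits: list[FitResult]) -> dict[str, float]:
        return {
            "S_I": float(np.mean([f.params.S_I for f in fits])),
            "S_G": float(np.mean([f.params.S_G for f in fits])),
            "glucose_mtt": float(np.mean([f.glucose_mtt for f in fits])),
            "insulin_mtt": float(np.mean([f.insulin_mtt for f in fits])),
        }
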