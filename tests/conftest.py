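import numpy as np
import pytest
from hypothesis import settings

from mealloop.cohort import ClampProtocol, PopulationSpec, canonical_patient, canonical_protocol, simulate_hec
from mealloop.estimation import si_prior_from_clamp
from mealloop.model import FixedConstants

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def consts():
    return FixedConstants()


@pytest.fixture(scope="session")
def protocol():
    return canonical_protocol()


@pytest.fixture(scope="session")
def patient(protocol, consts):
    return canonical_patient(protocol, consts)


@pytest.fixture(scope="session")
def si_prior(patient, protocol, consts):
    """Clamp-derived insulin-sensitivity prior for the canonical patient."""
    res = simulate_hec(patient, ClampProtocol(), consts,
                       weight_kg=protocol.weight_kg, BSA_m2=protocol.BSA_m2,
                       basal_rate=protocol.basal_rate)
    return si_prior_from_clamp(res.M_value, protocol.BSA_m2,
                               ClampProtocol().target_mmol_l, res.I_ss, res.I_b)


@pytest.fixture(scope="session")
def noise_free_obs(patient, protocol, consts):
    """Observations generated by the model itself without measurement noise
    (SD columns at the default assay CVs so weights stay defined)."""
    from mealloop.cohort import simulate_observations
    spec = PopulationSpec(mean=patient, noise_cv_glucose=0.0,
                          noise_cv_insulin=0.0)
    return simulate_observations(patient, protocol, spec,
                                 np.random.default_rng(0), consts)
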