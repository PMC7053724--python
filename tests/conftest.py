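import warnings

import numpy as np
import pytest

from cardiowork.cohort import NoiseConfig, sample_patient
from cardiowork.parameters import nominal_parameters, set_param
from cardiowork.simulator import simulate


@pytest.fixture(scope="session")
def nominal():
    return nominal_parameters()


@pytest.fixture(scope="session")
def healthy_sim():
    """Nominal healthy simulation (aortic A_eff_max = 2.5 cm^2), 15 beats."""
    return simulate(nominal_parameters(), n_beats=15)


@pytest.fixture(scope="session")
def stenotic_sim():
    """Severe-AS simulation: aortic A_eff_max reduced to 0.75 cm^2."""
    ps = nominal_parameters()
    set_param(ps, "valves.aortic.A_max", 0.75)
    set_param(ps, "valves.aortic.A_min", 0.00075)
    return simulate(ps, n_beats=15)


@pytest.fixture(scope="session")
def noise_free_patient():
    """One virtual patient with all measurement noise switched off."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sample_patient(
            "vp-clean", np.random.default_rng(7),
            noise=NoiseConfig(sigma_plv=0.0, sigma_pao=0.0, sigma_ava=0.0,
                              sigma_strain=0.0))
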