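import numpy as np
import pytest
from hypothesis import settings

from henapbpk import (DosingRegimen, build_model, create_reference_adult,
                      default_henagliflozin, nca, simulate_regimen)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound():
    return default_henagliflozin()


@pytest.fixture(scope="session")
def adult():
    return create_reference_adult()


@pytest.fixture(scope="session")
def adult_ss(compound, adult):
    """Reference adult, 5 mg once daily to steady state (tight tolerances)."""
    regimen = DosingRegimen(dose=5, interval=24.0, n_doses=10)
    model = build_model(compound, adult, regimen)
    result = simulate_regimen(model, regimen)
    pk = nca(result, interval=24.0, at_steady_state=True)
    return model, result, pk


@pytest.fixture(scope="session")
def single_dose_profile(compound, adult):
    """Adult 5 mg single-dose profile on a coarse grid (for synthetic data)."""
    regimen = DosingRegimen(dose=5, n_doses=1)
    model = build_model(compound, adult, regimen)
    result = simulate_regimen(model, regimen, duration=96.0, rtol=1e-6,
                              atol=1e-9, output_step=0.25)
    return result


@pytest.fixture(scope="session")
def sampling_times():
    return np.array([0.5, 1, 1.5, 2, 3, 4, 6, 8, 12, 24, 48, 72.0])
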