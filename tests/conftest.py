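import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dissopk as dk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: pre-registered seed for every stochastic test in the suite
SEED = 1


@pytest.fixture(scope="session")
def disposition() -> dk.DispositionParams:
    """Published desvenlafaxine two-compartment constants, 70 kg subject."""
    return dk.DispositionParams()


@pytest.fixture(scope="session")
def derived(disposition) -> dk.DerivedDisposition:
    return dk.derive_disposition(disposition)


@pytest.fixture(scope="session")
def absorption() -> dk.AbsorptionParams:
    return dk.AbsorptionParams(dose_mg=50.0)


@pytest.fixture(scope="session")
def study_fixture():
    return dk.make_study_fixture(SEED)


@pytest.fixture(scope="session")
def er_release_profile():
    """Noiseless reference ER dissolution profile on the 1-24 h grid."""
    fixture = dk.make_study_fixture(SEED)
    method = dk.MethodFixture(medium="0.9% NaCl", apparatus="paddle_sinker", speed_rpm=50)
    return dk.simulate_dissolution(
        fixture.products["Reference"], method, n_units=1, seed=0, noise_cv=0.0
    )


@pytest.fixture(scope="session")
def observed_plasma(disposition, absorption):
    """Forward-simulated reference plasma curve (noise-free stand-in)."""
    from dissopk.dissolution import WeibullParams, weibull_release

    t = np.arange(0.25, 36.01, 0.25)
    frac = weibull_release(t, WeibullParams(fmax=95, td=7.1, b=0.9)) / 100.0
    return dk.simulate_observed_plasma(disposition, absorption, (t, frac), noise_cv=0.0)
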