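import pytest
from hypothesis import HealthCheck, settings

import cutisim as cs
from cutisim import HOUR

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def defaults() -> cs.ModelParameters:
    """Calibrated CaCl2 + RSO 5 parameter set (1 g/L, 70 %RH, 20 C)."""
    return cs.ModelParameters()


@pytest.fixture(scope="session")
def derived(defaults):
    return cs.derive_constants(defaults)


@pytest.fixture(scope="session")
def baseline_result(defaults):
    """Full 48 h baseline run: 1 g/L CaCl2 + RSO 5 at 70 %RH."""
    return cs.run(defaults)


@pytest.fixture(scope="session")
def nohygro_result(defaults):
    """Same scenario with hygroscopic water absorption disabled."""
    return cs.run(defaults, hygroscopic_growth=False)


@pytest.fixture(scope="session")
def h97_result(defaults):
    return cs.run(cs.with_overrides(defaults, H=0.97))


@pytest.fixture(scope="session")
def h25_result(defaults):
    """Below the CaCl2 point of deliquescence (25 %RH < 32 %RH POD)."""
    return cs.run(cs.with_overrides(defaults, H=0.25))


@pytest.fixture(scope="session")
def coarse_params(defaults):
    """Reduced-resolution parameter set for fitting/statistics tests."""
    return cs.with_overrides(defaults, N_x=24, t_final=8 * HOUR,
                             rtol=1e-6, atol=1e-10)


@pytest.fixture(scope="session")
def coarse_result(coarse_params):
    return cs.run(coarse_params)


@pytest.fixture(scope="session")
def validation_rso5(defaults):
    return cs.validation_suite(True, defaults)


@pytest.fixture(scope="session")
def validation_plain(defaults):
    return cs.validation_suite(False, defaults)
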