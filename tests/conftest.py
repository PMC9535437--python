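import pytest
from hypothesis import HealthCheck, settings

from renoreg import GestationalCirculation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model() -> GestationalCirculation:
    """The shipped calibrated first-trimester model."""
    return GestationalCirculation.from_packaged("calibrated")


@pytest.fixture(scope="session")
def baseline(model) -> dict:
    """Beat-averaged baseline summary of the uncontrolled model."""
    return model.baseline_summary()


@pytest.fixture(scope="session")
def vc_pressure(baseline) -> float:
    return baseline["p_vc_mmhg"]
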