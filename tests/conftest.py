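import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import fbpakin as fk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    """The 7-frame whole-body acquisition (455 s frames, 45.5 s gaps)."""
    return fk.default_frame_schedule()


@pytest.fixture(scope="session")
def noiseless_study():
    """Default 11-organ synthetic study without noise."""
    return fk.make_study_fixture(fk.SimulationConfig(noise_cv=0.0))


@pytest.fixture(scope="session")
def plasma_input(noiseless_study):
    """Pipeline-reconstructed input function for the noiseless study."""
    return fk.build_plasma_input(noiseless_study.blood)
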