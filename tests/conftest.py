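import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scolibeam import (
    BeamParameters,
    REFERENCE_PROFILE,
    fit_initial_displacement,
    reference_midline,
    to_beam_frame,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_curve():
    """The bundled 29-point reference midline (mm)."""
    return reference_midline()


@pytest.fixture(scope="session")
def ref_frame(ref_curve):
    return to_beam_frame(ref_curve)


@pytest.fixture(scope="session")
def fitted(ref_frame):
    return fit_initial_displacement(ref_frame)


@pytest.fixture(scope="session")
def ref_profile():
    """The published cubic coefficients for the reference patient."""
    return REFERENCE_PROFILE


@pytest.fixture(scope="session")
def ref_params():
    """Structural constants of the reference patient."""
    return BeamParameters(EI=15.1, L=0.196, Li=0.042)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
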