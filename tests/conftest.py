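import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_fixture():
    """One positive synthetic slide (20% DAB, 33 deg) with ground truth."""
    from epiquant.synthetic import FixtureParams, generate_strip_image

    return generate_strip_image(FixtureParams(seed=7, dab_fraction=0.2, strip_angle=33))


@pytest.fixture(scope="session")
def negative_fixture():
    """A negative-control slide (no DAB)."""
    from epiquant.synthetic import FixtureParams, generate_strip_image

    return generate_strip_image(FixtureParams(seed=100, dab_fraction=0.0, strip_angle=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
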