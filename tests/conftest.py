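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


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rgb_image(rng):
    """A small random-but-valid RGB image."""
    from hsvsara import ColorImage

    return ColorImage(rng.uniform(0, 255, size=(16, 16, 3)))
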