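import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crmsnake.synthetic import PhantomSpec, make_phantom

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def u_phantom():
    """Concave binary phantom: disc with a rectangular notch."""
    return make_phantom(PhantomSpec(kind="u_shape", seed=1))


@pytest.fixture(scope="session")
def fundus_phantom():
    """Fundus-like phantom with vessels and mild noise."""
    return make_phantom(PhantomSpec(kind="disc_fundus", seed=3, noise_sd=0.01))


@pytest.fixture
def disc_image():
    """Binary bright disc, radius 30, on a 128x128 frame."""
    yy, xx = np.mgrid[0:128, 0:128]
    return ((xx - 64) ** 2 + (yy - 64) ** 2 <= 30**2).astype(float)
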