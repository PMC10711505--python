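import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungt2star import make_phantom, simulate_multiecho
from lungt2star.synthetic import DEFAULT_ECHO_TIMES

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def echo_times():
    return np.asarray(DEFAULT_ECHO_TIMES)


@pytest.fixture(scope="session")
def phantom30():
    """Thorax phantom at 30 weeks on a 48-voxel cubic grid."""
    return make_phantom(30.0, grid_shape=(48, 48, 48), seed=0)


@pytest.fixture(scope="session")
def noiseless_image(phantom30):
    return simulate_multiecho(phantom30, noise_model="none")
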