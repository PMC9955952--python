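import numpy as np
import pytest

from piradscaps.network import CapsOrdinalSegNet, NetworkConfig
from piradscaps.phantom import PhantomConfig, generate_case, generate_cohort


@pytest.fixture(scope="session")
def small_phantom_config():
    """Reduced-grid phantom settings so geometry tests stay fast."""
    return PhantomConfig(image_size=96, seed=11)


@pytest.fixture(scope="session")
def phantom_case(small_phantom_config):
    return generate_case(small_phantom_config, np.random.default_rng(5), "case_0000")


@pytest.fixture(scope="session")
def phantom_cohort_small(small_phantom_config):
    """A 6-case cohort on the reduced grid."""
    return generate_cohort(6, small_phantom_config)


@pytest.fixture(scope="session")
def desk_model():
    return CapsOrdinalSegNet(NetworkConfig.desk(seed=3))


@pytest.fixture(scope="session")
def default_model():
    return CapsOrdinalSegNet(NetworkConfig(seed=3))
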