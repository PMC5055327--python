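import numpy as np
import pytest

from t2texture import IntensityVolume, PhantomSpec, VOIMask, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20160921)


@pytest.fixture
def random_volume(rng):
    return IntensityVolume(data=rng.uniform(-50.0, 950.0, size=(8, 7, 5)))


@pytest.fixture
def sphere_mask():
    """A small blob mask on an 8x7x5 grid."""
    idx = np.indices((8, 7, 5))
    dist2 = (idx[0] - 4) ** 2 + (idx[1] - 3) ** 2 + (idx[2] - 2) ** 2
    return VOIMask(data=dist2 <= 5)


@pytest.fixture
def default_phantom_pair():
    return generate_phantom(PhantomSpec(seed=7))
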