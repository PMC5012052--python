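import numpy as np
import pytest
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(20160906)


def random_rigid_transform(rng, max_translation=100.0):
    """A uniformly random rotation matrix and translation vector."""
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


@pytest.fixture
def rigid_transform(rng):
    return random_rigid_transform(rng)
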