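import numpy as np
import pytest
from hypothesis import settings

from tomopick import Volume, default_template, make_spherical_mask

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_template():
    """A 12-box asymmetric smooth blob for rotation/matching tests."""
    return default_template(box_size=12, voxel_size=10.0)


@pytest.fixture
def small_mask():
    return make_spherical_mask(12, 5.0, voxel_size=10.0)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.standard_normal((24, 24, 24)).astype(np.float32),
                  voxel_size=10.0)
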