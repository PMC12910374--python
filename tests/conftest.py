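import numpy as np
import pytest

from celllists import PointCloud, toy_structure


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def uniform_cloud(rng):
    """300 points in a 50 A box: several cells at rc=10, mixed occupancy."""
    return PointCloud(coords=rng.uniform(0.0, 50.0, size=(300, 3)))


@pytest.fixture
def dumbbell():
    return toy_structure("dumbbell", separation=4.0)
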