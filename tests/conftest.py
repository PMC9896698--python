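import numpy as np
import pytest

from root3d.cloud import PointCloud
from root3d.synthetic import generate, taproot_spec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cloud(rng):
    pts = rng.uniform(-5, 5, (300, 3))
    return PointCloud(pts)


@pytest.fixture
def colored_cloud(rng):
    pts = rng.uniform(0, 1, (50, 3))
    cols = rng.integers(0, 256, (50, 3), dtype=np.uint8)
    return PointCloud(pts, cols)


@pytest.fixture(scope="session")
def small_taproot():
    """One small taproot specimen with ground truth, reused across tests."""
    spec = taproot_spec(depth=12.0, seed=7)
    return generate(spec)
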