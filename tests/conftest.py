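import numpy as np
import pytest

from tomolattice import DecorationSpec, make_synthetic_dataset, resample_path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_path():
    """70 nm straight filament along +z, resampled at the 7 nm ring pitch."""
    return resample_path(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 70.0]]), 7.0)


@pytest.fixture(scope="session")
def ring_dataset():
    """Noiseless ring-decorated dataset with planted truth (10 filaments)."""
    return make_synthetic_dataset(
        10, DecorationSpec(mode="ring", occupancy=0.3, seed=0), seed=7
    )


@pytest.fixture(scope="session")
def helix_dataset():
    """Noiseless helix-decorated dataset at the 33-degree geometry."""
    return make_synthetic_dataset(
        10, DecorationSpec(mode="helix", occupancy=0.3, seed=0), seed=7
    )


def random_rotation_matrices(n, seed=0):
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()
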