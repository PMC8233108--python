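import numpy as np
import pytest

from myeloconn import LabelVolume, ScalarVolume, Tractogram, WeightedConnectome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles (nodes 0-2 and 3-5)."""
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
        A[a, b] = A[b, a] = 1.0
    return A


@pytest.fixture
def two_cliques():
    """Two disconnected unit-weight 5-cliques."""
    A = np.zeros((10, 10))
    for grp in (range(5), range(5, 10)):
        for i in grp:
            for j in grp:
                if i != j:
                    A[i, j] = 1.0
    return A


def make_volumes(shape=(10, 10, 10), voxel=1.0):
    """A label volume with two 2x2x2 blocks (labels 5 and 9) and a constant
    scalar volume on the same grid."""
    affine = np.diag([voxel] * 3 + [1.0])
    grid = np.zeros(shape, dtype=np.int32)
    grid[1:3, 1:3, 1:3] = 5
    grid[7:9, 7:9, 7:9] = 9
    labels = LabelVolume(grid, affine)
    scalar = ScalarVolume(np.full(shape, 1.1), affine)
    return labels, scalar


@pytest.fixture
def toy_volumes():
    return make_volumes()


def symmetric_connectome(rng, n=8, kind="scalar", density=0.6):
    w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
    if kind == "nos":
        w = np.rint(w * 10)
    w = w + w.T
    return WeightedConnectome(np.arange(1, n + 1), w, kind=kind)
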