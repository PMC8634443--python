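import numpy as np
import pytest

from morphnet.network import BinaryNetwork


def _net(adj):
    return BinaryNetwork(adjacency=np.asarray(adj, dtype=bool), sparsity=0.5)


@pytest.fixture
def path3():
    """Path graph A-B-C."""
    a = np.zeros((3, 3), dtype=bool)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = True
    return _net(a)


@pytest.fixture
def star6():
    """Star: hub 0 with 5 leaves."""
    a = np.zeros((6, 6), dtype=bool)
    a[0, 1:] = a[1:, 0] = True
    return _net(a)


@pytest.fixture
def k6():
    a = ~np.eye(6, dtype=bool)
    return _net(a)


@pytest.fixture
def two_triangles():
    a = np.zeros((6, 6), dtype=bool)
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = True
    return _net(a)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """A small but fully featured cohort for integration tests."""
    from morphnet.simulate import CohortSpec
    return CohortSpec(n_per_group=(4, 4, 4), grid_shape=(24, 24, 24),
                      n_regions=30, seed=11)


@pytest.fixture(scope="session")
def vbm_runs20():
    """Twenty seeded replicates of the full voxelwise recovery pipeline."""
    from morphnet import evaluation as ev
    return [ev.vbm_recovery(seed) for seed in range(20)]
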