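"""Shared fixtures: small synthetic connectomes kept session-scoped for speed."""

import numpy as np
import pytest

from netmodes import GeneratorParams, generate_cohort, generate_connectome
from netmodes.core import Connectome, EdgeTrajectorySet, Grid


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale generator settings: 20 nodes on a 32^3 grid."""
    return GeneratorParams(n_nodes=20, grid_shape=(32, 32, 32), n_hubs=4)


@pytest.fixture(scope="session")
def small_connectome(small_params):
    return generate_connectome(small_params, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params, n_subjects=6, n_scans=2, seed=5)


@pytest.fixture()
def toy_grid():
    return Grid(origin=(-16.0, -16.0, -16.0), spacing=(2.0, 2.0, 2.0),
                shape=(17, 17, 17))


def make_two_node(weight=1.0, grid=None, n_mask=10):
    """Two-node connectome with a straight-line trajectory along x."""
    grid = grid or Grid(origin=(-16.0, -16.0, -16.0), spacing=(2.0,) * 3,
                        shape=(17, 17, 17))
    conn = Connectome(
        node_ids=["a", "b"],
        hemisphere=np.array(["L", "R"]),
        centroids=np.array([[-10.0, 0.0, 0.0], [10.0, 0.0, 0.0]]),
        volumes=np.array([10.0, 10.0]),
        adjacency=np.array([[0.0, weight], [weight, 0.0]]),
    )
    xs = np.linspace(3, 3 + n_mask - 1, n_mask).astype(int) % grid.shape[0]
    vox = np.column_stack([xs, np.full(n_mask, 8), np.full(n_mask, 8)])
    counts = np.full(n_mask, 5.0)
    traj = EdgeTrajectorySet(grid=grid, directed={(0, 1): (vox, counts),
                                                  (1, 0): (vox, counts)})
    traj.build_consensus(retain_fraction=1.0)
    return conn, traj


@pytest.fixture()
def two_node():
    return make_two_node()
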