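"""Virtual lesions: sphere voxelization, edge weakening, importance maps."""

import numpy as np
import pytest

from netmodes import (
    Lesion,
    apply_lesion,
    build_laplacian,
    eigendecompose,
    importance_at,
    importance_maps,
    stoppage_sweep,
    voxelize_sphere,
)
from netmodes.core import DataInconsistencyError, Grid, InvalidInputError
from conftest import make_two_node


class TestVoxelizeSphere:
    def test_tiny_sphere_is_single_voxel(self, toy_grid):
        center = toy_grid.voxel_to_world([8, 8, 8])
        vox = voxelize_sphere(Lesion(center=center, diameter=1.0), toy_grid)
        np.testing.assert_array_equal(vox, [[8, 8, 8]])

    def test_brute_force_count_at_1mm(self):
        # integer lattice at 1 mm: voxels within radius 6 of the center
        grid = Grid(origin=(-20.0, -20.0, -20.0), spacing=(1.0,) * 3,
                    shape=(41, 41, 41))
        vox = voxelize_sphere(Lesion(center=(0.0, 0.0, 0.0), diameter=12.0),
                              grid)
        ax = np.arange(-8, 9)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        expected = int(np.sum(np.sum(pts**2, axis=1) <= 36))
        assert len(vox) == expected

    def test_sphere_outside_grid_is_empty(self, toy_grid):
        with pytest.warns(UserWarning):
            vox = voxelize_sphere(Lesion(center=(500.0, 0.0, 0.0),
                                         diameter=12.0), toy_grid)
        assert len(vox) == 0

    def test_invalid_lesion_parameters(self):
        with pytest.raises(InvalidInputError):
            Lesion(center=(0, 0, 0), diameter=-1.0)
        with pytest.raises(InvalidInputError):
            Lesion(center=(0, 0, 0), stoppage=0.0)
        with pytest.raises(InvalidInputError):
            Lesion(center=(0, 0, 0), stoppage=1.5)


class TestApplyLesion:
    def test_edge_fully_covered_is_removed(self, two_node):
        conn, traj = two_node
        center = traj.grid.voxel_to_world([7, 8, 8])
        lesion = Lesion(center=center, diameter=100.0, stoppage=1.0)
        out = apply_lesion(conn, traj, lesion)
        assert out.adjacency[0, 1] == 0.0

    def test_vanishing_stoppage_leaves_graph_unchanged(self, two_node):
        conn, traj = two_node
        center = traj.grid.voxel_to_world([7, 8, 8])
        out = apply_lesion(conn, traj, Lesion(center=center, diameter=100.0,
                                              stoppage=1e-12))
        np.testing.assert_allclose(out.adjacency, conn.adjacency, atol=1e-9)

    def test_half_covered_edge_is_halved(self):
        conn, traj = make_two_node(weight=2.0, n_mask=10)
        # sphere covering exactly the first five mask voxels (x indices 3..7)
        covered = traj.grid.voxel_to_world(traj.consensus[(0, 1)][:5])
        center = covered.mean(axis=0)
        radius = np.linalg.norm(covered - center, axis=1).max() + 0.5
        out = apply_lesion(conn, traj, Lesion(center=center,
                                              diameter=2 * radius, stoppage=1.0))
        assert out.adjacency[0, 1] == pytest.approx(1.0)

    def test_positive_weight_without_mask_rejected(self, two_node):
        conn, traj = two_node
        bad = conn.with_adjacency(conn.adjacency)
        traj_empty = type(traj)(grid=traj.grid, directed=traj.directed,
                                consensus={})
        with pytest.raises(DataInconsistencyError):
            apply_lesion(bad, traj_empty,
                         Lesion(center=(0.0, 0.0, 0.0), diameter=12.0))


class TestImportanceAt:
    def test_lesion_missing_all_edges_gives_zero(self, two_node):
        conn, traj = two_node
        far = traj.grid.voxel_to_world([1, 1, 1])
        val = importance_at(conn, traj, Lesion(center=far, diameter=2.0))
        assert val == 0.0

    def test_two_node_closed_form(self, two_node):
        # unit edge: lambda_2 = 2; full removal -> importance = 2, with the
        # graph disconnecting (flagged by a warning)
        conn, traj = two_node
        center = traj.grid.voxel_to_world([7, 8, 8])
        with pytest.warns(UserWarning, match="disconnected"):
            val = importance_at(conn, traj,
                                Lesion(center=center, diameter=100.0,
                                       stoppage=1.0), mode=2)
        assert val == pytest.approx(2.0)

    def test_first_order_perturbation_oracle(self, small_connectome):
        """For small perturbations the eigenvalue decrease equals the
        quadratic form of the Laplacian change on the unperturbed mode."""
        conn, traj = small_connectome
        ref = eigendecompose(build_laplacian(conn))
        wm = traj.white_matter_voxels()
        rng = np.random.default_rng(12)
        centers = traj.grid.voxel_to_world(
            wm[rng.choice(len(wm), size=25, replace=False)])
        L0 = build_laplacian(conn).matrix
        checked = 0
        for center in centers:
            lesion = Lesion(center=center, diameter=12.0, stoppage=0.05)
            lesioned = apply_lesion(conn, traj, lesion)
            dL = L0 - build_laplacian(lesioned).matrix
            v = ref.eigenvector(2)
            estimate = v @ dL @ v
            if estimate < 1e-9:
                continue
            value = importance_at(conn, traj, lesion, reference=ref, mode=2)
            assert abs(value - estimate) / value < 0.1
            checked += 1
        assert checked >= 10


class TestImportanceMaps:
    def test_support_limited_to_dilated_edge_mask(self, two_node):
        conn, traj = two_node
        maps = importance_maps(conn, traj, modes=(2,), stoppages=(1.0,),
                               stride=1, diameter=6.0)
        imap = maps[(2, 1.0)]
        nz = np.argwhere(imap.values != 0)
        mask_mm = traj.grid.voxel_to_world(traj.consensus[(0, 1)])
        for vox in nz:
            d = np.linalg.norm(mask_mm - traj.grid.voxel_to_world(vox),
                               axis=1).min()
            assert d <= 3.0 + 1e-9  # within the lesion radius of the mask

    def test_nonnegative_with_identity_matching(self, small_connectome):
        # weight decreases cannot raise eigenvalues (Weyl monotonicity)
        conn, traj = small_connectome
        maps = importance_maps(conn, traj, modes=(2, 3), stoppages=(1.0,),
                               stride=3, window=0)
        for m in maps.values():
            assert m.evaluated_values().min() >= -1e-9

    def test_homogeneity_in_edge_weights(self, small_connectome):
        conn, traj = small_connectome
        doubled = conn.with_adjacency(2 * conn.adjacency)
        kw = dict(modes=(2,), stoppages=(1.0,), stride=4)
        base = importance_maps(conn, traj, **kw)[(2, 1.0)]
        big = importance_maps(doubled, traj, **kw)[(2, 1.0)]
        np.testing.assert_allclose(big.evaluated_values(),
                                   2 * base.evaluated_values(), rtol=1e-8)

    def test_monotone_in_stoppage_with_identity_matching(self, small_connectome):
        conn, traj = small_connectome
        maps = importance_maps(conn, traj, modes=(2,),
                               stoppages=(0.25, 0.5, 1.0), stride=3, window=0)
        v25 = maps[(2, 0.25)].evaluated_values()
        v50 = maps[(2, 0.5)].evaluated_values()
        v100 = maps[(2, 1.0)].evaluated_values()
        assert np.all(v25 <= v50 + 1e-12)
        assert np.all(v50 <= v100 + 1e-12)


class TestStoppageSweep:
    def test_correlations_high_and_scale_invariant(self, small_connectome):
        conn, traj = small_connectome
        kw = dict(modes=(2,), stoppages=(0.25, 1.0), stride=3)
        table = stoppage_sweep(conn, traj, **kw)
        assert (table["r"] > 0.95).all()
        scaled = stoppage_sweep(conn.with_adjacency(3 * conn.adjacency),
                                traj, **kw)
        np.testing.assert_allclose(scaled["r"], table["r"], atol=1e-8)

    def test_requires_two_stoppages(self, two_node):
        conn, traj = two_node
        with pytest.raises(InvalidInputError):
            stoppage_sweep(conn, traj, stoppages=(1.0,))


def test_small_perturbation_angle_below_between_subject_angle(small_cohort):
    """A 12 mm lesion rotates an eigenmode far less than subjects differ
    from one another (about an order of magnitude in angle)."""
    from netmodes import angle_variance, average_connectomes

    subj = small_cohort.subjects[0]
    conn, traj = subj.latent, subj.trajectories
    ref = eigendecompose(build_laplacian(conn))
    wm = traj.white_matter_voxels()
    rng = np.random.default_rng(4)
    angles = []
    for k in rng.choice(len(wm), size=10, replace=False):
        center = traj.grid.voxel_to_world(wm[k])
        lesioned = apply_lesion(conn, traj, Lesion(center=center, diameter=12.0))
        sys = eigendecompose(build_laplacian(lesioned))
        av = angle_variance(ref.eigenvector(2), 2, [sys])
        angles.append(av.angles_deg[0])
    perturbation_angle = np.mean(angles)

    means = small_cohort.subject_means()
    mean_sys = eigendecompose(build_laplacian(average_connectomes(means)))
    subj_sys = [eigendecompose(build_laplacian(c)) for c in means]
    between = angle_variance(mean_sys.eigenvector(2), 2, subj_sys).mean
    assert perturbation_angle < between
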