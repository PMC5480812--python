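"""Eigendecomposition, matching, angle variance, spectra, and the diffusion solver."""

import numpy as np
import pytest

from netmodes import (
    angle_variance,
    average_connectomes,
    build_laplacian,
    eigendecompose,
    match_eigenmode,
    normalize_spectrum,
    solve_network_diffusion,
)
from netmodes.core import InvalidInputError
from netmodes.eigen import EigenSystem


def _system(A):
    return eigendecompose(build_laplacian(np.asarray(A, float)))


class TestEigendecompose:
    def test_connected_graph_has_single_zero_mode(self, small_connectome):
        conn, _ = small_connectome
        sys = eigendecompose(build_laplacian(conn))
        scale = sys.eigenvalues[-1]
        assert abs(sys.eigenvalues[0]) < 1e-9 * scale
        assert sys.eigenvalues[1] > 1e-9 * scale
        assert sys.n_zero_modes() == 1

    def test_two_component_graph_has_two_zero_modes(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 2.0
        sys = _system(A)
        assert sys.n_zero_modes() == 2

    def test_complete_graph_spectrum(self):
        A = np.ones((4, 4)) - np.eye(4)
        np.testing.assert_allclose(_system(A).eigenvalues, [0, 4, 4, 4],
                                   atol=1e-12)

    def test_orthonormal_and_reconstructs(self, small_connectome):
        conn, _ = small_connectome
        L = build_laplacian(conn).matrix
        sys = eigendecompose(L)
        Q = sys.eigenvectors
        np.testing.assert_allclose(Q.T @ Q, np.eye(len(L)), atol=1e-10)
        recon = Q @ np.diag(sys.eigenvalues) @ Q.T
        assert np.linalg.norm(recon - L) < 1e-8 * np.linalg.norm(L)

    def test_asymmetric_rejected(self):
        with pytest.raises(InvalidInputError):
            eigendecompose(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestMatchEigenmode:
    @pytest.fixture()
    def sys5(self):
        rng = np.random.default_rng(0)
        A = rng.random((6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        return _system(A)

    def test_self_match_is_identity(self, sys5):
        m = match_eigenmode(sys5.eigenvector(3), 3, sys5)
        assert m.matched_index == 3
        assert m.sign == 1
        assert m.inner_product == pytest.approx(1.0)
        assert m.step_offset == 0

    def test_sign_reversal_detected(self, sys5):
        flipped = EigenSystem(sys5.eigenvalues, -sys5.eigenvectors)
        m = match_eigenmode(sys5.eigenvector(3), 3, flipped)
        assert m.matched_index == 3
        assert m.sign == -1
        assert m.inner_product == pytest.approx(1.0)

    def test_swapped_neighbours_give_step_offset(self, sys5):
        Q = sys5.eigenvectors.copy()
        Q[:, [2, 3]] = Q[:, [3, 2]]  # swap modes 3 and 4
        swapped = EigenSystem(sys5.eigenvalues, Q)
        m = match_eigenmode(sys5.eigenvector(3), 3, swapped)
        assert m.matched_index == 4
        assert m.step_offset == 1

    def test_window_limits_search(self, sys5):
        Q = np.roll(sys5.eigenvectors, 3, axis=1)
        rolled = EigenSystem(sys5.eigenvalues, Q)
        m = match_eigenmode(sys5.eigenvector(1), 1, rolled, window=1)
        assert m.matched_index <= 2  # true match at offset 3 is out of reach

    def test_orthogonal_reference_warns(self):
        # single candidate mode orthogonal to the reference: no real match
        one_mode = EigenSystem(np.array([0.0]), np.array([[1.0], [0.0]]))
        with pytest.warns(UserWarning):
            match_eigenmode(np.array([0.0, 1.0]), 1, one_mode, window=None)


class TestAngleVariance:
    def test_zero_angle_for_self_and_negated(self, small_connectome):
        conn, _ = small_connectome
        sys = eigendecompose(build_laplacian(conn))
        neg = EigenSystem(sys.eigenvalues, -sys.eigenvectors)
        av = angle_variance(sys.eigenvector(2), 2, [sys, neg])
        np.testing.assert_allclose(av.angles_deg, [0.0, 0.0], atol=1e-6)

    def test_orthogonal_candidate_is_90_degrees(self):
        sys = EigenSystem(np.array([0.0]), np.array([[0.0], [1.0]]))
        av = angle_variance(np.array([1.0, 0.0]), 1, [sys])
        assert av.angles_deg[0] == pytest.approx(90.0)


class TestNormalizeSpectrum:
    def test_hand_example(self):
        np.testing.assert_allclose(normalize_spectrum([0.0, 2.0, 4.0]),
                                   [0.0, 1.0, 2.0])

    def test_constant_spectrum(self):
        np.testing.assert_allclose(normalize_spectrum([3.0, 3.0, 3.0]),
                                   [1.0, 1.0, 1.0])

    def test_output_mean_is_one(self, small_connectome):
        conn, _ = small_connectome
        lam = eigendecompose(build_laplacian(conn)).eigenvalues
        assert normalize_spectrum(lam).mean() == pytest.approx(1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ZeroDivisionError):
            normalize_spectrum([0.0, 0.0])


class TestNetworkDiffusion:
    def test_t_zero_is_identity(self, small_connectome):
        conn, _ = small_connectome
        L = build_laplacian(conn)
        x0 = np.arange(conn.n_nodes, dtype=float)
        np.testing.assert_allclose(solve_network_diffusion(L, x0, t=0.0), x0,
                                   atol=1e-9)

    def test_steady_state_is_uniform_mean(self, small_connectome):
        conn, _ = small_connectome
        L = build_laplacian(conn)
        x0 = np.arange(conn.n_nodes, dtype=float)
        xt = solve_network_diffusion(L, x0, beta=1.0, t=1e6)
        np.testing.assert_allclose(xt, np.full_like(x0, x0.mean()), atol=1e-6)

    def test_two_node_closed_form(self):
        # x1(t) = 1/2 + 1/2 exp(-2 t); at t = ln(2)/2 -> 0.75
        L = build_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        xt = solve_network_diffusion(L, np.array([1.0, 0.0]), beta=1.0,
                                     t=np.log(2) / 2)
        np.testing.assert_allclose(xt, [0.75, 0.25], atol=1e-12)

    def test_mass_conservation(self, small_connectome):
        conn, _ = small_connectome
        L = build_laplacian(conn)
        rng = np.random.default_rng(1)
        x0 = rng.random(conn.n_nodes)
        for t in (0.1, 1.0, 10.0):
            xt = solve_network_diffusion(L, x0, t=t)
            assert abs(xt.sum() - x0.sum()) < 1e-9 * abs(x0.sum())

    def test_per_mode_exponential_decay(self, small_connectome):
        # an initial state along eigenmode i decays as exp(-beta lambda_i t)
        conn, _ = small_connectome
        L = build_laplacian(conn)
        sys = eigendecompose(L)
        beta, t = 0.7, 0.3
        for mode in (2, 4):
            v = sys.eigenvector(mode)
            xt = solve_network_diffusion(L, v, beta=beta, t=t, system=sys)
            expected = np.exp(-beta * sys.eigenvalue(mode) * t)
            assert v @ xt == pytest.approx(expected, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        L = build_laplacian(np.zeros((2, 2)))
        with pytest.raises(InvalidInputError):
            solve_network_diffusion(L, np.zeros(2), beta=-1.0, t=1.0)
        with pytest.raises(InvalidInputError):
            solve_network_diffusion(L, np.zeros(2), t=-1.0)


class TestAverageConnectomes:
    def test_identity_and_halving(self, small_connectome):
        conn, _ = small_connectome
        same = average_connectomes([conn, conn])
        np.testing.assert_allclose(same.adjacency, conn.adjacency)
        halved = average_connectomes([conn, conn.with_adjacency(
            np.zeros_like(conn.adjacency))])
        np.testing.assert_allclose(halved.adjacency, conn.adjacency / 2)

    def test_mean_preserves_symmetry_and_diagonal(self, small_cohort):
        mean = average_connectomes(small_cohort.all_scans())
        np.testing.assert_allclose(mean.adjacency, mean.adjacency.T)
        assert np.all(np.diag(mean.adjacency) == 0)

    def test_node_set_mismatch_rejected(self, small_connectome):
        conn, _ = small_connectome
        other = average_connectomes([conn])
        other.node_ids = list(reversed(other.node_ids))
        with pytest.raises(InvalidInputError):
            average_connectomes([conn, other])


def test_second_mode_separates_hemispheres(small_connectome):
    """Weak interhemispheric coupling makes the Fiedler mode the left-right
    gradient: the sign of v2 labels the hemispheres exactly."""
    conn, _ = small_connectome
    sys = eigendecompose(build_laplacian(conn))
    v2 = sys.eigenvector(2)
    left = conn.hemisphere == "L"
    assert len(np.unique(np.sign(v2[left]))) == 1
    assert len(np.unique(np.sign(v2[~left]))) == 1
    assert np.sign(v2[left][0]) != np.sign(v2[~left][0])
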