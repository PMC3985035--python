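"""Stiffness assembly, interpolation, matching stiffness, energy and the robust loop."""

import numpy as np
import pytest
from scipy import sparse

from pbnrr import fem_solver as fs
from pbnrr.fem_solver import (
    MaterialParams,
    SolverParams,
    assemble_interpolation,
    assemble_matching_stiffness,
    assemble_stiffness,
    average_node_stiffness,
    block_diag,
    element_stiffness,
    energy,
    robust_solve,
    solve_approximation,
)
from pbnrr.mesh import Mesh, build_rectilinear_mesh, _gauss_points

from conftest import full_mask


@pytest.fixture
def unit_hex():
    nodes = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                      (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], float)
    return Mesh(nodes, np.arange(8)[None, :], "hex8")


@pytest.fixture
def mesh3d():
    return build_rectilinear_mesh(full_mask((21, 21, 21)), 10.0)


@pytest.fixture
def mesh2d():
    return build_rectilinear_mesh(full_mask((41, 41)), 20.0)


MAT = MaterialParams(youngs_modulus=700.0, poisson_ratio=0.45)


class TestStiffness:
    def test_rigid_translation_null_space(self, unit_hex):
        K = assemble_stiffness(unit_hex, MAT)
        scale = np.abs(K.toarray()).max()
        for ax in range(3):
            t = np.zeros(24)
            t[ax::3] = 1.0
            assert np.max(np.abs(K @ t)) < 1e-10 * scale

    def test_symmetry_and_six_zero_modes(self, unit_hex):
        K = assemble_stiffness(unit_hex, MAT).toarray()
        assert np.max(np.abs(K - K.T)) < 1e-8 * np.abs(K).max()
        vals = np.linalg.eigvalsh(K)
        scale = vals.max()
        assert np.sum(np.abs(vals) < 1e-9 * scale) == 6  # 3 translations + 3 rotations
        assert np.all(vals > -1e-9 * scale)

    def test_matches_high_order_quadrature(self, unit_hex):
        from itertools import product

        Ke = element_stiffness(unit_hex, 0, MAT)
        # 4-point Gauss-Legendre per axis as the slow oracle
        x, w = np.polynomial.legendre.leggauss(4)
        pts = np.array(list(product(x, repeat=3)))
        wts = np.array([wa * wb * wc for wa, wb, wc in product(w, repeat=3)])
        Ko = element_stiffness(unit_hex, 0, MAT, quad_points=(pts, wts))
        assert np.max(np.abs(Ke - Ko)) < 1e-6 * np.abs(Ko).max()

    def test_2d_element_rigid_modes(self, mesh2d):
        K = assemble_stiffness(mesh2d, MAT)
        scale = np.abs(K.data).max()
        for ax in range(2):
            t = np.zeros(2 * mesh2d.n)
            t[ax::2] = 1.0
            assert np.max(np.abs(K @ t)) < 1e-8 * scale


class TestInterpolation:
    def test_point_at_node_identity_block(self, mesh3d):
        H, kept = assemble_interpolation(mesh3d, mesh3d.nodes[7][None, :])
        assert list(kept) == [0]
        row = H.toarray().reshape(3, mesh3d.n, 3)
        np.testing.assert_allclose(row[:, 7, :], np.eye(3), atol=1e-12)
        row[:, 7, :] = 0
        assert np.max(np.abs(row)) < 1e-12

    def test_linear_field_reproduction(self, mesh3d, rng):
        A = rng.standard_normal((3, 3))
        b = rng.standard_normal(3)
        nodal = (mesh3d.nodes @ A.T + b).ravel()
        pts = rng.uniform(mesh3d.nodes.min(0), mesh3d.nodes.max(0), size=(50, 3))
        H, kept = assemble_interpolation(mesh3d, pts)
        expected = (pts[kept] @ A.T + b).ravel()
        assert np.max(np.abs(H @ nodal - expected)) < 1e-9

    def test_constant_reproduction(self, mesh2d, rng):
        pts = rng.uniform(mesh2d.nodes.min(0), mesh2d.nodes.max(0), size=(20, 2))
        H, kept = assemble_interpolation(mesh2d, pts)
        c = np.tile([3.0, -4.0], mesh2d.n)
        np.testing.assert_allclose((H @ c).reshape(-1, 2),
                                   np.tile([3.0, -4.0], (len(kept), 1)), atol=1e-12)

    def test_all_points_outside_raises(self, mesh2d):
        with pytest.raises(fs.SolverError):
            assemble_interpolation(mesh2d, np.array([[1e5, 1e5]]))


class TestMatchingStiffness:
    def test_zero_confidence_zero_block(self):
        S = assemble_matching_stiffness([0.0, 1.0], balance=1.0, n_nodes=10,
                                        sigma=5.0, d=3)
        assert np.all(S[0] == 0)

    def test_reduces_to_scale(self):
        S = assemble_matching_stiffness([1.0], balance=1.0, n_nodes=1, sigma=4.2, d=2)
        np.testing.assert_allclose(S[0], 4.2 * np.eye(2))

    def test_tensor_weighting_constrains_edge_normal_only(self):
        # one quad element, a single point with a rank-1 tensor along axis 0:
        # the solve must fit the axis-0 component of D and ignore axis 1
        nodes = np.array([(0, 0), (10, 0), (10, 10), (0, 10)], float)
        mesh = Mesh(nodes, np.array([[0, 1, 2, 3]]), "quad4")
        K = assemble_stiffness(mesh, MAT)
        H, kept = assemble_interpolation(mesh, np.array([[5.0, 5.0]]))
        T = np.array([[[1.0, 0.0], [0.0, 0.0]]])
        sigma = average_node_stiffness(K, mesh) * 50  # strong data term
        S = assemble_matching_stiffness([1.0], tensors=T, balance=1.0,
                                        n_nodes=4, sigma=sigma, d=2)
        # S_k = lambda * c * (n/p) * sigma * d * T/tr(T) with n/p = 4, d = 2
        np.testing.assert_allclose(S[0], [[sigma * 8, 0], [0, 0]], atol=1e-9)
        D = np.array([3.0, 5.0])
        U = solve_approximation(K, H, S, D)
        fit = (H @ U).reshape(2)
        assert fit[0] == pytest.approx(3.0, rel=0.05)   # constrained axis follows D
        assert abs(fit[1]) < 0.5                         # orthogonal component ignored

    def test_zero_tensor_falls_back_to_isotropic(self):
        S = assemble_matching_stiffness([1.0], tensors=np.zeros((1, 3, 3)),
                                        balance=2.0, n_nodes=6, sigma=1.0, d=3)
        np.testing.assert_allclose(S[0], 2.0 * 6 * np.eye(3))

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            assemble_matching_stiffness([], balance=1.0, n_nodes=1, sigma=1.0, d=3)


def _system(mesh, rng, npts=60, sigma=None):
    K = assemble_stiffness(mesh, MAT)
    pts = rng.uniform(mesh.nodes.min(0) + 0.5, mesh.nodes.max(0) - 0.5,
                      size=(npts, mesh.ndim))
    H, kept = assemble_interpolation(mesh, pts)
    if sigma is None:
        sigma = average_node_stiffness(K, mesh)
    S = assemble_matching_stiffness(np.ones(len(kept)), balance=1.0,
                                    n_nodes=mesh.n, sigma=sigma, d=mesh.ndim)
    return K, H, S, kept


class TestSolve:
    def test_homogeneous_system(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        U = solve_approximation(K, H, S, np.zeros(H.shape[0]))
        assert np.max(np.abs(U)) < 1e-12

    def test_constant_translation_exact(self, mesh3d, rng):
        K, H, S, kept = _system(mesh3d, rng)
        t = np.array([2.0, -1.0, 0.5])
        D = np.tile(t, len(kept))
        U = solve_approximation(K, H, S, D)
        np.testing.assert_allclose(U.reshape(-1, 3), np.tile(t, (mesh3d.n, 1)),
                                   atol=1e-8)

    def test_matches_dense_solve(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0])
        U = solve_approximation(K, H, S, D)
        Sd = block_diag(S)
        A = (K + H.T @ Sd @ H).toarray()
        U_dense = np.linalg.solve(A, H.T @ (Sd @ D))
        assert np.max(np.abs(U - U_dense)) < 1e-8 * max(1.0, np.max(np.abs(U_dense)))

    def test_translation_equivariance(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0])
        t = np.array([5.0, -3.0])
        U0 = solve_approximation(K, H, S, D)
        U1 = solve_approximation(K, H, S, D + np.tile(t, len(kept)))
        np.testing.assert_allclose(U1.reshape(-1, 2) - U0.reshape(-1, 2),
                                   np.tile(t, (mesh2d.n, 1)), atol=1e-8)

    def test_residual_contract(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0]) * 10
        U = solve_approximation(K, H, S, D, linear_tol=1e-10)
        Sd = block_diag(S)
        A = K + H.T @ Sd @ H
        rhs = H.T @ (Sd @ D)
        assert np.linalg.norm(A @ U - rhs) / np.linalg.norm(rhs) <= 1e-8


class TestEnergy:
    def test_zero_state(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        assert energy(K, H, S, np.zeros(H.shape[0]), np.zeros(2 * mesh2d.n)) == 0.0

    def test_stationarity_of_solution(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0]) * 5
        U = solve_approximation(K, H, S, D)
        Sd = block_diag(S)
        grad = 2 * (K @ U) + 2 * (H.T @ (Sd @ (H @ U - D)))
        scale = np.linalg.norm(2 * (H.T @ (Sd @ D)))
        assert np.linalg.norm(grad) <= 1e-6 * scale

    def test_solution_is_global_minimum(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0]) * 5
        U = solve_approximation(K, H, S, D)
        e0 = energy(K, H, S, D, U)
        for _ in range(100):
            perturbed = U + rng.standard_normal(U.size) * rng.uniform(0.01, 1.0)
            assert energy(K, H, S, D, perturbed) >= e0

    def test_both_terms_nonnegative(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        U = rng.standard_normal(2 * mesh2d.n)
        D = rng.standard_normal(H.shape[0])
        Sd = block_diag(S)
        r = H @ U - D
        assert U @ (K @ U) >= -1e-9
        assert r @ (Sd @ r) >= -1e-9


class TestRobustLoop:
    def test_reduces_to_single_solve(self, mesh2d, rng):
        K, H, S, kept = _system(mesh2d, rng)
        D = rng.standard_normal(H.shape[0]) * 3
        params = SolverParams(n_outlier_iters=0, n_interp_iters=0)
        states = robust_solve(K, H, S, D, params, d=2)
        assert len(states) == 1
        np.testing.assert_allclose(states[0].U, solve_approximation(K, H, S, D),
                                   atol=1e-10)

    def test_interpolation_convergence_clean_data(self, mesh3d, rng):
        # mesh-representable data: residual must shrink monotonically
        K = assemble_stiffness(mesh3d, MAT)
        ax = np.linspace(mesh3d.nodes.min(0)[0] + 1, mesh3d.nodes.max(0)[0] - 1, 6)
        pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
        H, kept = assemble_interpolation(mesh3d, pts)
        U_true = np.sin(mesh3d.nodes / 12.0).ravel()
        D = H @ U_true
        S = assemble_matching_stiffness(
            np.ones(len(kept)), balance=1.0, n_nodes=mesh3d.n,
            sigma=average_node_stiffness(K, mesh3d), d=3)
        states = robust_solve(K, H, S, D,
                              SolverParams(n_outlier_iters=0, n_interp_iters=10), d=3)
        res = [np.nanmax(s.per_point_error) for s in states]
        assert all(res[i + 1] <= res[i] + 1e-9 for i in range(len(res) - 1))
        assert res[-1] < 0.10 * res[0]

    def test_outlier_recovery(self, mesh2d, rng):
        # smooth field + 10% gross outliers: LTS must capture >= 80% of them
        K = assemble_stiffness(mesh2d, MAT)
        pts = rng.uniform(mesh2d.nodes.min(0) + 1, mesh2d.nodes.max(0) - 1,
                          size=(200, 2))
        H, kept = assemble_interpolation(mesh2d, pts)
        smooth = np.column_stack([np.sin(pts[:, 0] / 15), np.cos(pts[:, 1] / 15)])
        D = smooth.copy()
        labels = rng.choice(200, size=20, replace=False)
        D[labels] += rng.standard_normal((20, 2)) * 10  # 10x magnitude
        S = assemble_matching_stiffness(
            np.ones(200), balance=1.0, n_nodes=mesh2d.n,
            sigma=average_node_stiffness(K, mesh2d), d=2)
        states = robust_solve(K, H, S, D.ravel(),
                              SolverParams(outlier_fraction=0.05, n_outlier_iters=5,
                                           n_interp_iters=0), d=2)
        rejected = set(np.flatnonzero(~states[-1].inlier_mask))
        assert len(rejected & set(labels)) >= 0.8 * len(labels)

    def test_rejection_never_empties_point_set(self, mesh2d, rng):
        # floor(fraction * inliers) reaches 0 before the last point could go,
        # so aggressive schedules terminate early with inliers remaining
        K, H, S, kept = _system(mesh2d, rng, npts=4)
        D = rng.standard_normal(H.shape[0]) * 5
        states = robust_solve(K, H, S, D,
                              SolverParams(outlier_fraction=0.49, n_outlier_iters=50,
                                           n_interp_iters=0), d=2)
        assert states[-1].inlier_mask.sum() >= 1
        assert len(states) < 51
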