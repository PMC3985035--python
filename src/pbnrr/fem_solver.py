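"""Robust linear-elastic finite-element scattered-data approximation.

The dense deformation is the minimiser of the energy

    W(U) = U^T K U + (H U - D)^T S (H U - D)

where K is the linear-elastic stiffness matrix of the mesh, H interpolates
nodal displacements to the p registration points through element shape
functions, D stacks the sparse block-matching displacements, and S is a
block-diagonal matching stiffness whose d x d blocks

    S_k = lambda * c_k * (n / p) * S_k^avg

weight each point by its matching confidence c_k, balance the data term
against the elastic regulariser (lambda), and normalise away the mesh and
point-set sizes (n/p).  S_k^avg carries stiffness units: sigma * I for
isotropic weighting, or the trace-normalised structure tensor for
anisotropic weighting that trusts only the edge-normal motion component
(aperture problem).

Setting dW/dU = 0 gives the linear system  [K + H^T S H] U = H^T S D.  The
robust loop has two phases:

* outlier rejection (least-trimmed-squares flavour): solve, rank the
  current inliers by residual ||(HU - D)_k||, discard the worst fraction,
  re-solve;
* approximation -> interpolation: iterate U_{i+1} = [K + H^T S H]^{-1}
  [H^T S D + K U_i].  Feeding the internal elastic force F = K U_i back as
  an external force progressively cancels the regulariser's pull, so the
  solution converges from the smooth approximation toward interpolating
  the surviving inliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .mesh import Mesh, _gauss_points, _jacobian, locate_point, shape_gradients

__all__ = [
    "MaterialParams",
    "SolverParams",
    "SolverState",
    "assemble_stiffness",
    "assemble_interpolation",
    "assemble_matching_stiffness",
    "solve_approximation",
    "robust_solve",
    "energy",
]


class SolverError(RuntimeError):
    pass


@dataclass
class MaterialParams:
    """Isotropic linear-elastic material; soft-tissue-scale defaults."""

    youngs_modulus: float = 700.0  # Pa
    poisson_ratio: float = 0.45

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


@dataclass
class SolverParams:
    balance: float = 1.0              # lambda
    outlier_fraction: float = 0.05    # per rejection round
    n_outlier_iters: int = 5
    n_interp_iters: int = 10
    stiffness_scale: float | None = None  # sigma; default: interior-node stiffness of K
    use_tensors: bool = False
    linear_tol: float = 1e-10
    force_in_rejection: bool = True   # recompute F = K U during phase 1

    def __post_init__(self):
        if self.balance <= 0:
            raise ValueError("balance (lambda) must be positive")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must lie in [0, 0.5)")


@dataclass
class SolverState:
    U: np.ndarray
    energy: float
    inlier_mask: np.ndarray
    per_point_error: np.ndarray  # mm, NaN at rejected points
    phase: str = ""


def _elasticity_matrix(material: MaterialParams, d: int) -> np.ndarray:
    """Isotropic elasticity tensor in Voigt form; plane strain in 2D."""
    E, nu = material.youngs_modulus, material.poisson_ratio
    f = E / ((1 + nu) * (1 - 2 * nu))
    if d == 2:
        return f * np.array(
            [[1 - nu, nu, 0.0], [nu, 1 - nu, 0.0], [0.0, 0.0, (1 - 2 * nu) / 2]]
        )
    C = np.zeros((6, 6))
    C[:3, :3] = nu
    np.fill_diagonal(C[:3, :3], 1 - nu)
    C[3:, 3:] = np.eye(3) * (1 - 2 * nu) / 2
    return f * C


def _strain_matrix(dN: np.ndarray) -> np.ndarray:
    """B matrix mapping stacked nodal displacements to Voigt strain.

    dN holds physical shape-function gradients, shape (nodes, d)."""
    nn, d = dN.shape
    if d == 2:
        B = np.zeros((3, 2 * nn))
        B[0, 0::2] = dN[:, 0]
        B[1, 1::2] = dN[:, 1]
        B[2, 0::2] = dN[:, 1]
        B[2, 1::2] = dN[:, 0]
    else:
        B = np.zeros((6, 3 * nn))
        B[0, 0::3] = dN[:, 0]
        B[1, 1::3] = dN[:, 1]
        B[2, 2::3] = dN[:, 2]
        B[3, 0::3] = dN[:, 1]
        B[3, 1::3] = dN[:, 0]
        B[4, 1::3] = dN[:, 2]
        B[4, 2::3] = dN[:, 1]
        B[5, 0::3] = dN[:, 2]
        B[5, 2::3] = dN[:, 0]
    return B


def element_stiffness(mesh: Mesh, e: int, material: MaterialParams,
                      quad_points=None) -> np.ndarray:
    """Single-element integral of B^T C B over the element."""
    d = mesh.ndim
    el = mesh.elements[e]
    C = _elasticity_matrix(material, d)
    if quad_points is None:
        pts, wts = _gauss_points(mesh.element_type)
    else:
        pts, wts = quad_points
    nn = len(el)
    Ke = np.zeros((d * nn, d * nn))
    for xi, w in zip(pts, wts):
        J = _jacobian(mesh, el, xi)
        detJ = np.linalg.det(J)
        if detJ <= 0:
            raise SolverError(f"element {e}: non-positive Jacobian during assembly")
        dN = shape_gradients(mesh.element_type, xi) @ np.linalg.inv(J)
        B = _strain_matrix(dN)
        Ke += w * detJ * (B.T @ C @ B)
    return Ke


def assemble_stiffness(mesh: Mesh, material: MaterialParams) -> sparse.csr_matrix:
    """Global stiffness K (dn x dn), symmetric PSD with rigid-body null space."""
    d = mesh.ndim
    n = mesh.n
    rows, cols, vals = [], [], []
    for e in range(len(mesh.elements)):
        Ke = element_stiffness(mesh, e, material)
        dofs = (d * mesh.elements[e][:, None] + np.arange(d)).ravel()
        r, c = np.meshgrid(dofs, dofs, indexing="ij")
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(Ke.ravel())
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(d * n, d * n),
    ).tocsr()
    return (K + K.T) / 2  # symmetrise away assembly round-off


def assemble_interpolation(mesh: Mesh, points) -> tuple[sparse.csr_matrix, np.ndarray]:
    """H (dp_kept x dn): row-block k holds shape weights of point k's element.

    Points outside the mesh are dropped; the kept-point index list is
    returned alongside.  Raises when no point can be located.
    """
    d = mesh.ndim
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rows, cols, vals = [], [], []
    kept = []
    for k, pt in enumerate(points):
        loc = locate_point(mesh, pt)
        if loc is None:
            continue
        kk = len(kept)
        kept.append(k)
        el = mesh.elements[loc.element_id]
        for node, w in zip(el, loc.weights):
            for ax in range(d):
                rows.append(d * kk + ax)
                cols.append(d * node + ax)
                vals.append(w)
    if not kept:
        raise SolverError("no registration point lies inside the mesh")
    H = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(d * len(kept), d * mesh.n)
    ).tocsr()
    return H, np.array(kept, dtype=int)


def assemble_matching_stiffness(
    confidences,
    tensors=None,
    balance: float = 1.0,
    n_nodes: int = 1,
    sigma: float = 1.0,
    d: int = 3,
) -> np.ndarray:
    """Per-point d x d blocks S_k = lambda * c_k * (n/p) * A_k.

    A_k is sigma*I when tensors are absent, else sigma * d * T_k/trace(T_k)
    (zero tensors fall back to the isotropic block).  Returns an array of
    shape (p, d, d); use :func:`block_diag` for the sparse matrix.
    """
    c = np.asarray(confidences, dtype=float)
    p = c.size
    if p == 0:
        raise ValueError("matching stiffness needs at least one point (p >= 1)")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    S = np.empty((p, d, d))
    eye = np.eye(d)
    for k in range(p):
        A = sigma * eye
        if tensors is not None:
            T = np.asarray(tensors[k], dtype=float)
            tr = np.trace(T)
            if tr > 0:
                A = sigma * d * T / tr
        S[k] = balance * c[k] * (n_nodes / p) * A
    return S


def average_node_stiffness(K: sparse.spmatrix, mesh: Mesh) -> float:
    """Default magnitude of S_k^avg: the (trace-average) diagonal stiffness
    of a fully-connected interior node of K.

    A registration point weighted this way behaves like an elastic node of
    the model: displacing it meets the same resistance as displacing an
    interior mesh node.  Falls back to the maximally-connected nodes when
    the mesh has no fully surrounded node (e.g. a single element).
    """
    d = mesh.ndim
    counts = np.zeros(mesh.n, dtype=int)
    for el in mesh.elements:
        counts[el] += 1
    full = 2 ** d if mesh.element_type in ("quad4", "hex8") else counts.max()
    sel = counts >= full
    if not sel.any():
        sel = counts == counts.max()
    node_diag = np.asarray(K.diagonal()).reshape(-1, d).mean(axis=1)
    return float(node_diag[sel].mean())


def block_diag(S_blocks: np.ndarray) -> sparse.csr_matrix:
    """Sparse block-diagonal matrix from (p, d, d) blocks."""
    p, d, _ = S_blocks.shape
    return sparse.block_diag(
        [S_blocks[k] for k in range(p)], format="csr"
    ) if p else sparse.csr_matrix((0, 0))


def solve_approximation(K, H, S, D, F=None, linear_tol: float = 1e-10) -> np.ndarray:
    """Solve [K + H^T S H] U = H^T S D + F with a sparse direct factorisation."""
    S = S if sparse.issparse(S) else block_diag(np.asarray(S))
    D = np.asarray(D, dtype=float).ravel()
    A = (K + H.T @ S @ H).tocsc()
    rhs = H.T @ (S @ D)
    if F is not None:
        rhs = rhs + np.asarray(F, dtype=float).ravel()
    try:
        lu = splu(A)
    except RuntimeError as err:
        raise SolverError(
            "system factorisation failed (singular/indefinite); supply more "
            "well-distributed nonzero-confidence points or a coarser mesh"
        ) from err
    U = lu.solve(rhs)
    denom = np.linalg.norm(rhs)
    if denom > 0:
        rel = np.linalg.norm(A @ U - rhs) / denom
        if rel > max(linear_tol, 1e-8):
            # one refinement step, then re-check
            U = U + lu.solve(rhs - A @ U)
            rel = np.linalg.norm(A @ U - rhs) / denom
            if rel > max(linear_tol * 100, 1e-6):
                raise SolverError(f"linear solve did not converge (rel residual {rel:.2e})")
    if not np.all(np.isfinite(U)):
        raise SolverError("non-finite solution from linear solve")
    return U


def energy(K, H, S, D, U) -> float:
    """W(U) = U^T K U + (HU - D)^T S (HU - D)."""
    S = S if sparse.issparse(S) else block_diag(np.asarray(S))
    U = np.asarray(U, dtype=float).ravel()
    D = np.asarray(D, dtype=float).ravel()
    if K.shape[0] != U.size or H.shape[1] != U.size or H.shape[0] != D.size:
        raise ValueError("inconsistent shapes in energy evaluation")
    r = H @ U - D
    return float(U @ (K @ U) + r @ (S @ r))


def _per_point_errors(H, U, D, d: int) -> np.ndarray:
    r = (H @ U - D).reshape(-1, d)
    return np.linalg.norm(r, axis=1)


def robust_solve(K, H, S_blocks, D, params: SolverParams, d: int | None = None):
    """Run the full robust loop; returns the list of SolverState snapshots.

    Phase 1 performs ``n_outlier_iters`` rejection rounds: after each solve
    the worst ``outlier_fraction`` of current inliers (by residual norm,
    unweighted by S) are removed and the system re-solved, carrying the
    elastic force F = K U forward when ``force_in_rejection`` is set.
    Phase 2 runs ``n_interp_iters`` force-feedback iterations on the final
    inlier set, driving the solution toward interpolation of the inliers.
    """
    S_blocks = np.asarray(S_blocks, dtype=float)
    p, dd = S_blocks.shape[0], S_blocks.shape[1]
    d = dd if d is None else d
    D = np.asarray(D, dtype=float).ravel()
    if D.size != p * d:
        raise ValueError("D length inconsistent with S blocks")

    inliers = np.ones(p, dtype=bool)

    def subsystem():
        idx = np.flatnonzero(inliers)
        row_sel = (d * idx[:, None] + np.arange(d)).ravel()
        return H[row_sel], block_diag(S_blocks[idx]), D[row_sel]

    def snapshot(U, phase):
        Hs, Ss, Ds = subsystem()
        err = np.full(p, np.nan)
        err[inliers] = _per_point_errors(Hs, U, Ds, d)
        return SolverState(U.copy(), energy(K, Hs, Ss, Ds, U), inliers.copy(), err, phase)

    states = []
    Hs, Ss, Ds = subsystem()
    U = solve_approximation(K, Hs, Ss, Ds, None, params.linear_tol)
    states.append(snapshot(U, "initial"))

    # phase 1: LTS-style outlier rejection
    for it in range(params.n_outlier_iters):
        idx = np.flatnonzero(inliers)
        if len(idx) == 0:
            raise SolverError("all registration points rejected as outliers")
        err = _per_point_errors(Hs, U, Ds, d)
        n_drop = int(np.floor(params.outlier_fraction * len(idx)))
        if n_drop == 0:
            break
        worst = np.argsort(-err, kind="stable")[:n_drop]
        inliers[idx[worst]] = False
        if not inliers.any():
            raise SolverError("all registration points rejected as outliers")
        Hs, Ss, Ds = subsystem()
        F = K @ U if params.force_in_rejection else None
        U = solve_approximation(K, Hs, Ss, Ds, F, params.linear_tol)
        if not np.all(np.isfinite(U)):
            raise SolverError(f"divergence at rejection round {it}")
        states.append(snapshot(U, f"reject-{it + 1}"))

    # phase 2: approximation -> interpolation via F = K U feedback
    Hs, Ss, Ds = subsystem()
    A = (K + Hs.T @ Ss @ Hs).tocsc()
    lu = splu(A)
    rhs_data = Hs.T @ (Ss @ Ds)
    for it in range(params.n_interp_iters):
        U = lu.solve(rhs_data + K @ U)
        if not np.all(np.isfinite(U)):
            raise SolverError(f"divergence at interpolation round {it}")
        states.append(snapshot(U, f"interp-{it + 1}"))
    return states
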