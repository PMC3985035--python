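"""End-to-end physics-based non-rigid registration pipeline and evaluation.

The pipeline wires the three stages together: feature selection on the
moving (preoperative) image inside its mask, exhaustive NCC block matching
against the fixed (intraoperative) image, and the robust finite-element
scattered-data solve on a mesh of the masked object.  Nodal displacements
are rasterized to a dense displacement field on the moving grid (pointing
moving -> fixed); warping the moving image onto the fixed grid then
requires the field's inverse, computed by damped fixed-point iteration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import fem_solver, mesh as mesh_mod
from .block_matching import MatchingParams, match_all
from .feature_selection import SelectionParams, select_feature_points
from .fem_solver import MaterialParams, SolverParams
from .image_io import (
    DisplacementFieldImage,
    MaskImage,
    ScalarImage,
    index_to_physical,
    physical_to_index,
    read_mesh,
)

logger = logging.getLogger("pbnrr")

__all__ = [
    "PipelineConfig",
    "run_pbnrr",
    "solve_scattered_data",
    "rasterize_field",
    "warp_image",
    "invert_field",
    "directed_hausdorff",
    "landmark_error",
]


@dataclass
class PipelineConfig:
    """All pipeline knobs with the implementation defaults."""

    selection: SelectionParams = dc_field(default_factory=SelectionParams)
    matching: MatchingParams = dc_field(default_factory=MatchingParams)
    material: MaterialParams = dc_field(default_factory=MaterialParams)
    solver: SolverParams = dc_field(default_factory=SolverParams)
    mesh_spacing: float = 20.0  # mm, built-in rectilinear mesh pitch
    mesh_file: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"]["non_connectivity"] = self.selection.non_connectivity.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        return cls(
            selection=SelectionParams(**d.get("selection", {})),
            matching=MatchingParams(**d.get("matching", {})),
            material=MaterialParams(**d.get("material", {})),
            solver=SolverParams(**d.get("solver", {})),
            mesh_spacing=d.get("mesh_spacing", 20.0),
            mesh_file=d.get("mesh_file"),
        )

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _grid_centers(image) -> np.ndarray:
    """(n_voxels, d) physical centres of every voxel, index-major order."""
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in image.pixels.shape[: image.ndim]],
                    indexing="ij"), axis=-1,
    ).reshape(-1, image.ndim)
    return index_to_physical(image, idx.astype(float))


def rasterize_field(mesh, U, grid) -> DisplacementFieldImage:
    """Evaluate nodal displacements at every voxel centre of ``grid``.

    Voxels outside all elements get the zero vector; their count is stored
    on the returned field as ``outside_count``.
    """
    d = mesh.ndim
    U = np.asarray(U, dtype=float).reshape(-1, d)
    if len(U) != mesh.n:
        raise ValueError("U length does not match mesh node count")
    centers = _grid_centers(grid)
    values = np.zeros((len(centers), d))
    outside = 0
    for i, pt in enumerate(centers):
        loc = mesh_mod.locate_point(mesh, pt)
        if loc is None:
            outside += 1
            continue
        values[i] = loc.weights @ U[mesh.elements[loc.element_id]]
    shape = grid.pixels.shape[: grid.ndim]
    fld = DisplacementFieldImage(
        values.reshape(*shape, d), grid.origin, grid.spacing, grid.direction
    )
    fld.outside_count = outside
    return fld


def _sample_field(field: DisplacementFieldImage, points: np.ndarray) -> np.ndarray:
    """Multilinear field interpolation at physical points; zero outside."""
    ref = field.geometry_image()
    idx = physical_to_index(ref, points)
    out = np.empty((len(points), field.ndim))
    coords = [idx[:, ax] for ax in range(field.ndim)]
    for c in range(field.ndim):
        out[:, c] = ndimage.map_coordinates(
            field.vectors[..., c], coords, order=1, mode="constant", cval=0.0
        )
    return out


def warp_image(image: ScalarImage, field: DisplacementFieldImage) -> ScalarImage:
    """Backward warp: output(x) = image(x + field(x)), multilinear interpolation.

    The field's grid defines the output grid; samples falling outside the
    input image get intensity 0.
    """
    if image.ndim != field.ndim:
        raise ValueError("image and field dimensionality differ")
    ref = field.geometry_image()
    centers = _grid_centers(ref)
    src = centers + field.vectors.reshape(-1, field.ndim)
    idx = physical_to_index(image, src)
    out = ndimage.map_coordinates(
        image.pixels, [idx[:, ax] for ax in range(image.ndim)],
        order=1, mode="constant", cval=0.0,
    )
    return ScalarImage(
        out.reshape(field.grid_shape), field.origin, field.spacing, field.direction
    )


def invert_field(
    field: DisplacementFieldImage, max_iters: int = 50, tol_mm: float = 0.01
) -> DisplacementFieldImage:
    """Invert a displacement field by damped fixed-point iteration.

    Solves g(x) = -f(x + g(x)) starting from g = -f; the step is damped by
    0.5 whenever the update grows.  The returned field carries the achieved
    ``composition_error`` array ||f(x + g(x)) + g(x)|| and a ``converged``
    flag.
    """
    ref = field.geometry_image()
    centers = _grid_centers(ref)
    f_flat = field.vectors.reshape(-1, field.ndim)
    g = -f_flat.copy()
    damping = 1.0
    prev_update = np.inf
    for _ in range(max_iters):
        target = -_sample_field(field, centers + g)
        update = target - g
        step = np.max(np.linalg.norm(update, axis=1))
        if step >= prev_update:  # growing or cycling update: damp
            damping = 0.5
        prev_update = step
        g = g + damping * update
        if step < tol_mm:
            break
    comp = np.linalg.norm(_sample_field(field, centers + g) + g, axis=1)
    inv = DisplacementFieldImage(
        g.reshape(field.vectors.shape), field.origin, field.spacing, field.direction
    )
    inv.composition_error = comp.reshape(field.grid_shape)
    inv.converged = bool(prev_update < tol_mm)
    if not inv.converged:
        logger.warning("field inversion did not reach %.3g mm in %d iterations",
                       tol_mm, max_iters)
    return inv


def directed_hausdorff(points_a, points_b) -> float:
    """One-directional Hausdorff distance max_a min_b ||a - b|| in mm."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("directed Hausdorff requires non-empty point sets")
    dists, _ = cKDTree(b).query(a)
    return float(np.max(dists))


def landmark_error(landmarks_fixed, landmarks_moving, field: DisplacementFieldImage):
    """Per-landmark registration error before and after applying the field.

    Before: ||fixed_k - moving_k||.  After: ||fixed_k - (moving_k +
    field(moving_k))||, i.e. the moving landmark pushed through the
    moving->fixed field.  Returns a dict with per-landmark arrays and means.
    """
    A = np.atleast_2d(np.asarray(landmarks_moving, dtype=float))
    C = np.atleast_2d(np.asarray(landmarks_fixed, dtype=float))
    if A.shape != C.shape:
        raise ValueError("landmark lists must have equal counts")
    before = np.linalg.norm(C - A, axis=1)
    B = A + _sample_field(field, A)
    after = np.linalg.norm(C - B, axis=1)
    return {
        "before": before,
        "after": after,
        "mean_before": float(before.mean()),
        "mean_after": float(after.mean()),
    }


def solve_scattered_data(
    points: np.ndarray,
    displacements: np.ndarray,
    mesh,
    material: MaterialParams,
    solver: SolverParams,
    confidences=None,
    tensors=None,
):
    """Sparse-to-dense core: assemble the system and run the robust solver.

    Returns (states, kept-point indices).  ``points`` outside the mesh are
    dropped along with their payloads.
    """
    d = mesh.ndim
    points = np.atleast_2d(np.asarray(points, dtype=float))
    displacements = np.atleast_2d(np.asarray(displacements, dtype=float))
    K = fem_solver.assemble_stiffness(mesh, material)
    H, kept = fem_solver.assemble_interpolation(mesh, points)
    c = np.ones(len(points)) if confidences is None else np.asarray(confidences, float)
    sigma = solver.stiffness_scale
    if sigma is None:
        sigma = fem_solver.average_node_stiffness(K, mesh)
    S = fem_solver.assemble_matching_stiffness(
        c[kept],
        None if (tensors is None or not solver.use_tensors) else np.asarray(tensors)[kept],
        balance=solver.balance,
        n_nodes=mesh.n,
        sigma=sigma,
        d=d,
    )
    D = displacements[kept].ravel()
    states = fem_solver.robust_solve(K, H, S, D, solver, d=d)
    return states, kept


def run_pbnrr(
    fixed: ScalarImage,
    moving: ScalarImage,
    mask: MaskImage,
    config: PipelineConfig | None = None,
):
    """Full pipeline: returns (field moving->fixed, warped moving, report)."""
    config = config or PipelineConfig()
    if not fixed.same_geometry(moving):
        raise ValueError("fixed and moving images must share geometry")
    if mask.pixels.shape != moving.pixels.shape:
        raise ValueError("mask geometry must match the moving image")

    sel = config.selection
    logger.info("selecting feature points (fraction %.3g)", sel.select_fraction)
    feats, variances = select_feature_points(moving, mask, sel)
    if len(feats) == 0:
        raise RuntimeError("feature selection returned no points")

    logger.info("block matching %d points", len(feats))
    disps, sims = match_all(fixed, moving, feats, config.matching)

    if config.mesh_file:
        msh = read_mesh(config.mesh_file)
    else:
        msh = mesh_mod.build_rectilinear_mesh(mask, config.mesh_spacing)
    logger.info("mesh: %d nodes, %d %s elements", msh.n, len(msh.elements),
                msh.element_type)

    states, kept = solve_scattered_data(
        disps.points, disps.payloads, msh, config.material, config.solver,
        confidences=sims.payloads,
        tensors=feats.payloads if sel.compute_tensors else None,
    )
    final = states[-1]
    U = final.U

    field = rasterize_field(msh, U, moving)
    inverse = invert_field(field)
    warped = warp_image(moving, inverse)

    report = {
        "n_selected": int(len(feats)),
        "n_matched": int(len(disps)),
        "n_in_mesh": int(len(kept)),
        "n_rejected": int(np.sum(~final.inlier_mask)),
        "mesh_nodes": int(msh.n),
        "mesh_elements": int(len(msh.elements)),
        "outside_mesh_voxels": int(getattr(field, "outside_count", 0)),
        "max_field_mm": float(np.max(np.linalg.norm(
            field.vectors.reshape(-1, field.ndim), axis=1))),
        "iterations": [
            {
                "phase": s.phase,
                "energy": float(s.energy),
                "max_inlier_error_mm": float(np.nanmax(s.per_point_error))
                if np.any(np.isfinite(s.per_point_error)) else 0.0,
                "n_inliers": int(np.sum(s.inlier_mask)),
            }
            for s in states
        ],
        "inversion_converged": bool(inverse.converged),
        "config": config.to_dict(),
    }
    return field, warped, report
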