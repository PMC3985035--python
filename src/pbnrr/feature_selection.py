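"""Feature-point selection by block intensity variance with crowding suppression.

Matching sites are chosen where a small block of the moving image carries
discriminative structure: candidate block centres are ranked by the intensity
variance within the block and accepted greedily, skipping any centre adjacent
to an already-accepted one under a prohibited connectivity (face / edge /
vertex neighbourhood).  A mask restricts candidates to the object of
interest, and a boundary margin of ``search_radius + block_radius`` voxels
guarantees that block matching never reads outside the image.

Optionally the structure tensor (sum of gradient outer products over the
block) is attached to each point; its eigenstructure encodes the local edge
orientation and lets the solver down-weight the motion component that is
unobservable along an edge (the aperture problem).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product

import numpy as np
from scipy import ndimage

from .image_io import DisplacementPointSet, MaskImage, ScalarImage, index_to_physical

__all__ = [
    "Connectivity",
    "SelectionParams",
    "block_variance",
    "structure_tensor",
    "select_feature_points",
]


class Connectivity(str, Enum):
    FACE = "face"      # 4-neighbourhood in 2D, 6 in 3D
    EDGE = "edge"      # 8 in 2D, 18 in 3D
    VERTEX = "vertex"  # 8 in 2D, 26 in 3D


class SelectionError(RuntimeError):
    pass


@dataclass
class SelectionParams:
    block_radius: int = 1
    select_fraction: float = 0.05
    non_connectivity: Connectivity = Connectivity.VERTEX
    search_radius: int = 3
    compute_tensors: bool = False

    def __post_init__(self):
        self.non_connectivity = Connectivity(self.non_connectivity)
        if self.block_radius < 1:
            raise ValueError("block_radius must be >= 1")
        if not 0 < self.select_fraction <= 1:
            raise ValueError("select_fraction must lie in (0, 1]")
        if self.search_radius < 0:
            raise ValueError("search_radius must be >= 0")


def _neighbour_offsets(d: int, connectivity: Connectivity) -> np.ndarray:
    """Prohibited index offsets: distance-1 neighbourhoods only."""
    offs = [o for o in product((-1, 0, 1), repeat=d) if any(o)]
    if connectivity is Connectivity.FACE:
        offs = [o for o in offs if sum(abs(c) for c in o) == 1]
    elif connectivity is Connectivity.EDGE and d == 3:
        offs = [o for o in offs if sum(abs(c) for c in o) <= 2]
    return np.array(offs, dtype=int)


def block_variance(image: ScalarImage, center, block_radius: int) -> float:
    """Population variance of intensities in the (2r+1)^d block around ``center``."""
    center = np.asarray(center, dtype=int)
    r = int(block_radius)
    lo, hi = center - r, center + r
    if np.any(lo < 0) or np.any(hi >= np.array(image.shape)):
        raise IndexError(f"block at {tuple(center)} with radius {r} crosses the image boundary")
    block = image.pixels[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]
    return float(np.var(block))


def structure_tensor(image: ScalarImage, center, block_radius: int) -> np.ndarray:
    """Sum over the block of grad(I) grad(I)^T, central differences in 1/mm."""
    center = np.asarray(center, dtype=int)
    r = int(block_radius)
    lo, hi = center - r - 1, center + r + 1
    if np.any(lo < 0) or np.any(hi >= np.array(image.shape)):
        raise IndexError(
            f"block at {tuple(center)} with radius {r} (plus gradient margin) out of bounds"
        )
    region = image.pixels[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]
    grads = np.gradient(region, *image.spacing)
    inner = tuple(slice(1, -1) for _ in range(image.ndim))
    g = np.stack([gr[inner].ravel() for gr in grads])  # (d, m)
    return g @ g.T


def _variance_map(pixels: np.ndarray, r: int) -> np.ndarray:
    """Population block variance at every voxel via box filtering, E[x^2]-E[x]^2."""
    size = 2 * r + 1
    m1 = ndimage.uniform_filter(pixels, size=size, mode="constant")
    m2 = ndimage.uniform_filter(pixels * pixels, size=size, mode="constant")
    return np.maximum(m2 - m1 * m1, 0.0)


def select_feature_points(
    image: ScalarImage, mask: MaskImage, params: SelectionParams
) -> tuple[DisplacementPointSet, np.ndarray]:
    """Greedy variance-ranked selection of block centres inside the mask.

    Returns a point set (payload: structure tensors when requested, else
    bare points) and the parallel array of block variances.  Candidates are
    sorted by variance descending with lexicographic index order breaking
    ties, then accepted unless adjacent to an accepted point under the
    prohibited connectivity; selection stops at
    ``floor(select_fraction * n_eligible)`` points.
    """
    if mask.pixels.shape != image.pixels.shape:
        raise ValueError("mask geometry does not match image geometry")
    d = image.ndim
    margin = params.search_radius + params.block_radius
    shape = np.array(image.shape)
    if np.any(shape <= 2 * margin):
        raise SelectionError(
            f"image of shape {tuple(shape)} leaves no voxel at least "
            f"search_radius + block_radius = {margin} voxels from every face"
        )
    eligible = mask.pixels != 0
    for ax in range(d):
        sl = [slice(None)] * d
        sl[ax] = slice(0, margin)
        eligible[tuple(sl)] = False
        sl[ax] = slice(shape[ax] - margin, shape[ax])
        eligible[tuple(sl)] = False
    idx = np.argwhere(eligible)
    if len(idx) == 0:
        raise SelectionError(
            "no eligible block centres: every masked voxel is within "
            f"search_radius + block_radius = {margin} voxels of an image face"
        )

    variances = _variance_map(image.pixels, params.block_radius)[tuple(idx.T)]
    # stable sort on (-variance, index lexicographic): argwhere is already lex-ordered
    order = np.argsort(-variances, kind="stable")
    idx, variances = idx[order], variances[order]

    target = int(np.floor(params.select_fraction * len(idx)))
    offsets = _neighbour_offsets(d, params.non_connectivity)
    accepted: list[int] = []
    taken = set()
    for k in range(len(idx)):
        if len(accepted) >= target:
            break
        c = idx[k]
        if any(tuple(c + o) in taken for o in offsets):
            continue
        accepted.append(k)
        taken.add(tuple(c))

    sel = idx[accepted]
    sel_var = variances[accepted]
    points = index_to_physical(image, sel.astype(float))
    tensors = None
    if params.compute_tensors:
        tensors = np.stack(
            [structure_tensor(image, c, params.block_radius) for c in sel]
        ) if len(sel) else np.zeros((0, d, d))
    ps = DisplacementPointSet(points.reshape(-1, d), tensors)
    ps.indices = sel  # integer voxel indices, used by block matching
    return ps, sel_var
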