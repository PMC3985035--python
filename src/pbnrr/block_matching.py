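"""Exhaustive NCC block matching: sparse displacement estimation at feature points.

For each feature point, a block of the moving image centred on the point is
compared against every integer-voxel translation inside a search window of
the fixed image; the translation maximising normalized cross-correlation
wins.  The resulting sparse displacement field D (moving -> fixed, physical
mm) and the per-point correlation values c_k feed the finite-element
scattered-data solver, where c_k act as matching confidences.

The search is translational and integer-voxel only (no subvoxel
refinement).  Ties at equal NCC go to the offset of smallest Euclidean
norm, then lexicographic order — preferring the smallest motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .image_io import DisplacementPointSet, ScalarImage, index_to_physical

__all__ = ["MatchingParams", "MatchResult", "ncc", "match_block", "match_all"]


@dataclass
class MatchingParams:
    block_radius: int = 1
    search_radius: int = 3

    def __post_init__(self):
        if self.block_radius < 1 or self.search_radius < 1:
            raise ValueError("block_radius and search_radius must be >= 1")


@dataclass
class MatchResult:
    displacement: np.ndarray  # mm, moving -> fixed
    similarity: float         # max(NCC, 0) at the winning offset


def ncc(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Normalized cross-correlation in [-1, 1]; 0 when either block is constant."""
    a = np.asarray(block_a, dtype=float)
    b = np.asarray(block_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"block shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("blocks need at least 2 voxels")
    a0 = a - np.mean(a)
    b0 = b - np.mean(b)
    va = np.sum(a0 * a0)
    vb = np.sum(b0 * b0)
    if va == 0.0 or vb == 0.0:
        return 0.0
    return float(np.clip(np.sum(a0 * b0) / np.sqrt(va * vb), -1.0, 1.0))


def _block(image: ScalarImage, center: np.ndarray, r: int) -> np.ndarray:
    lo, hi = center - r, center + r
    return image.pixels[tuple(slice(a, b + 1) for a, b in zip(lo, hi))]


def _check_bounds(index, r, sr, fixed_shape, moving_shape):
    index = np.asarray(index, dtype=int)
    for ax in range(index.size):
        if index[ax] - r < 0 or index[ax] + r >= moving_shape[ax]:
            raise IndexError(f"feature block out of moving-image bounds along axis {ax}")
        if index[ax] - r - sr < 0 or index[ax] + r + sr >= fixed_shape[ax]:
            raise IndexError(f"search window out of fixed-image bounds along axis {ax}")
    return index


def match_block(
    fixed: ScalarImage,
    moving: ScalarImage,
    feature_index,
    params: MatchingParams,
) -> MatchResult:
    """Exhaustive search over all (2*search_radius+1)^d integer offsets.

    The block comes from the MOVING image at ``feature_index``; the window
    slides over the FIXED image, so the displacement maps moving -> fixed.
    """
    d = fixed.ndim
    r, sr = params.block_radius, params.search_radius
    index = _check_bounds(feature_index, r, sr, fixed.shape, moving.shape)
    mblock = _block(moving, index, r)

    best_score = -np.inf
    best_key = None
    best_off = None
    for off in product(range(-sr, sr + 1), repeat=d):
        offa = np.array(off, dtype=int)
        score = ncc(mblock, _block(fixed, index + offa, r))
        key = (-score, float(offa @ offa)) + off
        if best_key is None or key < best_key:
            best_key, best_score, best_off = key, score, offa
    disp = index_to_physical(fixed, (index + best_off).astype(float)) - index_to_physical(
        moving, index.astype(float)
    )
    return MatchResult(displacement=disp, similarity=max(best_score, 0.0))


def match_all(
    fixed: ScalarImage,
    moving: ScalarImage,
    features: DisplacementPointSet,
    params: MatchingParams,
) -> tuple[DisplacementPointSet, DisplacementPointSet]:
    """Match every feature point; outputs preserve input order and coordinates.

    Per-point computations share no mutable state, so results are
    independent of evaluation order or chunking.
    """
    if not fixed.same_geometry(moving):
        raise ValueError("fixed and moving images must share geometry for matching")
    d = fixed.ndim
    indices = getattr(features, "indices", None)
    if indices is None:
        from .image_io import physical_to_index

        indices = np.rint(physical_to_index(fixed, features.points)).astype(int)
    p = len(features)
    disps = np.zeros((p, d))
    sims = np.zeros(p)
    for k in range(p):
        try:
            res = match_block(fixed, moving, indices[k], params)
        except IndexError as err:
            raise IndexError(f"feature point {k}: {err}") from err
        disps[k] = res.displacement
        sims[k] = res.similarity
    return (
        DisplacementPointSet(features.points.copy().reshape(-1, d) if p else np.zeros((0, d)), disps),
        DisplacementPointSet(features.points.copy().reshape(-1, d) if p else np.zeros((0, d)), sims),
    )
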