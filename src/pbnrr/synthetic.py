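"""Synthetic fixtures: textured phantoms, smooth ground-truth deformations,
warped counterparts and sparse/outlier-contaminated displacement sets.

These generators reproduce the shape of a sparse-to-dense recovery study
with an exactly known answer: a phantom image with rich internal texture,
an analytic fold-free deformation field, edge points of the phantom carrying
exact field samples, and optional gross-outlier contamination for stressing
the robust solver.  Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .image_io import (
    DisplacementFieldImage,
    DisplacementPointSet,
    MaskImage,
    ScalarImage,
    index_to_physical,
)

__all__ = [
    "PhantomSpec",
    "DeformationSpec",
    "make_phantom",
    "make_deformation",
    "sample_sparse_field",
    "inject_outliers",
]


@dataclass
class PhantomSpec:
    shape: tuple = (128, 128)
    spacing: tuple | float = 1.0
    texture_length_mm: float = 4.0
    intensity_range: tuple = (0.0, 100.0)
    object_semiaxes_frac: tuple | float = 0.42  # ellipse semi-axes as a fraction of extent
    seed: int = 0


@dataclass
class DeformationSpec:
    amplitude_mm: float = 6.0
    smoothness_mm: float = 32.0
    form: str = "gaussian"  # gaussian-smoothed noise | sinusoidal
    # the boundary ramp's slope is ~ amplitude * pi / (2 * margin); keep the
    # margin comfortably above half the default amplitude so windowing alone
    # cannot fold space
    support_margin_mm: float = 16.0
    seed: int = 0


def _geometry(spec: PhantomSpec):
    d = len(spec.shape)
    spacing = np.broadcast_to(np.asarray(spec.spacing, dtype=float), (d,)).copy()
    return d, spacing


def make_phantom(spec: PhantomSpec) -> tuple[ScalarImage, MaskImage]:
    """Correlated random texture inside an ellipse/ellipsoid mask, background 0."""
    d, spacing = _geometry(spec)
    shape = tuple(int(s) for s in spec.shape)
    if any(s < 8 for s in shape):
        raise ValueError(f"degenerate phantom shape {shape}")
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma_vox = spec.texture_length_mm / spacing
    tex = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    lo, hi = spec.intensity_range
    tmin, tmax = tex.min(), tex.max()
    tex = np.clip(lo + (hi - lo) * (tex - tmin) / (tmax - tmin), lo, hi)

    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    center = (np.array(shape) - 1) / 2
    semi = np.broadcast_to(
        np.asarray(spec.object_semiaxes_frac, dtype=float), (d,)
    ) * np.array(shape)
    r2 = np.sum(((idx - center) / semi) ** 2, axis=-1)
    mask_arr = (r2 <= 1.0).astype(float)

    origin = np.zeros(d)
    direction = np.eye(d)
    image = ScalarImage(tex * mask_arr, origin, spacing, direction)
    mask = MaskImage(mask_arr, origin, spacing, direction)
    return image, mask


def _support_window(shape, spacing, margin_mm) -> np.ndarray:
    """Smooth [0,1] window that is ~1 in the interior and 0 at the faces."""
    w = np.ones(shape)
    for ax, s in enumerate(shape):
        x = np.arange(s) * spacing[ax]
        extent = x[-1]
        m = max(margin_mm, spacing[ax])
        ramp = np.minimum(np.minimum(x, extent - x) / m, 1.0)
        ramp = np.clip(ramp, 0.0, 1.0)
        ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)  # smooth-step
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        w = w * ramp[tuple(sl)]
    return w


def make_deformation(spec: DeformationSpec, grid: ScalarImage) -> DisplacementFieldImage:
    """Smooth fold-free field on ``grid`` with max magnitude == amplitude.

    ``gaussian`` form: per-component white noise smoothed at the requested
    length scale, windowed to vanish near the boundary, rescaled so the
    largest vector norm equals the amplitude.  ``sinusoidal`` form: the
    closed-form product-of-sines field.  A finite-difference Jacobian scan
    rejects parameter combinations that fold space.
    """
    d = grid.ndim
    shape = grid.pixels.shape
    spacing = grid.spacing
    if spec.amplitude_mm == 0:
        fld = np.zeros((*shape, d))
        return DisplacementFieldImage(fld, grid.origin, grid.spacing, grid.direction)

    if spec.form == "sinusoidal":
        axes_mm = [np.arange(s) * spacing[ax] for ax, s in enumerate(shape)]
        extent = [x[-1] for x in axes_mm]
        mesh_mm = np.meshgrid(*axes_mm, indexing="ij")
        fld = np.empty((*shape, d))
        for c in range(d):
            comp = np.ones(shape)
            for ax in range(d):
                comp = comp * np.sin(np.pi * mesh_mm[ax] / extent[ax] * (1 + ((c + ax) % 2)))
            fld[..., c] = comp
    elif spec.form == "gaussian":
        rng = np.random.default_rng(spec.seed)
        sigma_vox = spec.smoothness_mm / spacing
        fld = np.empty((*shape, d))
        for c in range(d):
            fld[..., c] = ndimage.gaussian_filter(
                rng.standard_normal(shape), sigma=sigma_vox
            )
        fld *= _support_window(shape, spacing, spec.support_margin_mm)[..., None]
    else:
        raise ValueError(f"unknown deformation form {spec.form!r}")

    mag = np.linalg.norm(fld, axis=-1)
    peak = mag.max()
    if peak == 0:
        raise ValueError("degenerate deformation: field is identically zero")
    fld *= spec.amplitude_mm / peak

    # fold check: Jacobian of (id + f) must stay positive everywhere
    jac = np.zeros((*shape, d, d))
    for c in range(d):
        grads = np.gradient(fld[..., c], *spacing)
        for ax in range(d):
            jac[..., c, ax] = grads[ax]
    jac += np.eye(d)
    dets = np.linalg.det(jac)
    if dets.min() <= 0:
        raise ValueError(
            f"amplitude {spec.amplitude_mm} mm at smoothness {spec.smoothness_mm} mm "
            f"folds space (min Jacobian determinant {dets.min():.3g})"
        )
    return DisplacementFieldImage(fld, grid.origin, grid.spacing, grid.direction)


def sample_sparse_field(
    field: DisplacementFieldImage, image: ScalarImage, edge_threshold: float = 0.25
) -> DisplacementPointSet:
    """Exact field samples at the image's edge voxels.

    Edge voxels are those whose gradient magnitude exceeds
    ``edge_threshold`` times the image's maximum gradient magnitude; the
    payload is the field value at the same voxel (exact grid lookup).
    """
    if image.pixels.shape != field.grid_shape:
        raise ValueError("image and field must share geometry")
    grads = np.gradient(image.pixels, *image.spacing)
    mag = np.sqrt(sum(g * g for g in grads))
    thresh = edge_threshold * mag.max()
    idx = np.argwhere(mag > thresh)
    if len(idx) == 0:
        raise ValueError("no edge points: image has no gradient above threshold")
    points = index_to_physical(image, idx.astype(float))
    payloads = field.vectors[tuple(idx.T)]
    ps = DisplacementPointSet(points, payloads)
    ps.indices = idx
    return ps


def inject_outliers(
    points: DisplacementPointSet, fraction: float, magnitude_mm: float, seed: int = 0
) -> tuple[DisplacementPointSet, np.ndarray]:
    """Replace floor(fraction*p) payloads with gross random displacements.

    Replacement vectors are uniformly random directions with norm drawn
    from [0.5, 1] x magnitude.  Returns the contaminated set and the
    ground-truth outlier index list.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    p = len(points)
    d = points.points.shape[1]
    rng = np.random.default_rng(seed)
    n_out = int(np.floor(fraction * p))
    labels = np.sort(rng.choice(p, size=n_out, replace=False))
    payloads = points.payloads.copy()
    if n_out:
        dirs = rng.standard_normal((n_out, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        norms = magnitude_mm * rng.uniform(0.5, 1.0, size=n_out)
        payloads[labels] = dirs * norms[:, None]
    out = DisplacementPointSet(points.points.copy(), payloads)
    if hasattr(points, "indices"):
        out.indices = points.indices
    return out, labels
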