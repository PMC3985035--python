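"""Image, field, point-set and mesh I/O plus the index<->physical coordinate contract.

All geometry follows the ITK convention: voxel indices are 0-based and the
centre of voxel ``i`` sits at ``origin + direction @ (spacing * i)`` in
physical millimetres.  Pixel arrays are stored index-major, i.e.
``pixels[i0, i1, i2]`` corresponds to index ``(i0, i1, i2)`` in the same axis
order as origin/spacing/direction.  Direction matrices are honoured
everywhere (clinical NIfTI headers carry them).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ScalarImage",
    "MaskImage",
    "DisplacementFieldImage",
    "DisplacementPointSet",
    "read_image",
    "write_image",
    "read_mask",
    "read_field",
    "write_field",
    "read_point_set",
    "write_point_set",
    "read_mesh",
    "write_mesh",
    "index_to_physical",
    "physical_to_index",
]

_IMAGE_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Unsupported or malformed file format."""


class GeometryError(ValueError):
    """Invalid image or mesh geometry."""


def _check_geometry(origin, spacing, direction):
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    direction = np.asarray(direction, dtype=float)
    d = origin.size
    if spacing.shape != (d,) or direction.shape != (d, d):
        raise GeometryError("origin/spacing/direction dimensions disagree")
    if np.any(spacing <= 0):
        raise GeometryError(f"spacing must be positive, got {spacing}")
    if np.max(np.abs(direction.T @ direction - np.eye(d))) > 1e-6:
        raise GeometryError("direction matrix is not orthonormal")
    return origin, spacing, direction


@dataclass
class ScalarImage:
    """A d-dimensional scalar image (d in {2, 3}) with physical geometry."""

    pixels: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.origin, self.spacing, self.direction = _check_geometry(
            self.origin, self.spacing, self.direction
        )
        if self.pixels.ndim != self.origin.size:
            raise GeometryError(
                f"pixel array is {self.pixels.ndim}-D but geometry is {self.origin.size}-D"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise GeometryError("pixel array contains NaN/Inf")

    @property
    def ndim(self) -> int:
        return self.pixels.ndim

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def same_geometry(self, other: "ScalarImage", tol: float = 1e-6) -> bool:
        return (
            self.pixels.shape[: self.ndim] == other.pixels.shape[: other.ndim]
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


class MaskImage(ScalarImage):
    """Binary object mask; any nonzero input voxel is mapped to 1 on load."""

    def __post_init__(self):
        super().__post_init__()
        self.pixels = (self.pixels != 0).astype(float)
        if not self.pixels.any():
            raise GeometryError("mask contains no foreground voxels")


@dataclass
class DisplacementFieldImage:
    """Vector-valued image: per-voxel displacement in mm, components (x, y[, z])."""

    vectors: np.ndarray  # shape (*grid_shape, d)
    origin: np.ndarray
    spacing: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.origin, self.spacing, self.direction = _check_geometry(
            self.origin, self.spacing, self.direction
        )
        d = self.origin.size
        if self.vectors.ndim != d + 1 or self.vectors.shape[-1] != d:
            raise GeometryError(
                f"field shape {self.vectors.shape} inconsistent with {d}-D geometry"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise GeometryError("field contains NaN/Inf")

    @property
    def ndim(self) -> int:
        return self.origin.size

    @property
    def grid_shape(self) -> tuple:
        return self.vectors.shape[:-1]

    def geometry_image(self) -> ScalarImage:
        """A zero scalar image sharing this field's grid, for geometry plumbing."""
        return ScalarImage(
            np.zeros(self.grid_shape), self.origin, self.spacing, self.direction
        )


@dataclass
class DisplacementPointSet:
    """Physical points with per-point payloads.

    ``payloads`` is an array of shape (p, d) for displacement vectors, (p,)
    for similarity scalars, or (p, d, d) for structure tensors; ``None`` for
    bare points.
    """

    points: np.ndarray
    payloads: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.payloads is not None:
            self.payloads = np.asarray(self.payloads, dtype=float)
            if len(self.payloads) != len(self.points):
                raise ValueError("points and payloads length mismatch")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# coordinate contract


def index_to_physical(image, index) -> np.ndarray:
    """Map continuous voxel indices to physical mm: origin + D @ (spacing * i).

    ``index`` may be a single d-vector or an (m, d) array.
    """
    index = np.asarray(index, dtype=float)
    d = image.origin.size
    if index.shape[-1] != d:
        raise ValueError(f"index dimension {index.shape[-1]} != image dimension {d}")
    return image.origin + (index * image.spacing) @ image.direction.T


def physical_to_index(image, point) -> np.ndarray:
    """Exact inverse of :func:`index_to_physical` (continuous indices)."""
    point = np.asarray(point, dtype=float)
    d = image.origin.size
    if point.shape[-1] != d:
        raise ValueError(f"point dimension {point.shape[-1]} != image dimension {d}")
    return ((point - image.origin) @ image.direction) / image.spacing


# ---------------------------------------------------------------------------
# scalar / vector image files (SimpleITK backends: NIfTI, MetaImage)


def _check_path(path) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _IMAGE_EXTS):
        raise FormatError(f"unsupported image extension: {path.name}")
    return path


def _from_sitk(img: sitk.Image):
    d = img.GetDimension()
    origin = np.array(img.GetOrigin())
    spacing = np.array(img.GetSpacing())
    direction = np.array(img.GetDirection()).reshape(d, d)
    # sitk arrays come back slowest-axis-first; transpose to index-major order
    arr = sitk.GetArrayFromImage(img)
    return arr, origin, spacing, direction


def read_image(path) -> ScalarImage:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr, origin, spacing, direction = _from_sitk(sitk.ReadImage(str(path)))
    pixels = np.transpose(arr, axes=range(arr.ndim - 1, -1, -1))
    return ScalarImage(pixels, origin, spacing, direction)


def read_mask(path) -> MaskImage:
    img = read_image(path)
    return MaskImage(img.pixels, img.origin, img.spacing, img.direction)


def _to_sitk(pixels, origin, spacing, direction, is_vector=False) -> sitk.Image:
    if is_vector:
        spatial = pixels.ndim - 1
        arr = np.transpose(pixels, axes=list(range(spatial - 1, -1, -1)) + [spatial])
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    else:
        arr = np.transpose(pixels, axes=range(pixels.ndim - 1, -1, -1))
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetOrigin(tuple(float(v) for v in origin))
    img.SetSpacing(tuple(float(v) for v in spacing))
    img.SetDirection(tuple(float(v) for v in np.asarray(direction).ravel()))
    return img


def write_image(image: ScalarImage, path) -> None:
    path = _check_path(path)
    sitk.WriteImage(
        _to_sitk(image.pixels, image.origin, image.spacing, image.direction), str(path)
    )


def write_field(field: DisplacementFieldImage, path) -> None:
    path = _check_path(path)
    sitk.WriteImage(
        _to_sitk(field.vectors, field.origin, field.spacing, field.direction, True),
        str(path),
    )


def read_field(path) -> DisplacementFieldImage:
    path = _check_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    d = img.GetDimension()
    if img.GetNumberOfComponentsPerPixel() != d:
        raise FormatError(
            f"{path.name}: expected a {d}-component vector image, got "
            f"{img.GetNumberOfComponentsPerPixel()} components"
        )
    arr, origin, spacing, direction = _from_sitk(img)
    vectors = np.transpose(arr, axes=list(range(d - 1, -1, -1)) + [d])
    return DisplacementFieldImage(vectors, origin, spacing, direction)


# ---------------------------------------------------------------------------
# point sets (plain CSV: point coords then payload components)


def write_point_set(ps: DisplacementPointSet, path) -> None:
    d = ps.points.shape[1]
    header = [f"p{i}" for i in range(d)]
    payload = None
    if ps.payloads is not None:
        payload = ps.payloads.reshape(len(ps), -1)
        header += [f"v{i}" for i in range(payload.shape[1])]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for k in range(len(ps)):
            row = list(ps.points[k])
            if payload is not None:
                row += list(payload[k])
            w.writerow(repr(float(v)) for v in row)


def read_point_set(path, ndim: int | None = None) -> DisplacementPointSet:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2 and len(rows[0]) == 0:
        raise FormatError(f"{path}: empty point-set file")
    header, data = rows[0], rows[1:]
    d = sum(1 for h in header if h.startswith("p"))
    if ndim is not None and d != ndim:
        raise FormatError(f"{path}: {d}-D points where {ndim}-D expected")
    arr = np.array([[float(v) for v in row] for row in data], dtype=float)
    arr = arr.reshape(-1, len(header))
    points = arr[:, :d]
    payloads = None
    if len(header) > d:
        payloads = arr[:, d:]
        if payloads.shape[1] == 1:
            payloads = payloads[:, 0]
        elif payloads.shape[1] == d * d:
            payloads = payloads.reshape(-1, d, d)
    return DisplacementPointSet(points, payloads)


# ---------------------------------------------------------------------------
# VTK legacy unstructured-grid meshes

_VTK_CELL_TYPES = {9: ("quad4", 4), 12: ("hex8", 8), 10: ("tet4", 4)}
_CELL_TYPE_IDS = {"quad4": 9, "hex8": 12, "tet4": 10}


def read_mesh(path):
    """Read a VTK legacy ASCII unstructured grid holding quad/hex/tet cells."""
    from .mesh import Mesh  # local import to avoid a cycle

    tokens = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "unstructured" not in lines[3].lower():
        raise FormatError(f"{path}: not a VTK legacy unstructured grid")
    for line in lines[4:]:
        tokens.extend(line.split())
    pos = 0

    def expect(keyword):
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != keyword:
            pos += 1
        if pos == len(tokens):
            raise FormatError(f"{path}: missing {keyword} section")
        pos += 1

    expect("POINTS")
    npts = int(tokens[pos]); pos += 2  # count, dtype
    coords = np.array(tokens[pos : pos + 3 * npts], dtype=float).reshape(npts, 3)
    pos += 3 * npts
    expect("CELLS")
    ncells = int(tokens[pos]); total = int(tokens[pos + 1]); pos += 2
    raw = [int(t) for t in tokens[pos : pos + total]]
    pos += total
    cells = []
    i = 0
    for _ in range(ncells):
        cnt = raw[i]
        cells.append(raw[i + 1 : i + 1 + cnt])
        i += 1 + cnt
    expect("CELL_TYPES")
    pos += 1  # count
    type_ids = [int(t) for t in tokens[pos : pos + ncells]]

    kinds = {t for t in type_ids}
    unsupported = kinds - set(_VTK_CELL_TYPES)
    if unsupported or len(kinds) != 1:
        raise FormatError(
            f"{path}: unsupported or mixed cell types {sorted(kinds)} "
            "(need homogeneous quad/hexahedron/tetrahedron)"
        )
    element_type, nn = _VTK_CELL_TYPES[type_ids[0]]
    elements = np.array(cells, dtype=int)
    if elements.shape[1] != nn:
        raise FormatError(f"{path}: cell arity does not match {element_type}")
    d = 2 if element_type == "quad4" else 3
    nodes = coords[:, :d]
    return Mesh(nodes=nodes, elements=elements, element_type=element_type)


def write_mesh(mesh, path) -> None:
    nodes3 = np.zeros((len(mesh.nodes), 3))
    nodes3[:, : mesh.nodes.shape[1]] = mesh.nodes
    nn = mesh.elements.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes3)} double\n")
        for p in nodes3:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        ne = len(mesh.elements)
        fh.write(f"CELLS {ne} {ne * (nn + 1)}\n")
        for el in mesh.elements:
            fh.write(f"{nn} " + " ".join(str(i) for i in el) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        tid = _CELL_TYPE_IDS[mesh.element_type]
        for _ in range(ne):
            fh.write(f"{tid}\n")
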