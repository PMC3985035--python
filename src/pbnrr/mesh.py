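"""Finite-element discretization: rectilinear quad4/hex8 meshes, shape functions,
point location.

The built-in mesh is an axis-aligned grid of bilinear quadrilaterals (2D) or
trilinear hexahedra (3D) covering the masked object: the grid spans
``ceil(extent/spacing) + 1`` cells per axis centred on the mask's physical
bounding box, so every boundary voxel centre sits at least half an element
inside the mesh; cells containing no masked voxel centre are pruned and
unreferenced nodes removed.  Linear tetrahedra are supported for user-supplied
meshes read from VTK files.

Node ordering follows the VTK convention (quad: counter-clockwise; hex:
bottom face then top face), so meshes round-trip through ``.vtk`` files
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .image_io import MaskImage, index_to_physical

__all__ = ["Mesh", "ElementLocation", "build_rectilinear_mesh", "shape_values",
           "shape_gradients", "locate_point", "reference_corners"]

# natural coordinates of element corners, VTK ordering
_QUAD4 = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
_HEX8 = np.array(
    [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
     (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)], dtype=float)
_TET4 = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)], dtype=float)


def reference_corners(element_type: str) -> np.ndarray:
    return {"quad4": _QUAD4, "hex8": _HEX8, "tet4": _TET4}[element_type]


@dataclass
class ElementLocation:
    element_id: int
    natural_coords: np.ndarray
    weights: np.ndarray


@dataclass
class Mesh:
    nodes: np.ndarray          # (n, d) physical mm
    elements: np.ndarray       # (m, nodes-per-element) int
    element_type: str          # quad4 | hex8 | tet4
    grid: dict | None = field(default=None, repr=False)  # rectilinear metadata

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.element_type not in ("quad4", "hex8", "tet4"):
            raise ValueError(f"unknown element type {self.element_type!r}")
        n = len(self.nodes)
        if self.elements.size and (self.elements.min() < 0 or self.elements.max() >= n):
            raise ValueError("element connectivity references a missing node")
        for el in self.elements:
            if len(set(el)) != len(el):
                raise ValueError("element repeats a node index")
        self._check_volumes()

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def ndim(self) -> int:
        return self.nodes.shape[1]

    def _check_volumes(self):
        for e, el in enumerate(self.elements):
            coords = self.nodes[el]
            if self.element_type == "tet4":
                vol = np.linalg.det(coords[1:] - coords[0]) / 6.0
                if vol <= 0:
                    raise ValueError(f"element {e} has non-positive volume {vol}")
            else:
                for xi in _gauss_points(self.element_type)[0]:
                    J = _jacobian(self, el, xi)
                    if np.linalg.det(J) <= 0:
                        raise ValueError(f"element {e} has non-positive Jacobian")

    def element_centroid(self, e: int) -> np.ndarray:
        return self.nodes[self.elements[e]].mean(axis=0)

    def mean_edge_length(self) -> float:
        """Mean length of the axis edges of the first element (uniform grids)
        or of all tet edges; used to scale the matching stiffness."""
        lengths = []
        for el in self.elements[: min(len(self.elements), 50)]:
            coords = self.nodes[el]
            if self.element_type == "tet4":
                for i in range(4):
                    for j in range(i + 1, 4):
                        lengths.append(np.linalg.norm(coords[i] - coords[j]))
            elif self.element_type == "quad4":
                for i, j in ((0, 1), (1, 2), (2, 3), (3, 0)):
                    lengths.append(np.linalg.norm(coords[i] - coords[j]))
            else:
                for i, j in ((0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6),
                             (6, 7), (7, 4), (0, 4), (1, 5), (2, 6), (3, 7)):
                    lengths.append(np.linalg.norm(coords[i] - coords[j]))
        return float(np.mean(lengths))


def _shape_values_raw(element_type: str, xi: np.ndarray) -> np.ndarray:
    if element_type == "tet4":
        return np.array([1.0 - xi.sum(), *xi])
    corners = reference_corners(element_type)
    return np.prod(1.0 + corners * xi, axis=1) / 2 ** xi.size


def shape_values(element_type: str, natural_coords) -> np.ndarray:
    """Multilinear (quad4/hex8) or barycentric (tet4) shape functions."""
    xi = np.asarray(natural_coords, dtype=float)
    tol = 1e-6
    if element_type == "tet4":
        w = _shape_values_raw(element_type, xi)
        if np.any(w < -tol):
            raise ValueError(f"natural coords {xi} outside reference tetrahedron")
        return w
    if np.any(np.abs(xi) > 1 + tol):
        raise ValueError(f"natural coords {xi} outside reference element")
    return _shape_values_raw(element_type, xi)


def shape_gradients(element_type: str, natural_coords) -> np.ndarray:
    """d(N_i)/d(xi_j), shape (nodes, d), in reference coordinates."""
    xi = np.asarray(natural_coords, dtype=float)
    if element_type == "tet4":
        return np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    corners = reference_corners(element_type)
    d = xi.size
    grads = np.empty((len(corners), d))
    terms = 1.0 + corners * xi  # (nodes, d)
    for j in range(d):
        others = np.prod(np.delete(terms, j, axis=1), axis=1)
        grads[:, j] = corners[:, j] * others / 2 ** d
    return grads


def _jacobian(mesh: Mesh, element_nodes, xi) -> np.ndarray:
    """dx/dxi at natural coords xi: coords^T @ dN."""
    return mesh.nodes[element_nodes].T @ shape_gradients(mesh.element_type, xi)


def _gauss_points(element_type: str):
    """(points, weights) for stiffness integration: 2-pt/axis tensor rule for
    quad/hex, 1-point for tet."""
    if element_type == "tet4":
        return np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
    g = 1.0 / np.sqrt(3.0)
    d = 2 if element_type == "quad4" else 3
    pts = np.array(list(product((-g, g), repeat=d)))
    return pts, np.ones(len(pts))


def build_rectilinear_mesh(mask: MaskImage, element_spacing) -> Mesh:
    """Axis-aligned quad4/hex8 mesh over the mask with ~20 mm default pitch.

    The grid covers the bounding box of masked voxel centres with
    ``ceil(extent/spacing) + 1`` cells per axis, centred so the overhang is
    symmetric (at least half an element per side); elements containing no
    masked voxel centre are dropped and orphan nodes removed.
    """
    d = mask.ndim
    spacing = np.broadcast_to(np.asarray(element_spacing, dtype=float), (d,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("element_spacing must be positive")
    if np.any(spacing < 2 * mask.spacing):
        import warnings

        warnings.warn(
            "element spacing below twice the voxel spacing: the mesh is finer "
            "than the data it regularizes", stacklevel=2)
    vox = np.argwhere(mask.pixels != 0)
    if len(vox) == 0:
        raise ValueError("mask has no foreground voxels")
    centers = index_to_physical(mask, vox.astype(float))
    bmin, bmax = centers.min(axis=0), centers.max(axis=0)
    extent = bmax - bmin
    ncells = (np.ceil(extent / spacing) + 1).astype(int)
    gmin = (bmin + bmax) / 2 - ncells * spacing / 2

    node_shape = ncells + 1
    axes = [gmin[a] + spacing[a] * np.arange(node_shape[a]) for a in range(d)]
    grid_nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)

    def nid(idx):  # node grid index -> flat id
        return np.ravel_multi_index(idx, node_shape)

    element_type = "quad4" if d == 2 else "hex8"
    corners = ((reference_corners(element_type) + 1) / 2).astype(int)
    cells = []
    cell_ids = []
    for ci in product(*(range(nc) for nc in ncells)):
        cells.append([nid(tuple(np.array(ci) + c)) for c in corners])
        cell_ids.append(ci)
    cells = np.array(cells, dtype=int)
    cell_ids = np.array(cell_ids, dtype=int)

    # prune: keep cells containing >= 1 masked voxel centre
    cell_of_center = np.floor((centers - gmin) / spacing).astype(int)
    cell_of_center = np.clip(cell_of_center, 0, ncells - 1)
    occupied = set(map(tuple, cell_of_center))
    keep = np.array([tuple(ci) in occupied for ci in cell_ids], dtype=bool)
    cells, cell_ids = cells[keep], cell_ids[keep]

    used = np.unique(cells)
    remap = -np.ones(len(grid_nodes), dtype=int)
    remap[used] = np.arange(len(used))
    mesh = Mesh(
        nodes=grid_nodes[used],
        elements=remap[cells],
        element_type=element_type,
        grid={
            "gmin": gmin,
            "spacing": spacing,
            "ncells": ncells,
            "cell_lookup": {tuple(ci): e for e, ci in enumerate(cell_ids)},
        },
    )
    return mesh


def locate_point(mesh: Mesh, point) -> ElementLocation | None:
    """Find the element containing ``point`` and its natural coordinates.

    Rectilinear meshes use the exact per-axis affine inverse; tet4 the
    barycentric solve; general quad/hex fall back to a Newton inversion of
    the multilinear map.  Returns ``None`` when the point lies outside all
    elements (within a 1e-6 natural-coordinate tolerance).
    """
    point = np.asarray(point, dtype=float)
    tol = 1e-6
    if mesh.grid is not None:
        g = mesh.grid
        rel = (point - g["gmin"]) / g["spacing"]
        ci = np.floor(rel).astype(int)
        ci = np.minimum(np.maximum(ci, 0), g["ncells"] - 1)
        frac = rel - ci
        if np.any(frac < -tol) or np.any(frac > 1 + tol):
            return None
        e = g["cell_lookup"].get(tuple(ci))
        if e is None:
            return None
        xi = np.clip(2 * frac - 1, -1, 1)
        return ElementLocation(e, xi, shape_values(mesh.element_type, xi))

    for e, el in enumerate(mesh.elements):
        coords = mesh.nodes[el]
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        slack = tol * (1 + np.abs(hi - lo))
        if np.any(point < lo - slack) or np.any(point > hi + slack):
            continue
        xi = _invert_map(mesh, e, point, tol)
        if xi is not None:
            return ElementLocation(e, xi, shape_values(mesh.element_type, xi))
    return None


def _invert_map(mesh: Mesh, e: int, point: np.ndarray, tol: float):
    el = mesh.elements[e]
    coords = mesh.nodes[el]
    if mesh.element_type == "tet4":
        A = (coords[1:] - coords[0]).T
        xi = np.linalg.solve(A, point - coords[0])
        w = np.array([1 - xi.sum(), *xi])
        return xi if np.all(w >= -tol) else None
    # Newton on the multilinear map
    xi = np.zeros(mesh.ndim)
    for _ in range(30):
        xi = np.clip(xi, -1.5, 1.5)
        res = _shape_values_raw(mesh.element_type, xi) @ coords - point
        if np.linalg.norm(res) < 1e-12:
            break
        J = _jacobian(mesh, el, xi)
        xi = xi - np.linalg.solve(J, res)
    if np.any(np.abs(xi) > 1 + tol):
        return None
    return np.clip(xi, -1, 1)
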