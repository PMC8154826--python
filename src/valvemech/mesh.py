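"""8-node hexahedral meshes and legacy-VTK unstructured-grid I/O.

The mesh container is deliberately small: node coordinates, trilinear-hex
connectivity, integer material labels with a name map, named node/face sets,
and an explicit physical-unit tag (``mm`` at the organ/tissue scales, ``um``
at the cell scale).  All solver-side quantities (shape functions, Jacobians)
live here so that both the FE assembly and the shape-function-based mesh
refinement use the same basis.

Node ordering follows the common trilinear-hex convention (VTK_HEXAHEDRON):
nodes 0-3 are the bottom face counter-clockwise, 4-7 the top face.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexMesh",
    "NODE_XI",
    "FACE_NODES",
    "FACE_NAMES",
    "hex_shape",
    "hex_shape_grad",
    "gauss_points",
    "read_vtk",
    "write_vtk",
]

# Natural (parametric) coordinates of the 8 corner nodes, xi in [-1, 1]^3.
NODE_XI = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)

# Local faces with outward-pointing node ordering.
FACE_NODES = np.array(
    [
        [0, 4, 7, 3],  # -x
        [1, 2, 6, 5],  # +x
        [0, 1, 5, 4],  # -y
        [3, 7, 6, 2],  # +y
        [0, 3, 2, 1],  # -z
        [4, 5, 6, 7],  # +z
    ]
)
FACE_NAMES = ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax")


def hex_shape(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi); ``xi`` (..., 3) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * NODE_XI, axis=-1)


def hex_shape_grad(xi: np.ndarray) -> np.ndarray:
    """Shape-function gradients dN_a/dxi_k; ``xi`` (..., 3) -> (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    one = 1.0 + xi[..., None, :] * NODE_XI  # (..., 8, 3)
    grad = np.empty(xi.shape[:-1] + (8, 3))
    grad[..., 0] = 0.125 * NODE_XI[:, 0] * one[..., 1] * one[..., 2]
    grad[..., 1] = 0.125 * NODE_XI[:, 1] * one[..., 0] * one[..., 2]
    grad[..., 2] = 0.125 * NODE_XI[:, 2] * one[..., 0] * one[..., 1]
    return grad


def gauss_points(n: int = 2):
    """Tensor-product Gauss rule on [-1,1]^3: returns (points (G,3), weights (G,))."""
    if n == 1:
        return np.zeros((1, 3)), np.array([8.0])
    if n == 2:
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([[sx * g, sy * g, sz * g]
                        for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
        return pts, np.ones(8)
    x, w = np.polynomial.legendre.leggauss(n)
    pts = np.array([[a, b, c] for c in x for b in x for a in x])
    wts = np.array([wa * wb * wc for wc in w for wb in w for wa in w])
    return pts, wts


class MeshError(ValueError):
    """Invalid mesh topology or geometry."""


@dataclass
class HexMesh:
    """An 8-node hexahedral mesh with material ids and named sets."""

    points: np.ndarray                       # (N, 3) float
    cells: np.ndarray                        # (E, 8) int
    units: str = "mm"
    material: np.ndarray | None = None       # (E,) int
    material_names: dict[str, int] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)  # (K, 2): (elem, local face)
    structured_dims: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshError("points must be (N, 3)")
        if self.cells.ndim != 2 or self.cells.shape[1] != 8:
            raise MeshError("cells must be (E, 8)")
        if self.material is None:
            self.material = np.zeros(len(self.cells), dtype=np.int64)
        else:
            self.material = np.asarray(self.material, dtype=np.int64)
        if self.units not in ("mm", "um"):
            raise MeshError(f"unknown unit tag {self.units!r}; use 'mm' or 'um'")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.cells)

    def element_coords(self) -> np.ndarray:
        """Corner coordinates per element, (E, 8, 3)."""
        return self.points[self.cells]

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    def material_of(self, name: str) -> np.ndarray:
        """Element indices carrying the named material."""
        if name not in self.material_names:
            raise KeyError(f"material {name!r} not in mesh (have {sorted(self.material_names)})")
        return np.flatnonzero(self.material == self.material_names[name])

    def face_node_ids(self, faces: np.ndarray) -> np.ndarray:
        """Global node ids (K, 4) for (elem, local-face) pairs."""
        faces = np.asarray(faces, dtype=int)
        return self.cells[faces[:, 0][:, None], FACE_NODES[faces[:, 1]]]

    def boundary_faces(self) -> np.ndarray:
        """All (elem, local-face) pairs on the mesh boundary (faces used once)."""
        quads = self.cells[:, FACE_NODES]                     # (E, 6, 4)
        keys = np.sort(quads.reshape(-1, 4), axis=1)
        _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
        once = counts[inv] == 1
        e, f = np.divmod(np.flatnonzero(once), 6)
        return np.stack([e, f], axis=1)

    # -- validation -------------------------------------------------------
    def jacobians(self) -> np.ndarray:
        """det(dX/dxi) at the 2x2x2 Gauss points, (E, 8)."""
        pts, _ = gauss_points(2)
        dN = hex_shape_grad(pts)                              # (8, 8, 3)
        X = self.element_coords()                             # (E, 8, 3)
        J = np.einsum("gak,eaj->egkj", dN, X)                 # dX_j/dxi_k
        return np.linalg.det(J)

    def validate(self, raise_on_error: bool = True) -> dict:
        report: dict = {"ok": True, "messages": []}
        if self.cells.size and (self.cells.min() < 0 or self.cells.max() >= self.n_nodes):
            report["ok"] = False
            report["messages"].append("connectivity references nonexistent nodes")
        else:
            det = self.jacobians()
            bad = np.flatnonzero((det <= 0).any(axis=1))
            if bad.size:
                report["ok"] = False
                report["messages"].append(
                    f"non-positive Jacobian in elements {bad[:10].tolist()}"
                )
            report["min_jacobian"] = float(det.min()) if det.size else float("nan")
        for name, faces in self.face_sets.items():
            faces = np.asarray(faces)
            if faces.size and (faces[:, 0].max() >= self.n_elements or faces[:, 1].max() > 5):
                report["ok"] = False
                report["messages"].append(f"face set {name!r} references missing faces")
        if not report["ok"] and raise_on_error:
            raise MeshError("; ".join(report["messages"]))
        return report

    def copy(self) -> "HexMesh":
        return copy.deepcopy(self)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_grid(cls, xs, ys, zs, units: str = "mm") -> "HexMesh":
        """Structured box mesh from edge-coordinate arrays along each axis.

        Node/element numbering is x-fastest; the six box sides are registered
        as face sets and node sets named xmin/xmax/ymin/ymax/zmin/zmax.
        """
        xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
        for a in (xs, ys, zs):
            if a.ndim != 1 or len(a) < 2 or np.any(np.diff(a) <= 0):
                raise MeshError("grid coordinates must be increasing 1-D arrays")
        nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

        def nid(i, j, k):
            return (k * (ny + 1) + j) * (nx + 1) + i

        i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        i, j, k = (a.transpose(2, 1, 0).ravel() for a in (i, j, k))  # element id x-fastest
        cells = np.stack(
            [
                nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                nid(i, j + 1, k + 1),
            ],
            axis=1,
        )
        mesh = cls(points=points, cells=cells, units=units, structured_dims=(nx, ny, nz))

        def eid(i, j, k):
            return (k * ny + j) * nx + i

        jj, kk = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        ii, kk2 = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
        ii2, jj2 = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        sides = {
            "xmin": (eid(0, jj, kk).ravel(), 0),
            "xmax": (eid(nx - 1, jj, kk).ravel(), 1),
            "ymin": (eid(ii, 0, kk2).ravel(), 2),
            "ymax": (eid(ii, ny - 1, kk2).ravel(), 3),
            "zmin": (eid(ii2, jj2, 0).ravel(), 4),
            "zmax": (eid(ii2, jj2, nz - 1).ravel(), 5),
        }
        lo, hi = mesh.bbox()
        vals = {"xmin": (0, lo[0]), "xmax": (0, hi[0]), "ymin": (1, lo[1]),
                "ymax": (1, hi[1]), "zmin": (2, lo[2]), "zmax": (2, hi[2])}
        tol = 1e-9 * float(np.max(hi - lo))
        for name, (elems, lf) in sides.items():
            mesh.face_sets[name] = np.stack([elems, np.full(len(elems), lf)], axis=1)
            ax, v = vals[name]
            mesh.node_sets[name] = np.flatnonzero(np.abs(points[:, ax] - v) <= tol)
        return mesh


# ---------------------------------------------------------------------------
# Legacy-VTK ASCII I/O (unstructured grid, hexahedra only)
# ---------------------------------------------------------------------------

def write_vtk(mesh: HexMesh, path) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    The title line carries the unit tag so a round trip preserves it.
    Material ids are written as integer CELL_DATA.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"valvemech hex mesh units={mesh.units}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.points, fmt="%.12g")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {E * 9}\n")
        np.savetxt(fh, np.hstack([np.full((E, 1), 8, dtype=np.int64), mesh.cells]), fmt="%d")
        fh.write(f"CELL_TYPES {E}\n")
        np.savetxt(fh, np.full(E, 12, dtype=np.int64), fmt="%d")
        fh.write(f"CELL_DATA {E}\nSCALARS material int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.material, fmt="%d")
        if mesh.material_names:
            pairs = " ".join(f"{k}:{v}" for k, v in sorted(mesh.material_names.items()))
            fh.write(f"// material_names {pairs}\n")


def read_vtk(path) -> HexMesh:
    """Read a legacy ASCII VTK unstructured grid of hexahedra.

    The mesh is validated on import; an inverted-node-order file (top face
    listed first) is repaired by swapping the two faces.
    """
    with open(path) as fh:
        tokens_lines = fh.readlines()
    units = "mm"
    if len(tokens_lines) > 1 and "units=" in tokens_lines[1]:
        units = tokens_lines[1].split("units=")[1].strip() or "mm"
    material_names: dict[str, int] = {}
    body: list[str] = []
    for ln in tokens_lines:
        if ln.startswith("// material_names"):
            for pair in ln.split()[2:]:
                k, v = pair.rsplit(":", 1)
                material_names[k] = int(v)
        elif not ln.startswith(("#", "//")):
            body.append(ln)
    tok = " ".join(body).split()

    def find(kw):
        try:
            return tok.index(kw)
        except ValueError:
            raise MeshError(f"not a legacy VTK unstructured grid (missing {kw})") from None

    if "UNSTRUCTURED_GRID" not in tok:
        raise MeshError("unsupported VTK dataset type (need UNSTRUCTURED_GRID)")
    ip = find("POINTS")
    n = int(tok[ip + 1])
    pts = np.array(tok[ip + 3: ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ic = find("CELLS")
    ne = int(tok[ic + 1])
    raw = np.array(tok[ic + 3: ic + 3 + 9 * ne], dtype=np.int64).reshape(ne, 9)
    if not np.all(raw[:, 0] == 8):
        raise MeshError("only 8-node hexahedra are supported")
    cells = raw[:, 1:]
    it = find("CELL_TYPES")
    types = np.array(tok[it + 2: it + 2 + ne], dtype=int)
    if not np.all(types == 12):
        raise MeshError("only VTK_HEXAHEDRON cells are supported")
    material = None
    if "CELL_DATA" in tok and "material" in tok:
        im = tok.index("material")
        material = np.array(tok[im + 5: im + 5 + ne], dtype=np.int64)
    mesh = HexMesh(points=pts, cells=cells, units=units, material=material,
                   material_names=material_names)
    det = mesh.jacobians()
    if (det <= 0).all():
        mesh.cells = np.hstack([mesh.cells[:, 4:], mesh.cells[:, :4]])
        det = mesh.jacobians()
    if (det <= 0).any():
        bad = int(np.flatnonzero((det <= 0).any(axis=1))[0])
        raise MeshError(f"non-positive Jacobian in element {bad}")
    return mesh
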