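"""Organ -> tissue -> cell couplings (submodeling).

The chain implemented here:

1. ``extract_patch``    — cut a 5x5x3-element belly patch (with its nodal
   displacement history) out of the organ-scale mesh.
2. ``refine_patch``     — subdivide every patch element in its own parametric
   space through the trilinear shape functions (default 6x6x2 = 72 children
   per parent, 75 -> 5400 elements).
3. ``interpolate_boundary_displacements`` — transfer the organ displacement
   history to the refined boundary nodes via the same shape functions.
4. ``assign_layers``    — label fibrosa / spongiosa / ventricularis through
   the thickness (41 / 30 / 29 % by default, fibrosa on the aortic side).
5. ``run_tissue_stage`` — pre-stretch linearly to the start-of-diastole
   configuration, then track the diastolic displacement history.
6. ``extract_fibrosa_stress`` — circumferential/radial Cauchy stress averaged
   over the central region of the fibrosa layer (away from the driven
   boundary).
7. ``build_cell_patch`` / ``run_cell_stage`` — a fibrosa-ECM micro patch with
   one ellipsoidal VIC inclusion in the symmetry corner, loaded by the
   tissue-derived stress curves as follower normal tractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biaxial as _biaxial
from .fehex import (BoundaryHistory, DirichletBC, SolveResult, SolverConfig,
                    TieBC, TractionBC, apply_symmetry, solve_static)
from .mesh import HexMesh, hex_shape

__all__ = [
    "PatchSelection",
    "LayerSpec",
    "CellSpec",
    "ParentMap",
    "extract_patch",
    "refine_patch",
    "interpolate_boundary_displacements",
    "assign_layers",
    "run_tissue_stage",
    "extract_fibrosa_stress",
    "build_cell_patch",
    "run_cell_stage",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class PatchSelection:
    """Element index block (i, j, k ranges, half-open) in a structured mesh."""

    i: tuple[int, int] = (0, 5)
    j: tuple[int, int] = (0, 5)
    k: tuple[int, int] = (0, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.i[1] - self.i[0], self.j[1] - self.j[0], self.k[1] - self.k[0])

    @property
    def n_elements(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz


@dataclass
class LayerSpec:
    """Through-thickness layer fractions, listed from the aortic surface down.

    Defaults: fibrosa 41 %, spongiosa 30 %, ventricularis 29 % of the total
    thickness, fibrosa on the +z (aortic) side.
    """

    fractions: tuple[float, ...] = (0.41, 0.30, 0.29)
    names: tuple[str, ...] = ("fibrosa", "spongiosa", "ventricularis")
    fibrosa_top: bool = True

    def __post_init__(self):
        if len(self.fractions) != len(self.names):
            raise ValueError("one fraction per layer name")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("layer fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("layer fractions must sum to 1")

    def boundaries_from_bottom(self) -> np.ndarray:
        """Cumulative fraction boundaries measured from z = bottom."""
        fr = np.asarray(self.fractions, dtype=float)
        if self.fibrosa_top:
            fr = fr[::-1]
        return np.concatenate([[0.0], np.cumsum(fr)])

    def names_from_bottom(self) -> tuple[str, ...]:
        return tuple(reversed(self.names)) if self.fibrosa_top else self.names


@dataclass
class CellSpec:
    """Cell-scale patch geometry (lengths in micrometres).

    The VIC is an ellipsoid centred at the symmetry corner (origin); its
    ``vic_axes`` are full axis lengths, so the octant actually meshed has
    semi-axes of half these values.
    """

    dims: tuple[float, float, float] = (100.0, 100.0, 30.0)   # circ, rad, normal
    vic_axes: tuple[float, float, float] = (10.0, 7.7, 7.7)
    element_size: float = 1.25
    min_elems_per_axis: int = 4

    def __post_init__(self):
        if any(d <= 0 for d in self.dims):
            raise ValueError("patch dimensions must be positive")
        if any(a < 0 for a in self.vic_axes):
            raise ValueError("VIC axes must be non-negative")
        if self.element_size <= 0:
            raise ValueError("element size must be positive")
        for d, a in zip(self.dims, self.vic_axes):
            if a / 2.0 > d:
                raise ValueError("VIC semi-axes must fit inside the patch")
        for d in self.dims:
            n = d / self.element_size
            if abs(n - round(n)) > 1e-8:
                raise ValueError("element size must divide the patch dimensions")

    @classmethod
    def reduced(cls) -> "CellSpec":
        """Down-scaled patch for fast FE runs (same VIC, coarser admissible grid)."""
        return cls(dims=(19.25, 19.25, 15.4), element_size=1.925)


@dataclass
class ParentMap:
    """Child-node parametric coordinates within parent elements."""

    parent_elem: np.ndarray      # (Nc,) parent element index
    xi: np.ndarray               # (Nc, 3) natural coordinates in the parent
    parent: HexMesh
    factors: tuple[int, int, int]


# ---------------------------------------------------------------------------
# Patch extraction and refinement
# ---------------------------------------------------------------------------

def extract_patch(mesh: HexMesh, U: np.ndarray,
                  selection: PatchSelection | None = None
                  ) -> tuple[HexMesh, np.ndarray, np.ndarray]:
    """Cut a structured sub-block out of an organ mesh.

    ``U`` is the (T, N, 3) nodal displacement history of the organ mesh.
    Returns (patch mesh, patch displacement history (T, M, 3), node map).
    """
    if mesh.structured_dims is None:
        raise ValueError("patch extraction requires a structured mesh")
    selection = selection or PatchSelection()
    nx, ny, nz = mesh.structured_dims
    (i0, i1), (j0, j1), (k0, k1) = selection.i, selection.j, selection.k
    if not (0 <= i0 < i1 <= nx and 0 <= j0 < j1 <= ny and 0 <= k0 < k1 <= nz):
        raise ValueError(f"selection {selection} outside mesh dims {(nx, ny, nz)}")
    ii, jj, kk = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1),
                             np.arange(k0, k1), indexing="ij")
    eids = ((kk * ny + jj) * nx + ii).transpose(2, 1, 0).ravel()
    cells_old = mesh.cells[eids]
    used, inverse = np.unique(cells_old, return_inverse=True)
    patch = HexMesh(points=mesh.points[used],
                    cells=inverse.reshape(cells_old.shape),
                    units=mesh.units,
                    material=mesh.material[eids].copy(),
                    material_names=dict(mesh.material_names),
                    structured_dims=selection.shape)
    U = np.asarray(U, dtype=float)
    return patch, U[:, used, :], used


def refine_patch(patch: HexMesh, factors: tuple[int, int, int] = (6, 6, 2)
                 ) -> tuple[HexMesh, ParentMap]:
    """Shape-function subdivision of every element in its parametric space.

    Each parent hex is split into fx*fy*fz children; new node positions are
    trilinear interpolations of the parent corner coordinates, so planar
    parent faces are preserved exactly and neighbouring parents share the
    interface nodes (deduplicated by coordinate).
    """
    fx, fy, fz = factors
    if min(fx, fy, fz) < 1 or any(int(f) != f for f in factors):
        raise ValueError("subdivision factors must be positive integers")
    gx = np.linspace(-1.0, 1.0, fx + 1)
    gy = np.linspace(-1.0, 1.0, fy + 1)
    gz = np.linspace(-1.0, 1.0, fz + 1)
    Z, Y, X = np.meshgrid(gz, gy, gx, indexing="ij")
    lattice = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)  # (L, 3)
    N = hex_shape(lattice)                                          # (L, 8)

    npx, npy = fx + 1, fy + 1

    def lid(i, j, k):
        return (k * npy + j) * npx + i

    i, j, k = np.meshgrid(np.arange(fx), np.arange(fy), np.arange(fz), indexing="ij")
    i, j, k = (a.transpose(2, 1, 0).ravel() for a in (i, j, k))
    local_cells = np.stack(
        [lid(i, j, k), lid(i + 1, j, k), lid(i + 1, j + 1, k), lid(i, j + 1, k),
         lid(i, j, k + 1), lid(i + 1, j, k + 1), lid(i + 1, j + 1, k + 1),
         lid(i, j + 1, k + 1)], axis=1)

    scale = float(np.max(np.abs(patch.points))) or 1.0
    decimals = max(0, 9 - int(np.floor(np.log10(scale))) if scale >= 1 else 9)
    key_of: dict[tuple, int] = {}
    coords: list[np.ndarray] = []
    pelem: list[int] = []
    pxi: list[np.ndarray] = []
    cells = np.empty((patch.n_elements * len(local_cells), 8), dtype=np.int64)
    material = np.empty(len(cells), dtype=np.int64)
    Xe = patch.element_coords()
    row = 0
    for e in range(patch.n_elements):
        pts = N @ Xe[e]                                            # (L, 3)
        gids = np.empty(len(pts), dtype=np.int64)
        keys = np.round(pts, decimals)
        for l, key in enumerate(map(tuple, keys)):
            gid = key_of.get(key)
            if gid is None:
                gid = len(coords)
                key_of[key] = gid
                coords.append(pts[l])
                pelem.append(e)
                pxi.append(lattice[l])
            gids[l] = gid
        nloc = len(local_cells)
        cells[row:row + nloc] = gids[local_cells]
        material[row:row + nloc] = patch.material[e]
        row += nloc
    refined = HexMesh(points=np.array(coords), cells=cells, units=patch.units,
                      material=material, material_names=dict(patch.material_names))
    pmap = ParentMap(parent_elem=np.array(pelem, dtype=np.int64),
                     xi=np.array(pxi), parent=patch, factors=(fx, fy, fz))
    return refined, pmap


def interpolate_displacements(U_patch: np.ndarray, pmap: ParentMap,
                              nodes: np.ndarray | None = None) -> np.ndarray:
    """Trilinear evaluation of the parent displacement history at child nodes."""
    if nodes is None:
        nodes = np.arange(len(pmap.parent_elem))
    pe = pmap.parent_elem[nodes]
    xi = pmap.xi[nodes]
    N = hex_shape(xi)                                   # (M, 8)
    conn = pmap.parent.cells[pe]                        # (M, 8)
    U_patch = np.asarray(U_patch, dtype=float)
    return np.einsum("ma,tmai->tmi", N, U_patch[:, conn, :])


def interpolate_boundary_displacements(
        U_patch: np.ndarray, refined: HexMesh, pmap: ParentMap,
        times: np.ndarray, markers: dict | None = None,
        boundary: str = "lateral") -> BoundaryHistory:
    """Trilinear transfer of the organ displacement history to refined
    boundary nodes.

    ``boundary="lateral"`` drives only the four cut faces (the physical top
    and bottom leaflet surfaces stay traction-free); ``"all"`` prescribes
    every boundary node, which forces the organ kinematics through the
    thickness as well.
    """
    if boundary not in ("lateral", "all"):
        raise ValueError("boundary must be 'lateral' or 'all'")
    bfaces = refined.boundary_faces()
    if boundary == "lateral":
        quads = refined.face_node_ids(bfaces)
        pts = refined.points[quads]                     # (K, 4, 3)
        n = np.cross(pts[:, 1] - pts[:, 0], pts[:, 3] - pts[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        keep = np.abs(n[:, 2]) < 0.5                    # reference normal not +-z
        bfaces = bfaces[keep]
    nodes = np.unique(refined.face_node_ids(bfaces))
    vals = interpolate_displacements(U_patch, pmap, nodes)
    return BoundaryHistory(times=np.asarray(times, dtype=float),
                           dirichlet=[DirichletBC(nodes=nodes, values=vals,
                                                  name=f"organ_bc_{boundary}")],
                           markers=dict(markers or {}))


def assign_layers(patch: HexMesh, spec: LayerSpec | None = None,
                  tol: float = 1e-9) -> HexMesh:
    """Label elements by tissue layer from their through-thickness position.

    Element layers must align with the fraction boundaries (each element must
    lie wholly inside one layer); otherwise an error suggests compatible
    subdivision factors.
    """
    spec = spec or LayerSpec()
    out = patch.copy()
    z = out.element_coords()[..., 2]
    zmin, zmax = float(out.points[:, 2].min()), float(out.points[:, 2].max())
    th = zmax - zmin
    bounds = zmin + spec.boundaries_from_bottom() * th
    names = spec.names_from_bottom()
    lo = z.min(axis=1)
    hi = z.max(axis=1)
    name_to_id = {n: i for i, n in enumerate(sorted(set(spec.names)))}
    mat = np.empty(out.n_elements, dtype=np.int64)
    atol = tol * max(th, 1.0)
    for e in range(out.n_elements):
        layer = None
        for li in range(len(names)):
            if lo[e] >= bounds[li] - atol and hi[e] <= bounds[li + 1] + atol:
                layer = names[li]
                break
        if layer is None:
            raise ValueError(
                f"element {e} spans a layer boundary (z in [{lo[e]:.4g}, {hi[e]:.4g}]); "
                "use through-thickness subdivision factors compatible with the "
                "layer fractions")
        mat[e] = name_to_id[layer]
    out.material = mat
    out.material_names = name_to_id
    return out


# ---------------------------------------------------------------------------
# Tissue stage
# ---------------------------------------------------------------------------

def _diastole_indices(markers: dict, T: int, stride: int) -> list[int]:
    """Strided diastolic sample indices, always keeping marked frames and the end."""
    m = markers["start_of_diastole"]
    idx = set(range(m, T, max(1, stride)))
    idx.add(T - 1)
    for v in markers.values():
        if m <= v < T:
            idx.add(int(v))
    return sorted(idx)


def _preload_indices(history: BoundaryHistory, n_pre: int, preload: str):
    """Sample schedule for the two phases.

    ``preload="history"`` tracks the organ-scale samples up to the
    start-of-diastole marker (the surrogate path is isochoric, which keeps
    the bulk-penalty term quiescent); ``"linear"`` replaces them with an
    n_pre-step linear displacement ramp to the start-of-diastole state.
    """
    if "start_of_diastole" not in history.markers:
        raise ValueError("history lacks the 'start_of_diastole' marker")
    if preload not in ("history", "linear"):
        raise ValueError("preload must be 'history' or 'linear'")
    m = history.markers["start_of_diastole"]
    if preload == "history":
        return list(range(m + 1)), None
    return [m], np.linspace(0.0, 1.0, n_pre + 1)


def _phased_history(history: BoundaryHistory, n_pre: int, stride: int,
                    preload: str = "history") -> BoundaryHistory:
    """Preload to the start-of-diastole state, then diastole tracking."""
    m = history.markers["start_of_diastole"]
    T = history.n_steps
    pre_idx, ramp_s = _preload_indices(history, n_pre, preload)
    dia_idx = _diastole_indices(history.markers, T, stride)
    t_m = history.times[m]
    if ramp_s is None:
        pre_times = history.times[pre_idx[:-1]]
        n_preload = len(pre_idx) - 1
    else:
        pre_times = t_m - (1.0 - ramp_s[:-1])
        n_preload = n_pre
    times = np.concatenate([pre_times, [t_m], history.times[dia_idx[1:]]])
    phases = ["preload"] * n_preload + ["diastole"] * len(dia_idx)
    dirichlet = []
    for bc in history.dirichlet:
        if bc.values is None:
            dirichlet.append(DirichletBC(bc.nodes, None, bc.comps, bc.name))
            continue
        if ramp_s is None:
            pre_vals = bc.values[pre_idx[:-1]]
        else:
            pre_vals = ramp_s[:-1, None, None] * bc.values[m][None]
        vals = np.concatenate([pre_vals, bc.values[m][None], bc.values[dia_idx[1:]]])
        dirichlet.append(DirichletBC(bc.nodes, vals, bc.comps, bc.name))
    tractions = []
    for tr in history.tractions:
        if ramp_s is None:
            pre_sig = tr.sigma[pre_idx[:-1]]
        else:
            pre_sig = ramp_s[:-1] * tr.sigma[m]
        sig = np.concatenate([pre_sig, [tr.sigma[m]], tr.sigma[dia_idx[1:]]])
        tractions.append(TractionBC(tr.faces, sig, tr.follower, tr.name))
    markers = {"start_of_diastole": n_preload}
    for name, v in history.markers.items():
        if name != "start_of_diastole" and v in dia_idx:
            markers[name] = n_preload + dia_idx.index(v)
    return BoundaryHistory(times=times, dirichlet=dirichlet, tractions=tractions,
                           markers=markers, phases=phases,
                           metadata=dict(history.metadata))


def run_tissue_stage(refined: HexMesh, materials: dict[int, object],
                     history: BoundaryHistory, config: SolverConfig | None = None,
                     n_pre: int = 10, stride: int = 1,
                     U_patch: np.ndarray | None = None,
                     pmap: ParentMap | None = None,
                     preload: str = "history") -> SolveResult:
    """Pre-stretch to the start-of-diastole state, then track the diastolic
    displacement history.

    When the full organ displacement history (``U_patch``, ``pmap``) is
    supplied, its trilinear interpolation over all refined nodes seeds the
    Newton solve of each step (incremental predictor); this is what makes
    the near-reference-state solve of the exponential layers tractable.
    """
    staged = _phased_history(history, n_pre=n_pre, stride=stride, preload=preload)
    predictor = None
    if U_patch is not None and pmap is not None:
        V_org = interpolate_displacements(U_patch, pmap)   # (T_org, N, 3)
        m = history.markers["start_of_diastole"]
        pre_idx, ramp_s = _preload_indices(history, n_pre, preload)
        dia_idx = _diastole_indices(history.markers, history.n_steps, stride)
        if ramp_s is None:
            V_pre = V_org[pre_idx]
        else:
            V_pre = ramp_s[:, None, None] * V_org[m][None]
        V = np.concatenate([V_pre, V_org[dia_idx[1:]]])    # (T_staged, N, 3)

        def predictor(s, a0, a1, u0):
            prev = V[s - 1] if s > 0 else np.zeros_like(V[0])
            return u0 + (a1 - a0) * (V[s] - prev)

    return solve_static(refined, materials, staged, config, predictor=predictor)


def extract_fibrosa_stress(result: SolveResult, mesh: HexMesh,
                           region: str = "central", fraction: float = 1.0 / 3.0,
                           layer: str = "fibrosa") -> pd.DataFrame:
    """Volume-averaged circumferential/radial Cauchy stress in the fibrosa.

    Averages sigma_cc and sigma_rr (Gauss-weighted, reference volumes) over
    the fibrosa elements whose in-plane centroid falls in the central
    ``fraction`` of the patch footprint (``region="all"`` keeps every fibrosa
    element).
    """
    if layer in mesh.material_names:
        elems = mesh.material_of(layer)
    else:  # single-material patch: use everything
        elems = np.arange(mesh.n_elements)
    if region == "central":
        c = mesh.centroids()[elems]
        lo, hi = mesh.bbox()
        mid = 0.5 * (lo + hi)
        half = 0.5 * fraction * (hi - lo)
        keep = (np.abs(c[:, 0] - mid[0]) <= half[0] + 1e-12) & \
               (np.abs(c[:, 1] - mid[1]) <= half[1] + 1e-12)
        elems = elems[keep]
    if elems.size == 0:
        raise ValueError("no elements in the requested fibrosa region")
    w = result.detJw[elems]                       # (e, 8)
    wsum = w.sum()
    sig = result.cauchy[:, elems]                 # (T, e, 8, 3, 3)
    s_c = np.einsum("eg,teg->t", w, sig[..., 0, 0]) / wsum
    s_r = np.einsum("eg,teg->t", w, sig[..., 1, 1]) / wsum
    return pd.DataFrame({"time": result.times, "phase": result.phases,
                         "sigma_circ_MPa": s_c, "sigma_rad_MPa": s_r})


# ---------------------------------------------------------------------------
# Cell stage
# ---------------------------------------------------------------------------

def build_cell_patch(spec: CellSpec | None = None) -> HexMesh:
    """Structured ECM patch with an octant-ellipsoid VIC at the corner.

    Elements whose centroid satisfies the ellipsoid inequality are labelled
    ``vic``; the mesh is conforming by construction (staircase boundary).
    An error is raised when the grid cannot resolve the inclusion (fewer
    than ``min_elems_per_axis`` elements across any full VIC axis).
    """
    spec = spec or CellSpec()
    h = spec.element_size
    a, b, c = (ax / 2.0 for ax in spec.vic_axes)
    has_vic = min(spec.vic_axes) > 0
    if has_vic:
        for ax in spec.vic_axes:
            if ax / h < spec.min_elems_per_axis:
                raise ValueError(
                    f"element size {h} too coarse to resolve the VIC "
                    f"(need >= {spec.min_elems_per_axis} elements across each axis)")
    ns = [int(round(d / h)) for d in spec.dims]
    mesh = HexMesh.from_grid(*(np.linspace(0.0, d, n + 1) for d, n in zip(spec.dims, ns)),
                             units="um")
    mesh.material_names = {"ecm": 0, "vic": 1}
    if has_vic:
        cen = mesh.centroids()
        inside = (cen[:, 0] / a) ** 2 + (cen[:, 1] / b) ** 2 + (cen[:, 2] / c) ** 2 <= 1.0
        mesh.material[inside] = 1
    return mesh


def _densify_stress_history(t, sc, sr, ratio: float = 2.0, floor: float = 0.05):
    """Insert geometrically spaced samples where the stress magnitude jumps."""
    tt, cc, rr = [t[0]], [sc[0]], [sr[0]]
    for i in range(1, len(t)):
        m0 = max(abs(sc[i - 1]), abs(sr[i - 1]), floor)
        m1 = max(abs(sc[i]), abs(sr[i]), floor)
        big, small = max(m0, m1), min(m0, m1)
        n_ins = int(np.ceil(np.log(big / small) / np.log(ratio))) - 1 \
            if big > ratio * small else 0
        for k in range(1, n_ins + 1):
            target = m0 * (m1 / m0) ** (k / (n_ins + 1))   # geometric m0 -> m1
            a = min(max((target - m0) / (m1 - m0), 0.0), 1.0)
            tt.append(t[i - 1] + (t[i] - t[i - 1]) * k / (n_ins + 1))
            cc.append(sc[i - 1] + a * (sc[i] - sc[i - 1]))
            rr.append(sr[i - 1] + a * (sr[i] - sr[i - 1]))
        tt.append(t[i])
        cc.append(sc[i])
        rr.append(sr[i])
    return np.asarray(tt), np.asarray(cc), np.asarray(rr)


def run_cell_stage(cell_mesh: HexMesh, materials: dict[int, object],
                   sigma: pd.DataFrame, config: SolverConfig | None = None,
                   n_pre: int = 6, ecm_material=None,
                   predictor: bool = True) -> SolveResult:
    """Load the cell patch with tissue-derived stress curves.

    Symmetry planes x=0, y=0, z=0; follower normal tractions sigma_circ on
    the +x face and sigma_rad on the +y face; the outer thickness face is
    traction-free.  Phase A ramps to the first (start-of-diastole) stress
    state, phase B tracks the curves.  A homogeneous material-point solution
    of the ECM provides the Newton initial guess during the ramp, which the
    exponential toe region of the fibrosa ECM makes essentially mandatory.
    """
    cfg = config or SolverConfig()
    if "phase" in sigma.columns and (sigma["phase"] == "diastole").any():
        sigma = sigma[sigma["phase"] == "diastole"]
    t = sigma["time"].to_numpy(dtype=float)
    sc = sigma["sigma_circ_MPa"].to_numpy(dtype=float)
    sr = sigma["sigma_rad_MPa"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError("empty stress history")

    # insert geometric intermediates across large stress jumps: the strain of
    # the exponential ECM grows with log(sigma), so linear substepping in
    # stress wastes Newton attempts
    t, sc, sr = _densify_stress_history(t, sc, sr)

    sym = [apply_symmetry(cell_mesh, ax, 0.0) for ax in ("x", "y", "z")]
    ramp = np.linspace(0.0, 1.0, n_pre + 1)
    times = np.concatenate([t[0] - (1.0 - ramp), t[1:]])
    sig_c = np.concatenate([ramp * sc[0], sc[1:]])
    sig_r = np.concatenate([ramp * sr[0], sr[1:]])
    phases = ["preload"] * n_pre + ["diastole"] * (len(t))
    tractions = [
        TractionBC(cell_mesh.face_sets["xmax"], sig_c, follower=True, name="sigma_circ"),
        TractionBC(cell_mesh.face_sets["ymax"], sig_r, follower=True, name="sigma_rad"),
    ]
    # RVE-style loading: the loaded faces stay plane (normal displacement
    # tied); the leaflet law has no fiber-shear term, and a free traction
    # face would otherwise shear-band and fold at high stress
    ties = [TieBC(np.unique(cell_mesh.face_node_ids(cell_mesh.face_sets["xmax"])),
                  comp=0, name="xmax_plane"),
            TieBC(np.unique(cell_mesh.face_node_ids(cell_mesh.face_sets["ymax"])),
                  comp=1, name="ymax_plane")]
    history = BoundaryHistory(times=times, dirichlet=sym, tractions=tractions,
                              ties=ties, markers={"start_of_diastole": n_pre},
                              phases=phases)

    guess_fn = None
    if predictor:
        if ecm_material is None:
            ecm_material = materials[cell_mesh.material_names.get("ecm", 0)]
        X = cell_mesh.points
        n_ramp = n_pre

        lam_cache: dict[tuple, np.ndarray] = {}

        def lam_at(step, a):
            key = (step, round(a, 12))
            if key not in lam_cache:
                pc = sig_c[step - 1] if step else 0.0
                pr = sig_r[step - 1] if step else 0.0
                s_c = pc + a * (sig_c[step] - pc)
                s_r = pr + a * (sig_r[step] - pr)
                lam_cache[key] = _biaxial.stretches_from_stress(ecm_material, s_c, s_r)
            return lam_cache[key]

        def guess_fn(step, a0, a1, u0):
            # incremental homogeneous guess: keeps the local VIC correction
            try:
                d_lam = lam_at(step, a1) - lam_at(step, a0)
            except _biaxial.BiaxialSolveError:
                return None
            return u0 + X * d_lam

    return solve_static(cell_mesh, materials, history, cfg, predictor=guess_fn)
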