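"""Quasi-static, total-Lagrangian FE solver for 8-node hexahedral meshes.

Geometrically nonlinear equilibrium is solved by Newton continuation over a
time-sampled boundary history (Dirichlet displacements, symmetry planes, and
normal follower tractions).  Inertia is deliberately absent: the diastolic
plateau states of interest are equilibrium states, so a quasi-static implicit
solve replaces an explicit dynamic one.

Numerics:

* 2x2x2 Gauss quadrature.  Selective reduced integration (single centre
  point on the volumetric part) is available as an option, but full
  integration is the default: with the near-zero deviatoric toe stiffness of
  the exponential leaflet materials, a centre-point penalty term leaves
  spurious low-energy modes that stall the Newton iteration, while
  volumetric locking is mild for the membrane-like states of interest.
* Newton with relative residual tolerance (default 1e-6), step-length capping
  and automatic interval halving (default depth 8) on divergence.
* Follower tractions are re-evaluated on the deformed faces each iteration;
  their load-stiffness contribution to the tangent is neglected, which costs
  a few extra iterations but keeps the tangent symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import FACE_NODES, HexMesh, gauss_points, hex_shape_grad

__all__ = [
    "DirichletBC",
    "TractionBC",
    "TieBC",
    "BoundaryHistory",
    "SolverConfig",
    "SolveResult",
    "StaticProblem",
    "assemble",
    "solve_static",
    "apply_symmetry",
    "follower_traction",
    "follower_traction_stiffness",
    "reduction_operator",
    "SolveError",
    "GeometryError",
]

_I3 = np.eye(3)


class SolveError(RuntimeError):
    """Newton continuation failed after exhausting substepping."""


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Boundary conditions
# ---------------------------------------------------------------------------

@dataclass
class DirichletBC:
    """Prescribed displacements on a node set.

    ``values`` is (T, M, 3) per history sample, or None for homogeneous
    (zero) constraints; ``comps`` masks which components are constrained.
    """

    nodes: np.ndarray
    values: np.ndarray | None = None
    comps: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=bool))
    name: str = ""

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.comps = np.asarray(self.comps, dtype=bool)
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    def values_at(self, t_index: int) -> np.ndarray:
        if self.values is None:
            return np.zeros((len(self.nodes), 3))
        return self.values[t_index]


@dataclass
class TractionBC:
    """Normal traction (MPa) on a face set; positive = outward tension."""

    faces: np.ndarray                 # (K, 2) (elem, local face)
    sigma: np.ndarray                 # (T,) target normal Cauchy stress
    follower: bool = True
    name: str = ""

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))


@dataclass
class TieBC:
    """Equal-displacement constraint: one component shared by a node set.

    Used to keep a loaded face plane (RVE-style loading): the leaflet
    materials carry almost no fiber-shear stiffness, and without the tie a
    traction-loaded face develops an unresisted shear band and folds over.
    """

    nodes: np.ndarray
    comp: int                         # 0, 1, 2
    name: str = ""

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        if self.comp not in (0, 1, 2):
            raise ValueError("comp must be 0, 1 or 2")


@dataclass
class BoundaryHistory:
    """Time-sampled boundary conditions plus named time markers."""

    times: np.ndarray
    dirichlet: list[DirichletBC] = field(default_factory=list)
    tractions: list[TractionBC] = field(default_factory=list)
    ties: list[TieBC] = field(default_factory=list)
    markers: dict[str, int] = field(default_factory=dict)
    phases: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("history times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def validate(self, mesh: HexMesh) -> None:
        T = self.n_steps
        for bc in self.dirichlet:
            if bc.nodes.size and bc.nodes.max() >= mesh.n_nodes:
                raise ValueError(f"Dirichlet record {bc.name!r} references missing nodes")
            if bc.values is not None and bc.values.shape != (T, len(bc.nodes), 3):
                raise ValueError(f"Dirichlet record {bc.name!r} has wrong value shape")
        for tr in self.tractions:
            if tr.faces.size and tr.faces[:, 0].max() >= mesh.n_elements:
                raise ValueError(f"traction record {tr.name!r} references missing faces")
            if len(tr.sigma) != T:
                raise ValueError(f"traction record {tr.name!r} has wrong length")
        for tie in self.ties:
            if tie.nodes.size and tie.nodes.max() >= mesh.n_nodes:
                raise ValueError(f"tie record {tie.name!r} references missing nodes")
        for idx in self.markers.values():
            if not (0 <= idx < T):
                raise ValueError("marker index outside the time grid")


@dataclass
class SolverConfig:
    rtol: float = 1e-6
    atol: float = 1e-10
    max_iter: int = 100
    max_halvings: int = 8
    du_cap_frac: float = 0.1     # Newton step cap, fraction of bbox diagonal
    max_backtracks: int = 12
    min_step: float = 1e-3       # fallback damping when backtracking stalls
    stagnation_window: int = 15  # bail out early when this many iterations
    stagnation_factor: float = 0.5   # fail to halve the residual
    store_fields: bool = True


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class StaticProblem:
    """Precomputed kinematic data and assembly for one mesh + material table."""

    def __init__(self, mesh: HexMesh, materials: dict[int, object],
                 sri: bool = False):
        mesh.validate()
        self.mesh = mesh
        self.materials = materials
        self.sri = sri
        present = set(np.unique(mesh.material).tolist())
        missing = present - set(materials)
        if missing:
            raise KeyError(f"no material supplied for mesh material ids {sorted(missing)}")
        self.groups = [(materials[mid], np.flatnonzero(mesh.material == mid))
                       for mid in sorted(present)]

        X = mesh.element_coords()                              # (E, 8, 3)
        pts, w = gauss_points(2)
        dN = hex_shape_grad(pts)                               # (8, 8, 3)
        Jac = np.einsum("gak,eaj->egkj", dN, X)                # dX_j/dxi_k
        det = np.linalg.det(Jac)
        invJ = np.linalg.inv(Jac)
        self.B = np.einsum("gak,egJk->egaJ", dN, invJ)         # dN_a/dX_J
        self.detJw = det * w                                   # (E, 8)

        pts_c, w_c = gauss_points(1)
        dNc = hex_shape_grad(pts_c)
        Jc = np.einsum("gak,eaj->egkj", dNc, X)
        self.Bc = np.einsum("gak,egJk->egaJ", dNc, np.linalg.inv(Jc))
        self.detJwc = np.linalg.det(Jc) * w_c                  # (E, 1)

        # strain-displacement operator in matrix form: dF_(iJ) = L @ du_(a,c)
        self._L = {id(self.B): self._strain_matrix(self.B),
                   id(self.Bc): self._strain_matrix(self.Bc)}

        self.ndof = 3 * mesh.n_nodes
        dofs = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(-1, 24)
        self._rows = np.repeat(dofs, 24, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 24)).ravel()
        self._dofs = dofs
        lo, hi = mesh.bbox()
        self.bbox_diag = float(np.linalg.norm(hi - lo))

    # -- kinematics -------------------------------------------------------
    def deformation(self, u: np.ndarray, B: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.cells]                                # (E, 8, 3)
        return _I3 + np.einsum("eai,egaJ->egiJ", ue, B)

    @staticmethod
    def _strain_matrix(B: np.ndarray) -> np.ndarray:
        """L with dF_(3i+J) = L[.., 3i+J, 3a+c] du_(a,c): L = delta_ic B_aJ."""
        E, G = B.shape[:2]
        L = np.zeros((E, G, 9, 24))
        BT = np.swapaxes(B, -1, -2)                            # (E, G, 3, 8)
        for i in range(3):
            L[:, :, 3 * i:3 * i + 3, i::3] = BT
        return L

    def _part(self, u, B, detJw, part, want_tangent):
        """Internal force and stiffness from one quadrature family.

        The tangent block per Gauss point is L^T A L with
        A_(iJ)(kL) = delta_ik S_JL + F_iI C_IJML F_kM, evaluated as batched
        matrix products (FI = F kron I)."""
        F = self.deformation(u, B)
        if np.linalg.det(F).min() <= 0.0 or not np.isfinite(F).all():
            return None, None
        nE, nG = F.shape[0], F.shape[1]
        S = np.zeros_like(F)
        D = np.zeros(F.shape + (3, 3)) if want_tangent else None
        for mat, idx in self.groups:
            Sg, Dg = mat.pk2_and_tangent(F[idx], part=part, want_tangent=want_tangent)
            S[idx] = Sg
            if want_tangent:
                D[idx] = Dg
        P = np.einsum("egiI,egIJ->egiJ", F, S)
        fint = np.einsum("eg,egiJ,egaJ->eai", detJw, P, B)
        if not want_tangent:
            return fint, None
        FI = np.einsum("egiI,JL->egiJIL", F, _I3).reshape(nE, nG, 9, 9)
        A9 = FI @ D.reshape(nE, nG, 9, 9) @ np.swapaxes(FI, -1, -2)
        # geometric part: block-diagonal delta_ik S_JL
        for i in range(3):
            A9[:, :, 3 * i:3 * i + 3, 3 * i:3 * i + 3] += S
        L = self._L[id(B)]
        Ke = np.swapaxes(L, -1, -2) @ (A9 * detJw[..., None, None]) @ L
        return fint, Ke.sum(axis=1)

    def assemble(self, u: np.ndarray, want_tangent: bool = True):
        """Internal force vector and sparse tangent at displacement ``u``.

        Returns (fint (ndof,), K csr or None); (None, None) signals an
        inadmissible state (element inversion / overflow) to the stepper.
        """
        if self.sri:
            f_dev, K_dev = self._part(u, self.B, self.detJw, "dev", want_tangent)
            if f_dev is None:
                return None, None
            f_vol, K_vol = self._part(u, self.Bc, self.detJwc, "vol", want_tangent)
            if f_vol is None:
                return None, None
            f_el, K_el = f_dev + f_vol, (K_dev + K_vol) if want_tangent else None
        else:
            f_el, K_el = self._part(u, self.B, self.detJw, "full", want_tangent)
            if f_el is None:
                return None, None
        fint = np.zeros(self.ndof)
        np.add.at(fint.reshape(-1, 3), self.mesh.cells.ravel(),
                  f_el.reshape(-1, 3))
        if not want_tangent:
            return fint, None
        Ke = K_el.reshape(-1)
        K = sp.coo_matrix((Ke, (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return fint, K

    # -- stress recovery ----------------------------------------------------
    def stresses(self, u: np.ndarray):
        """(F, cauchy) at the 2x2x2 Gauss points (with SRI, the volumetric
        stress is evaluated at the element centre)."""
        F = self.deformation(u, self.B)
        S = np.zeros_like(F)
        if self.sri:
            Fc = self.deformation(u, self.Bc)
            for mat, idx in self.groups:
                Sd, _ = mat.pk2_and_tangent(F[idx], part="dev", want_tangent=False)
                Sv, _ = mat.pk2_and_tangent(Fc[idx], part="vol", want_tangent=False)
                S[idx] = Sd + Sv
        else:
            for mat, idx in self.groups:
                S[idx], _ = mat.pk2_and_tangent(F[idx], want_tangent=False)
        J = np.linalg.det(F)
        sig = np.einsum("egiI,egIJ,egjJ->egij", F, S, F) / J[..., None, None]
        return F, sig

    def total_energy(self, u: np.ndarray) -> float:
        """Stored strain energy, with the same quadrature split as the assembly."""
        F = self.deformation(u, self.B)
        total = 0.0
        if self.sri:
            Fc = self.deformation(u, self.Bc)
            for mat, idx in self.groups:
                total += float(np.sum(self.detJw[idx] * mat.energy(F[idx], part="dev")))
                total += float(np.sum(self.detJwc[idx] * mat.energy(Fc[idx], part="vol")))
        else:
            for mat, idx in self.groups:
                total += float(np.sum(self.detJw[idx] * mat.energy(F[idx])))
        return total

    # -- external loads -----------------------------------------------------
    def traction_force(self, faces: np.ndarray, sigma: float, u: np.ndarray,
                       follower: bool = True) -> np.ndarray:
        return follower_traction(self.mesh, faces, sigma, u if follower else None)


_QXI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_QGP = np.array([[sx / np.sqrt(3), sy / np.sqrt(3)]
                 for sy in (-1, 1) for sx in (-1, 1)])


def follower_traction(mesh: HexMesh, faces: np.ndarray, sigma: float,
                      u: np.ndarray | None = None) -> np.ndarray:
    """Nodal force vector from a uniform normal traction on a face set.

    With ``u`` given, the traction acts on the deformed faces (follower
    load tracking the current area and normal); with ``u=None`` it is a dead
    load on the reference geometry.  Positive sigma pulls along the outward
    normal.
    """
    faces = np.asarray(faces, dtype=np.int64)
    fn = mesh.face_node_ids(faces)                             # (K, 4)
    x = mesh.points[fn]
    if u is not None:
        x = x + u[fn]
    fvec = np.zeros((mesh.n_nodes, 3))
    for gp in _QGP:
        N = 0.25 * (1 + gp[0] * _QXI[:, 0]) * (1 + gp[1] * _QXI[:, 1])
        dNx = 0.25 * _QXI[:, 0] * (1 + gp[1] * _QXI[:, 1])
        dNe = 0.25 * _QXI[:, 1] * (1 + gp[0] * _QXI[:, 0])
        tx = np.einsum("a,kai->ki", dNx, x)
        te = np.einsum("a,kai->ki", dNe, x)
        nda = np.cross(tx, te)                                 # outward, |.| = dA
        if np.any(np.linalg.norm(nda, axis=1) <= 0):
            raise GeometryError("degenerate face in traction set")
        np.add.at(fvec, fn.ravel(),
                  (sigma * N[None, :, None] * nda[:, None, :]).reshape(-1, 3))
    return fvec.ravel()


def _skew(v: np.ndarray) -> np.ndarray:
    """Batched cross-product matrices: skew(v) @ w = v x w."""
    S = np.zeros(v.shape[:-1] + (3, 3))
    S[..., 0, 1], S[..., 0, 2] = -v[..., 2], v[..., 1]
    S[..., 1, 0], S[..., 1, 2] = v[..., 2], -v[..., 0]
    S[..., 2, 0], S[..., 2, 1] = -v[..., 1], v[..., 0]
    return S


def follower_traction_stiffness(mesh: HexMesh, faces: np.ndarray, sigma: float,
                                u: np.ndarray) -> sp.csr_matrix:
    """d(f_ext)/d(u) of a follower normal traction (non-symmetric).

    f_a = sigma sum_gp N_a (t_xi x t_eta); differentiating the deformed
    tangents gives K_ab = sigma sum_gp N_a [skew(t_xi) dN_eta,b
    - skew(t_eta) dN_xi,b].
    """
    faces = np.asarray(faces, dtype=np.int64)
    fn = mesh.face_node_ids(faces)                             # (K, 4)
    x = mesh.points[fn] + u[fn]
    ndof = 3 * mesh.n_nodes
    Ke = np.zeros((len(faces), 4, 3, 4, 3))
    for gp in _QGP:
        N = 0.25 * (1 + gp[0] * _QXI[:, 0]) * (1 + gp[1] * _QXI[:, 1])
        dNx = 0.25 * _QXI[:, 0] * (1 + gp[1] * _QXI[:, 1])
        dNe = 0.25 * _QXI[:, 1] * (1 + gp[0] * _QXI[:, 0])
        tx = np.einsum("a,kai->ki", dNx, x)
        te = np.einsum("a,kai->ki", dNe, x)
        blk = (np.einsum("kij,b->kbij", _skew(tx), dNe)
               - np.einsum("kij,b->kbij", _skew(te), dNx))     # (K, 4, 3, 3)
        Ke += sigma * np.einsum("a,kbij->kaibj", N, blk)
    dofs = (3 * fn[:, :, None] + np.arange(3)).reshape(len(faces), 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    return sp.coo_matrix((Ke.reshape(-1), (rows, cols)),
                         shape=(ndof, ndof)).tocsr()


def assemble(mesh: HexMesh, materials: dict[int, object], u: np.ndarray):
    """One-shot residual (internal force) and tangent; convenience wrapper."""
    prob = StaticProblem(mesh, materials)
    u = np.asarray(u, dtype=float).reshape(mesh.n_nodes, 3)
    return prob.assemble(u)


def apply_symmetry(mesh: HexMesh, axis, value: float | None = None,
                   tol: float | None = None) -> DirichletBC:
    """Zero normal displacement on an axis-aligned symmetry plane.

    The plane must coincide with a mesh face (a bounding plane of the mesh);
    otherwise a GeometryError is raised.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if ax not in (0, 1, 2):
        raise GeometryError(f"unknown symmetry axis {axis!r}")
    lo, hi = mesh.bbox()
    if tol is None:
        tol = 1e-8 * max(float(np.max(hi - lo)), 1.0)
    if value is None:
        value = float(lo[ax])
    if not (abs(value - lo[ax]) <= tol or abs(value - hi[ax]) <= tol):
        raise GeometryError(
            f"symmetry plane {('x', 'y', 'z')[ax]}={value} does not coincide "
            "with a mesh face")
    nodes = np.flatnonzero(np.abs(mesh.points[:, ax] - value) <= tol)
    comps = np.zeros(3, dtype=bool)
    comps[ax] = True
    return DirichletBC(nodes=nodes, values=None, comps=comps,
                       name=f"sym_{('x', 'y', 'z')[ax]}")


# ---------------------------------------------------------------------------
# Newton continuation
# ---------------------------------------------------------------------------

@dataclass
class SolveResult:
    """Converged states at every history sample."""

    times: np.ndarray
    u: np.ndarray                       # (T, N, 3)
    F: np.ndarray | None                # (T, E, 8, 3, 3)
    cauchy: np.ndarray | None           # (T, E, 8, 3, 3)
    fint: np.ndarray                    # (T, ndof) internal forces (reactions)
    detJw: np.ndarray                   # (E, 8) reference Gauss weights
    mesh: HexMesh
    phases: list[str]
    converged: np.ndarray
    iterations: list[int]
    markers: dict[str, int] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.times)

    @staticmethod
    def concat(a: "SolveResult", b: "SolveResult") -> "SolveResult":
        return SolveResult(
            times=np.concatenate([a.times, b.times]),
            u=np.concatenate([a.u, b.u]),
            F=None if a.F is None else np.concatenate([a.F, b.F]),
            cauchy=None if a.cauchy is None else np.concatenate([a.cauchy, b.cauchy]),
            fint=np.concatenate([a.fint, b.fint]),
            detJw=a.detJw, mesh=a.mesh,
            phases=list(a.phases) + list(b.phases),
            converged=np.concatenate([a.converged, b.converged]),
            iterations=list(a.iterations) + list(b.iterations),
            markers={**a.markers, **b.markers},
        )


def _fixed_dof_tables(history: BoundaryHistory, n_nodes: int):
    """Per-record flat dof indices; later records override earlier ones."""
    tables = []
    for bc in history.dirichlet:
        comps = np.flatnonzero(bc.comps)
        dofs = (3 * bc.nodes[:, None] + comps[None, :]).ravel()
        tables.append((bc, comps, dofs))
    return tables


def reduction_operator(ndof: int, fixmask: np.ndarray,
                       ties: list[TieBC] | None = None) -> sp.csr_matrix:
    """Sparse map from reduced unknowns to full dofs.

    Free dofs map one-to-one; the dofs of a tie group share one reduced
    unknown; prescribed dofs get empty rows (they are set directly).
    """
    red = -np.ones(ndof, dtype=np.int64)
    nxt = 0
    for tie in ties or []:
        dofs = 3 * tie.nodes + tie.comp
        dofs = dofs[~fixmask[dofs]]
        if dofs.size == 0:
            continue
        red[dofs] = nxt
        nxt += 1
    rest = np.flatnonzero((red < 0) & ~fixmask)
    red[rest] = nxt + np.arange(len(rest))
    nred = nxt + len(rest)
    rows = np.flatnonzero(red >= 0)
    return sp.csr_matrix((np.ones(len(rows)), (rows, red[rows])),
                         shape=(ndof, nred))


def _newton(prob: StaticProblem, u: np.ndarray, fixmask: np.ndarray,
            fixvals: np.ndarray, tractions, cfg: SolverConfig,
            T: sp.csr_matrix | None = None):
    """Solve equilibrium at fixed BC targets; returns (ok, iterations).

    Newton with a residual-norm backtracking line search and adaptive
    Levenberg damping of the direction: the very soft deviatoric response
    of the exponential materials near the reference state makes undamped
    steps overshoot wildly, and near-null shear modes pollute raw
    directions.  Damping and the line search change only the iteration
    path, never the converged state.  ``T`` (see
    :func:`reduction_operator`) folds equal-dof tie constraints into the
    reduced unknowns.
    """
    if T is None:
        T = reduction_operator(prob.ndof, fixmask)
    Tt = T.T.tocsr()
    uf = u.reshape(-1)
    uf[fixmask] = fixvals[fixmask]
    du_cap = cfg.du_cap_frac * prob.bbox_diag

    def residual_norm(want_tangent):
        fint, K = prob.assemble(u, want_tangent=want_tangent)
        if fint is None:
            return None, None, None
        fext = np.zeros(prob.ndof)
        for faces, sig, follower in tractions:
            if sig != 0.0:
                fext += follower_traction(prob.mesh, faces, sig,
                                          u if follower else None)
        r = fint - fext
        if not np.isfinite(r).all():
            return None, None, None
        res = np.linalg.norm(Tt @ r)
        ref = max(np.linalg.norm(fint), np.linalg.norm(fext))
        return res, ref, (Tt @ r, K)

    mu = 0.0   # Levenberg-style damping; the residual stays exact, so
    # damping changes the Newton path, never the converged solution
    res_window: list[float] = []
    for it in range(cfg.max_iter + 1):
        res, ref, rk = residual_norm(True)
        if res is None:
            return False, it
        if res <= max(cfg.rtol * ref, cfg.atol):
            return True, it
        if it == cfg.max_iter:
            return False, it
        res_window.append(res)
        if len(res_window) > cfg.stagnation_window:
            res_window.pop(0)
            if res > cfg.stagnation_factor * res_window[0]:
                return False, it   # no useful progress: hand back for substepping
        r_red, K = rk
        for faces, sig, follower in tractions:
            if follower and sig != 0.0:
                K = K - follower_traction_stiffness(prob.mesh, faces, sig, u)
        Kred = (Tt @ K @ T).tocsc()
        diag_scale = np.abs(Kred.diagonal()).mean() or 1.0
        accepted = False
        du = None
        u_base = uf.copy()
        for _trial in range(6):
            Ksolve = Kred if mu == 0.0 else (
                Kred + (mu * diag_scale) * sp.identity(Kred.shape[0], format="csc"))
            try:
                du_red = spla.spsolve(Ksolve, -r_red)
            except Exception:
                du_red = None
            if du_red is None or not np.isfinite(du_red).all():
                mu = min(max(10.0 * mu, 1e-8), 1e4)
                continue
            du = T @ du_red
            m = np.abs(du).max(initial=0.0)
            if m > du_cap:
                du *= du_cap / m
            step = 1.0
            for _ in range(cfg.max_backtracks + 1):
                uf[:] = u_base + step * du
                res_new, _, _ = residual_norm(False)
                if res_new is not None and res_new < res:
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                if step == 1.0:
                    mu /= 8.0
                    if mu < 1e-12:
                        mu = 0.0
                elif step < 0.25:
                    # direction dominated by noisy soft modes: damp harder
                    mu = min(max(4.0 * mu, 1e-8), 1e4)
                break
            uf[:] = u_base
            mu = min(max(10.0 * mu, 1e-8), 1e4)
        if not accepted:
            if du is None:
                return False, it
            uf[:] = u_base + cfg.min_step * du   # last resort: tiny step
    return False, cfg.max_iter


def solve_static(mesh: HexMesh, materials: dict[int, object],
                 history: BoundaryHistory, config: SolverConfig | None = None,
                 u0: np.ndarray | None = None,
                 predictor=None) -> SolveResult:
    """Track the boundary history quasi-statically.

    ``predictor(step_index, alpha0, alpha1, u_at_alpha0)`` may supply an
    initial guess before the Newton solve of a (sub)step; alpha in [0, 1]
    parameterises the interval from the previous converged sample.
    """
    cfg = config or SolverConfig()
    history.validate(mesh)
    prob = StaticProblem(mesh, materials)
    T = history.n_steps
    tables = _fixed_dof_tables(history, mesh.n_nodes)
    fixmask = np.zeros(prob.ndof, dtype=bool)
    for _, _, dofs in tables:
        fixmask[dofs] = True
    T_red = reduction_operator(prob.ndof, fixmask, history.ties)

    def targets(ti: int) -> np.ndarray:
        vals = np.zeros(prob.ndof)
        for bc, comps, dofs in tables:
            vals[dofs] = bc.values_at(ti)[:, comps].ravel()
        return vals

    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else np.array(u0, dtype=float)
    out_u = np.empty((T, mesh.n_nodes, 3))
    out_F = np.empty((T, mesh.n_elements, 8, 3, 3)) if cfg.store_fields else None
    out_sig = np.empty_like(out_F) if cfg.store_fields else None
    out_fint = np.empty((T, prob.ndof))
    iters: list[int] = []
    conv = np.zeros(T, dtype=bool)

    prev_vals = np.zeros(prob.ndof)
    prev_sig = [0.0] * len(history.tractions)
    for s in range(T):
        tgt_vals = targets(s)
        tgt_sig = [float(tr.sigma[s]) for tr in history.tractions]

        def attempt(a0: float, a1: float, depth: int, total_it: int) -> int:
            nonlocal u
            vals = prev_vals + a1 * (tgt_vals - prev_vals)
            sigs = [(tr.faces, prev_sig[i] + a1 * (tgt_sig[i] - prev_sig[i]), tr.follower)
                    for i, tr in enumerate(history.tractions)]
            u_save = u.copy()
            if predictor is not None:
                guess = predictor(s, a0, a1, u)
                if guess is not None:
                    u = guess.copy()
            ok, it = _newton(prob, u, fixmask, vals, sigs, cfg, T_red)
            total_it += it
            if ok:
                return total_it
            u = u_save
            if depth >= cfg.max_halvings:
                raise SolveError(
                    f"step {s} (t={history.times[s]:g}) failed after "
                    f"{cfg.max_halvings} halvings")
            mid = 0.5 * (a0 + a1)
            total_it = attempt(a0, mid, depth + 1, total_it)
            return attempt(mid, a1, depth + 1, total_it)

        n_it = attempt(0.0, 1.0, 0, 0)
        prev_vals, prev_sig = tgt_vals, tgt_sig
        conv[s] = True
        iters.append(n_it)
        out_u[s] = u
        fint, _ = prob.assemble(u, want_tangent=False)
        out_fint[s] = fint
        if cfg.store_fields:
            F, sig = prob.stresses(u)
            out_F[s], out_sig[s] = F, sig

    phases = list(history.phases) if history.phases is not None else ["load"] * T
    return SolveResult(times=history.times.copy(), u=out_u, F=out_F,
                       cauchy=out_sig, fint=out_fint, detJw=prob.detJw,
                       mesh=mesh, phases=phases, converged=conv,
                       iterations=iters, markers=dict(history.markers))
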