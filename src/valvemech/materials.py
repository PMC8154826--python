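"""Constitutive models for aortic valve leaflet tissue and cells.

Two families are provided:

* A Fung-type anisotropic hyperelastic law for the leaflet and its fibrosa /
  ventricularis layers,

      U = C/2 (exp(Q) - 1) + K ((J^2 - 1)/2 - ln J),

  with Q a quadratic form in the Green-Lagrange strain expressed in the
  material frame (f = fiber/circumferential, s = cross-fiber/radial,
  n = through-thickness).  The default exponent is

      Q = 2 b1 tr(E) + b2 E_ff^2 + b3 (E_ss^2 + E_nn^2 + 2 E_ns^2),

  i.e. the fiber term enters squared, keeping the energy even in fiber
  strain; ``q_form="as_printed"`` switches to the variant with a linear
  b2*E_ff term found in parts of the Guccione-derived literature.

* Finite-strain isotropic elasticity for the spongiosa layer and the valve
  interstitial cell (VIC), parameterised by (E_mod, nu).  Two extensions of
  the small-strain law are implemented: Saint Venant-Kirchhoff (the simplest
  objective extension, exposed as :func:`iso_stress`) and a compressible
  neo-Hookean law, which remains well-behaved under the large diastolic
  in-plane stretches where SVK loses its traction-free thickness solution.
  The FE pipeline uses the neo-Hookean form by default.

All evaluators are batched: ``F`` may have shape (..., 3, 3).
Stress/stiffness units are MPa throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FungParams",
    "IsoElasticParams",
    "DeformationState",
    "FungMaterial",
    "SVKMaterial",
    "NeoHookeanMaterial",
    "strain_energy",
    "pk2_stress",
    "cauchy_stress",
    "iso_stress",
    "stability_check",
    "load_presets",
    "get_preset",
    "material_from_preset",
    "InvalidDeformationError",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant (or not finite)."""


def _orthonormal(frame: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (3, 3):
        raise ValueError("frame must be a 3x3 matrix with rows f, s, n")
    if not np.allclose(frame @ frame.T, _I3, atol=tol):
        raise ValueError("material frame (f, s, n) must be orthonormal to 1e-10")
    return frame


@dataclass(frozen=True)
class FungParams:
    """Fung-type parameter set: stress scale C, exponents b1..b3, bulk K (MPa)."""

    C: float
    b1: float
    b2: float
    b3: float
    K: float
    frame: np.ndarray = field(default_factory=lambda: _I3.copy())
    name: str = ""

    def __post_init__(self):
        if not (self.C > 0):
            raise ValueError("C must be positive")
        if not (self.K > 0):
            raise ValueError("K must be positive")
        object.__setattr__(self, "frame", _orthonormal(self.frame))

    def with_frame(self, f, s, n) -> "FungParams":
        return FungParams(self.C, self.b1, self.b2, self.b3, self.K,
                          frame=np.array([f, s, n], dtype=float), name=self.name)


@dataclass(frozen=True)
class IsoElasticParams:
    """Isotropic elastic parameters: Young modulus (MPa) and Poisson ratio."""

    E_mod: float
    nu: float
    model: str = "neo_hookean"
    name: str = ""

    def __post_init__(self):
        if not (self.E_mod > 0):
            raise ValueError("E_mod must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E_mod * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E_mod / (2 * (1 + self.nu))
        return lam, mu


class DeformationState:
    """A deformation gradient with derived Green strain and volume ratio."""

    def __init__(self, F: np.ndarray):
        F = np.asarray(F, dtype=float)
        if F.shape[-2:] != (3, 3):
            raise ValueError("F must have shape (..., 3, 3)")
        if not np.all(np.isfinite(F)):
            raise InvalidDeformationError("non-finite deformation gradient")
        self.F = F
        self.J = np.linalg.det(F)
        if np.any(self.J <= 0):
            raise InvalidDeformationError("non-positive det(F)")

    @property
    def E_green(self) -> np.ndarray:
        return 0.5 * (np.einsum("...ki,...kj->...ij", self.F, self.F) - _I3)

    @property
    def C_right(self) -> np.ndarray:
        return np.einsum("...ki,...kj->...ij", self.F, self.F)


# ---------------------------------------------------------------------------
# Material evaluators (batched; used directly by the FE assembly)
# ---------------------------------------------------------------------------

_Q_CLIP = 85.0  # exp overflow guard; states this far out never survive a Newton step


def _green(F):
    return 0.5 * (np.einsum("...ki,...kj->...ij", F, F) - _I3)


def _vol_stress_tangent(F, K, want_tangent):
    """Penalty part K((J^2-1)/2 - lnJ): PK2 stress and tangent dS/dE."""
    C = np.einsum("...ki,...kj->...ij", F, F)
    J2 = np.linalg.det(C)
    Cinv = np.linalg.inv(C)
    S = K * (J2 - 1.0)[..., None, None] * Cinv
    if not want_tangent:
        return S, None
    CC = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    Csym = np.einsum("...ik,...jl->...ijkl", Cinv, Cinv) + np.einsum(
        "...il,...jk->...ijkl", Cinv, Cinv)
    D = 2.0 * K * J2[..., None, None, None, None] * CC \
        - K * (J2 - 1.0)[..., None, None, None, None] * Csym
    return S, D


class FungMaterial:
    """Batched stress/tangent evaluation of the Fung-type law."""

    def __init__(self, params: FungParams, q_form: str = "squared"):
        if q_form not in ("squared", "as_printed"):
            raise ValueError("q_form must be 'squared' or 'as_printed'")
        self.params = params
        self.q_form = q_form
        self.R = params.frame.T  # columns f, s, n
        # Q is (at most) quadratic in E, so dG/dE is a constant 4th-order
        # tensor; build it once by differencing the affine map E -> G(E).
        G0 = self._G(np.zeros((3, 3)))
        H = np.empty((3, 3, 3, 3))
        for k in range(3):
            for l in range(3):
                Eb = np.zeros((3, 3))
                Eb[k, l] = 1.0
                H[:, :, k, l] = self._G(Eb) - G0
        self._G0, self._H = G0, H

    # Q and its strain gradient, evaluated with E symmetrised internally.
    def _frame_strain(self, E):
        Es = 0.5 * (E + np.swapaxes(E, -1, -2))
        return np.einsum("ia,...ij,jb->...ab", self.R, Es, self.R)

    def _Q(self, E):
        p = self.params
        Ef = self._frame_strain(E)
        tr = np.trace(Ef, axis1=-2, axis2=-1)
        Eff, Ess, Enn = Ef[..., 0, 0], Ef[..., 1, 1], Ef[..., 2, 2]
        Ens = 0.5 * (Ef[..., 1, 2] + Ef[..., 2, 1])
        fiber = p.b2 * Eff**2 if self.q_form == "squared" else p.b2 * Eff
        return 2 * p.b1 * tr + fiber + p.b3 * (Ess**2 + Enn**2 + 2 * Ens**2)

    def _G(self, E):
        p = self.params
        Ef = self._frame_strain(E)
        Eff, Ess, Enn = Ef[..., 0, 0], Ef[..., 1, 1], Ef[..., 2, 2]
        Ens = 0.5 * (Ef[..., 1, 2] + Ef[..., 2, 1])
        Gf = np.zeros(Ef.shape)
        Gf[..., 0, 0] = 2 * p.b2 * Eff if self.q_form == "squared" else p.b2
        Gf[..., 1, 1] = 2 * p.b3 * Ess
        Gf[..., 2, 2] = 2 * p.b3 * Enn
        Gf[..., 1, 2] = Gf[..., 2, 1] = 2 * p.b3 * Ens
        Gf = Gf + 2 * p.b1 * _I3
        return np.einsum("ai,...ab,bj->...ij", self.R, Gf, self.R)

    def energy(self, F, part: str = "full"):
        p = self.params
        out = 0.0
        if part in ("full", "dev"):
            Q = np.clip(self._Q(_green(F)), None, _Q_CLIP)
            out = out + 0.5 * p.C * np.expm1(Q)
        if part in ("full", "vol"):
            J = np.linalg.det(F)
            out = out + p.K * (0.5 * (J**2 - 1.0) - np.log(J))
        return out

    def pk2(self, F, part: str = "full"):
        return self.pk2_and_tangent(F, part, want_tangent=False)[0]

    def pk2_and_tangent(self, F, part: str = "full", want_tangent: bool = True):
        p = self.params
        S = 0.0
        D = 0.0 if want_tangent else None
        if part in ("full", "dev"):
            E = _green(F)
            Q = np.clip(self._Q(E), None, _Q_CLIP)
            G = self._G(E)
            fac = (0.5 * p.C * np.exp(Q))[..., None, None]
            S = S + fac * G
            if want_tangent:
                D = D + fac[..., None, None] * (
                    np.einsum("...ij,...kl->...ijkl", G, G) + self._H)
        if part in ("full", "vol"):
            Sv, Dv = _vol_stress_tangent(F, p.K, want_tangent)
            S = S + Sv
            if want_tangent:
                D = D + Dv
        return S, D


class SVKMaterial:
    """Saint Venant-Kirchhoff: S = lam tr(E) I + 2 mu E."""

    def __init__(self, params: IsoElasticParams):
        self.params = params
        self.lam, self.mu = params.lame
        lam, mu = self.lam, self.mu
        D = lam * np.einsum("ij,kl->ijkl", _I3, _I3) + mu * (
            np.einsum("ik,jl->ijkl", _I3, _I3) + np.einsum("il,jk->ijkl", _I3, _I3))
        self._D = D
        self._Ddev = D - lam * np.einsum("ij,kl->ijkl", _I3, _I3)

    def energy(self, F, part: str = "full"):
        E = _green(F)
        tr = np.trace(E, axis1=-2, axis2=-1)
        ee = np.einsum("...ij,...ij->...", E, E)
        if part == "dev":
            return self.mu * ee
        if part == "vol":
            return 0.5 * self.lam * tr**2
        return 0.5 * self.lam * tr**2 + self.mu * ee

    def pk2(self, F, part: str = "full"):
        return self.pk2_and_tangent(F, part, want_tangent=False)[0]

    def pk2_and_tangent(self, F, part: str = "full", want_tangent: bool = True):
        E = _green(F)
        tr = np.trace(E, axis1=-2, axis2=-1)[..., None, None]
        if part == "dev":
            S = 2 * self.mu * E
            D = self._Ddev
        elif part == "vol":
            S = self.lam * tr * np.broadcast_to(_I3, E.shape)
            D = self.lam * np.einsum("ij,kl->ijkl", _I3, _I3)
        else:
            S = self.lam * tr * _I3 + 2 * self.mu * E
            D = self._D
        if want_tangent:
            D = np.broadcast_to(D, E.shape + (3, 3))
        else:
            D = None
        return S, D


class NeoHookeanMaterial:
    """Compressible neo-Hookean consistent with (E_mod, nu) at small strain.

    U = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2;
    S = mu (I - C^-1) + lam ln J C^-1.
    """

    def __init__(self, params: IsoElasticParams):
        self.params = params
        self.lam, self.mu = params.lame

    def energy(self, F, part: str = "full"):
        C = np.einsum("...ki,...kj->...ij", F, F)
        J = np.linalg.det(F)
        lnJ = np.log(J)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        if part == "dev":
            return 0.5 * self.mu * (I1 - 3.0) - self.mu * lnJ
        if part == "vol":
            return 0.5 * self.lam * lnJ**2
        return 0.5 * self.mu * (I1 - 3.0) - self.mu * lnJ + 0.5 * self.lam * lnJ**2

    def pk2(self, F, part: str = "full"):
        return self.pk2_and_tangent(F, part, want_tangent=False)[0]

    def pk2_and_tangent(self, F, part: str = "full", want_tangent: bool = True):
        lam, mu = self.lam, self.mu
        C = np.einsum("...ki,...kj->...ij", F, F)
        Cinv = np.linalg.inv(C)
        lnJ = 0.5 * np.log(np.linalg.det(C))[..., None, None]
        if part == "dev":
            S = mu * (_I3 - Cinv)
        elif part == "vol":
            S = lam * lnJ * Cinv
        else:
            S = mu * (_I3 - Cinv) + lam * lnJ * Cinv
        if not want_tangent:
            return S, None
        Csym = np.einsum("...ik,...jl->...ijkl", Cinv, Cinv) + np.einsum(
            "...il,...jk->...ijkl", Cinv, Cinv)
        CC = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
        lnJ4 = lnJ[..., None, None]
        if part == "dev":
            D = mu * Csym
        elif part == "vol":
            D = lam * CC - lam * lnJ4 * Csym
        else:
            D = lam * CC + (mu - lam * lnJ4) * Csym
        return S, D


# ---------------------------------------------------------------------------
# Spec-level operations on (params, state)
# ---------------------------------------------------------------------------

def _fung_material(params: FungParams, q_form: str = "squared") -> FungMaterial:
    return FungMaterial(params, q_form=q_form)


def strain_energy(params: FungParams, state: DeformationState,
                  q_form: str = "squared") -> np.ndarray | float:
    """Strain energy density U (MPa) of the Fung-type law."""
    out = _fung_material(params, q_form).energy(state.F)
    return float(out) if np.ndim(out) == 0 else out


def pk2_stress(params: FungParams, state: DeformationState,
               q_form: str = "squared") -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dU/dE (MPa)."""
    return _fung_material(params, q_form).pk2(state.F)


def cauchy_stress(params, state: DeformationState, q_form: str = "squared") -> np.ndarray:
    """Cauchy stress: push-forward sigma = J^-1 F S F^T (MPa)."""
    if isinstance(params, FungParams):
        S = _fung_material(params, q_form).pk2(state.F)
    elif isinstance(params, IsoElasticParams):
        S = iso_stress(params, state)
    else:
        S = params.pk2(state.F)  # a material evaluator
    F, J = state.F, state.J
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]


def iso_stress(params: IsoElasticParams, state: DeformationState) -> np.ndarray:
    """Saint Venant-Kirchhoff PK2 stress S = lam tr(E) I + 2 mu E (MPa)."""
    return SVKMaterial(params).pk2(state.F)


def tangent_voigt(material, F) -> np.ndarray:
    """dS/dE as a symmetric 6x6 in the Mandel basis (sqrt(2)-scaled shears)."""
    _, D = material.pk2_and_tangent(np.asarray(F, dtype=float))
    idx = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    r2 = np.sqrt(2.0)
    M = np.empty(D.shape[:-4] + (6, 6))
    for a, (i, j) in enumerate(idx):
        for b, (k, l) in enumerate(idx):
            fac = (r2 if i != j else 1.0) * (r2 if k != l else 1.0)
            sym = 0.25 * (D[..., i, j, k, l] + D[..., j, i, k, l]
                          + D[..., i, j, l, k] + D[..., j, i, l, k])
            M[..., a, b] = fac * sym
    return 0.5 * (M + np.swapaxes(M, -1, -2))


def stability_check(params: FungParams, strain_range=(0.0, 0.2), n: int = 11,
                    q_form: str = "squared", tol: float = 1e-8) -> list[dict]:
    """Scan biaxial Green-strain states for loss of tangent positive definiteness.

    States are isochoric (lambda_n = 1/(lambda_f lambda_s)) on an n x n grid of
    in-plane Green strains; each state's 6x6 Mandel tangent is eigen-tested.
    Returns the flagged states (possibly empty).
    """
    lo, hi = strain_range
    if n <= 0 or hi < lo:
        return []
    mat = _fung_material(params, q_form)
    grid = np.linspace(lo, hi, n)
    Eff, Ess = np.meshgrid(grid, grid, indexing="ij")
    lf = np.sqrt(2 * Eff + 1.0)
    ls = np.sqrt(2 * Ess + 1.0)
    ln = 1.0 / (lf * ls)
    F = np.zeros(Eff.shape + (3, 3))
    F[..., 0, 0], F[..., 1, 1], F[..., 2, 2] = lf, ls, ln
    M = tangent_voigt(mat, F)
    eig = np.linalg.eigvalsh(M)[..., 0]
    scale = np.abs(M).max(axis=(-1, -2)) + 1e-30
    bad = eig < -tol * scale
    flagged = []
    for i, j in zip(*np.nonzero(bad)):
        flagged.append({"E_ff": float(Eff[i, j]), "E_ss": float(Ess[i, j]),
                        "min_eig": float(eig[i, j])})
    return flagged


# ---------------------------------------------------------------------------
# Preset catalog
# ---------------------------------------------------------------------------

def load_presets() -> dict[str, FungParams | IsoElasticParams]:
    """Load the shipped material catalog (leaflet layers, spongiosa, VIC, wall)."""
    text = (importlib.resources.files("valvemech") / "data" / "material_presets.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, FungParams | IsoElasticParams] = {}
    for name, d in raw.get("fung", {}).items():
        out[name] = FungParams(C=d["C"], b1=d["b1"], b2=d["b2"], b3=d["b3"],
                               K=d["K"], name=name)
    for name, d in raw.get("isotropic", {}).items():
        out[name] = IsoElasticParams(E_mod=d["E_mod"], nu=d["nu"],
                                     model=d.get("model", "neo_hookean"), name=name)
    return out


def get_preset(name: str):
    presets = load_presets()
    if name not in presets:
        raise KeyError(f"unknown material preset {name!r}; have {sorted(presets)}")
    return presets[name]


def material_from_preset(name: str, q_form: str = "squared"):
    """Instantiate the FE evaluator for a catalog entry."""
    p = get_preset(name)
    if isinstance(p, FungParams):
        return FungMaterial(p, q_form=q_form)
    if p.model == "svk":
        return SVKMaterial(p)
    return NeoHookeanMaterial(p)
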