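"""Synthetic organ-scale kinematics: the data-generating stand-in for a full
subject-specific aortic-root simulation.

The generator emulates what the downstream stages actually consume from an
organ-scale model of the leaflet belly:

* a 5x5x3-element belly patch (~2 mm x 2 mm x 0.4289 mm, three geometric
  layers sized 41/30/29 % of the thickness),
* a cardiac-cycle displacement history whose in-plane Green strains rise
  with the transvalvular pressure, peak at peak diastole and then plateau,
  with peak values configurable inside the physiological ranges
  (circumferential 0.31-0.35, radial 0.23-0.59),
* isochoric kinematics: lambda_n = 1/(lambda_c lambda_r), so J = 1
  identically when the optional bending gradient is off,
* a "start_of_diastole" marker (the tissue stage pre-stretches linearly to
  this configuration before tracking the curve).

It also provides the paradigmatic leaflet thickness profile (belly 0.4289 mm
to 1.2 mm at the attachment edge and the free margin) and noise-controlled
synthetic biaxial datasets for the parameter-identification workflow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import biaxial as _biaxial
from .materials import FungParams
from .mesh import HexMesh

__all__ = [
    "SurrogateConfig",
    "LeafletThicknessProfile",
    "OrganPatch",
    "generate_organ_patch",
    "generate_thickness_profile",
    "generate_biaxial_data",
    "CIRC_STRAIN_RANGE",
    "RAD_STRAIN_RANGE",
]

# Physiological peak Green-strain ranges in the belly at peak diastole.
CIRC_STRAIN_RANGE = (0.31, 0.35)
RAD_STRAIN_RANGE = (0.23, 0.59)


@dataclass
class SurrogateConfig:
    """Belly-patch geometry and diastolic loading template."""

    size: tuple[float, float] = (2.0, 2.0)        # in-plane extent (mm)
    thickness: float = 0.4289                     # belly thickness (mm)
    grid: tuple[int, int, int] = (5, 5, 3)
    layer_fractions: tuple[float, float, float] = (0.41, 0.30, 0.29)  # fibrosa-first
    eps_circ_peak: float = 0.33                   # peak Green strains
    eps_rad_peak: float = 0.41
    systole_frac: float = 0.35                    # fraction of the cycle before loading
    peak_frac: float = 0.45                       # time of peak diastole
    plateau_level: float = 0.97                   # end-of-cycle load relative to peak
    n_samples: int = 30                           # frames per cardiac cycle
    bending_gradient: float = 0.0                 # through-thickness strain modulation
    seed: int = 0
    allow_out_of_range: bool = False

    def __post_init__(self):
        if not self.allow_out_of_range:
            if not (CIRC_STRAIN_RANGE[0] <= self.eps_circ_peak <= CIRC_STRAIN_RANGE[1]):
                raise ValueError(
                    f"eps_circ_peak {self.eps_circ_peak} outside {CIRC_STRAIN_RANGE}; "
                    "set allow_out_of_range=True to override")
            if not (RAD_STRAIN_RANGE[0] <= self.eps_rad_peak <= RAD_STRAIN_RANGE[1]):
                raise ValueError(
                    f"eps_rad_peak {self.eps_rad_peak} outside {RAD_STRAIN_RANGE}; "
                    "set allow_out_of_range=True to override")
        if not (0.0 < self.systole_frac < self.peak_frac < 1.0):
            raise ValueError("need 0 < systole_frac < peak_frac < 1")


@dataclass
class OrganPatch:
    """Generated organ-scale kinematics."""

    mesh: HexMesh
    times: np.ndarray             # (T,) normalized cardiac-phase units
    U: np.ndarray                 # (T, N, 3) nodal displacements
    markers: dict[str, int]
    config: SurrogateConfig
    load_curve: np.ndarray        # (T,) normalized loading g(t)

    @property
    def peak_green_strains(self) -> tuple[float, float]:
        return (self.config.eps_circ_peak, self.config.eps_rad_peak)


def _load_curve(times: np.ndarray, cfg: SurrogateConfig) -> np.ndarray:
    """Normalized transvalvular loading: zero in systole, smooth rise to 1 at
    peak diastole, then a gentle decay to the plateau level."""
    g = np.zeros_like(times)
    rise = (times > cfg.systole_frac) & (times <= cfg.peak_frac)
    s = (times[rise] - cfg.systole_frac) / (cfg.peak_frac - cfg.systole_frac)
    g[rise] = 3 * s**2 - 2 * s**3
    after = times > cfg.peak_frac
    s2 = (times[after] - cfg.peak_frac) / max(1.0 - cfg.peak_frac, 1e-12)
    g[after] = 1.0 - (1.0 - cfg.plateau_level) * s2
    return g


def generate_organ_patch(config: SurrogateConfig | None = None) -> OrganPatch:
    """Build the belly patch mesh and its prescribed displacement history.

    The field is affine in space, u(x, t) = (Lambda(t) - I) x with
    Lambda = diag(lambda_c, lambda_r, 1/(lambda_c lambda_r)); peak Green
    strains therefore equal the configured targets exactly.  The optional
    bending gradient modulates the in-plane strain linearly through the
    thickness (top surface stretched more), breaking exact isochoricity.
    """
    cfg = config or SurrogateConfig()
    nx, ny, nz = cfg.grid
    if nz != len(cfg.layer_fractions):
        raise ValueError("grid nz must equal the number of geometric layers")
    xs = np.linspace(0.0, cfg.size[0], nx + 1)
    ys = np.linspace(0.0, cfg.size[1], ny + 1)
    frac_bottom = np.array(cfg.layer_fractions[::-1], dtype=float)  # ventricularis up
    zs = cfg.thickness * np.concatenate([[0.0], np.cumsum(frac_bottom)])
    mesh = HexMesh.from_grid(xs, ys, zs, units="mm")

    times = np.linspace(0.0, 1.0, cfg.n_samples)
    # snap the waveform's peak onto the sample grid so the configured peak
    # strain is attained exactly at a stored frame
    ip = int(round(cfg.peak_frac * (cfg.n_samples - 1)))
    cfg = dataclasses.replace(cfg, peak_frac=float(times[ip]),
                              allow_out_of_range=True)
    g = _load_curve(times, cfg)

    eps_c = cfg.eps_circ_peak * g
    eps_r = cfg.eps_rad_peak * g
    lam_c = np.sqrt(2 * eps_c + 1.0)
    lam_r = np.sqrt(2 * eps_r + 1.0)
    X = mesh.points
    zc = (X[:, 2] / cfg.thickness) - 0.5
    mod = 1.0 + cfg.bending_gradient * zc                      # (N,)
    U = np.empty((cfg.n_samples, mesh.n_nodes, 3))
    for t in range(cfg.n_samples):
        lc = 1.0 + (lam_c[t] - 1.0) * mod
        lr = 1.0 + (lam_r[t] - 1.0) * mod
        ln = 1.0 / (lam_c[t] * lam_r[t])
        U[t, :, 0] = (lc - 1.0) * X[:, 0]
        U[t, :, 1] = (lr - 1.0) * X[:, 1]
        U[t, :, 2] = (ln - 1.0) * X[:, 2]

    above = np.flatnonzero(g >= 0.5)
    start_dia = int(above[0]) if above.size else cfg.n_samples - 1
    markers = {"start_of_diastole": start_dia, "peak_diastole": ip}
    return OrganPatch(mesh=mesh, times=times, U=U, markers=markers,
                      config=cfg, load_curve=g)


@dataclass
class LeafletThicknessProfile:
    """Smooth belly-to-edge thickness map over a normalized radial coordinate.

    r = 0 is the attachment edge, r = 1 the free margin, r = 0.5 the belly;
    thickness is minimal (belly value) at the centre and rises monotonically
    to the edge value at both ends.
    """

    belly: float = 0.4289          # mm
    edge: float = 1.2              # mm
    power: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.belly <= self.edge):
            raise ValueError("need 0 < belly <= edge thickness")
        if self.power <= 0:
            raise ValueError("power must be positive")

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        s = np.abs(r - 0.5) / 0.5
        return self.belly + (self.edge - self.belly) * s**self.power

    @property
    def min_thickness(self) -> float:
        return self.belly

    @property
    def max_thickness(self) -> float:
        return self.edge


def generate_thickness_profile(belly: float = 0.4289, edge: float = 1.2,
                               shape: float = 2.0) -> LeafletThicknessProfile:
    """Region-dependent leaflet thickness profile (constant when belly == edge)."""
    return LeafletThicknessProfile(belly=belly, edge=edge, power=shape)


def generate_biaxial_data(params: FungParams,
                          protocol: "_biaxial.StretchProtocol | None" = None,
                          noise: float = 0.0, seed: int = 0,
                          q_form: str = "squared") -> "_biaxial.BiaxialDataset":
    """Synthetic biaxial test curves with multiplicative Gaussian noise.

    ``noise`` is the relative stress noise level (e.g. 0.01 for 1 %); the
    RNG seed is recorded in the dataset metadata.
    """
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    data = _biaxial.simulate_biaxial(params, protocol, q_form=q_form)
    if noise > 0:
        rng = np.random.default_rng(seed)
        for col in ("stress_c_MPa", "stress_r_MPa"):
            fac = 1.0 + noise * rng.standard_normal(len(data.df))
            data.df[col] = data.df[col].to_numpy() * fac
    data.metadata["noise"] = noise
    data.metadata["seed"] = seed
    return data
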