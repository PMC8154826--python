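"""Postprocessing: strain measures, peak extraction, layer stress tables,
cellular aspect ratios, and linear regressions.

Strains default to Green-Lagrange components in the circumferential/radial/
normal frame; stretch ratios lambda = sqrt(2E + 1) are emitted alongside,
since both appear in valve-mechanics reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fehex import SolveResult
from .mesh import HexMesh
from .scales import CellSpec

__all__ = [
    "RegressionResult",
    "CellMetrics",
    "strain_measures",
    "peak_diastolic",
    "compute_car",
    "linreg",
    "layer_stress_report",
]

_I3 = np.eye(3)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self):
        if not (np.isnan(self.r_squared) or -1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("R^2 outside [0, 1]")


@dataclass
class CellMetrics:
    """Deformed VIC axis lengths and aspect-ratio time courses.

    Normal CAR = deformed circumferential axis / deformed normal axis;
    Radial CAR = deformed circumferential axis / deformed radial axis.
    At the reference state both equal the reference axis ratio
    (10 / 7.7 ~ 1.30 for the default VIC).
    """

    times: np.ndarray
    phases: list[str]
    axis_circ: np.ndarray
    axis_rad: np.ndarray
    axis_norm: np.ndarray
    markers: dict[str, int] = field(default_factory=dict)

    @property
    def normal_car(self) -> np.ndarray:
        return self.axis_circ / self.axis_norm

    @property
    def radial_car(self) -> np.ndarray:
        return self.axis_circ / self.axis_rad

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "phase": self.phases,
            "axis_circ": self.axis_circ, "axis_rad": self.axis_rad,
            "axis_norm": self.axis_norm,
            "normal_CAR": self.normal_car, "radial_CAR": self.radial_car,
        })


def strain_measures(result: SolveResult, frame: np.ndarray | None = None
                    ) -> pd.DataFrame:
    """Volume-averaged Green strains and stretch ratios per time step.

    ``frame`` rows are the (circ, rad, normal) directions; defaults to the
    global axes.  Averages are Gauss-weighted over the whole mesh.
    """
    if result.F is None:
        raise ValueError("SolveResult carries no deformation fields")
    R = _I3 if frame is None else np.asarray(frame, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("frame must be a 3x3 matrix with rows circ, rad, normal")
    F = result.F                                          # (T, E, G, 3, 3)
    E = 0.5 * (np.einsum("tegki,tegkj->tegij", F, F) - _I3)
    Ef = np.einsum("ai,tegij,bj->tegab", R, E, R)
    w = result.detJw
    wsum = w.sum()
    out = {"time": result.times, "phase": result.phases}
    for name, idx in (("circ", 0), ("rad", 1)):
        comp = Ef[..., idx, idx]
        out[f"E_{name}"] = np.einsum("eg,teg->t", w, comp) / wsum
        out[f"stretch_{name}"] = np.einsum("eg,teg->t", w,
                                           np.sqrt(2 * comp + 1.0)) / wsum
    return pd.DataFrame(out)


def peak_diastolic(series, markers) -> tuple[float, int]:
    """Maximum of a time series over the diastolic window.

    ``markers`` is a dict with ``start_of_diastole`` (or an int index).
    Returns (peak value, absolute time index).
    """
    y = np.asarray(series, dtype=float)
    start = markers["start_of_diastole"] if isinstance(markers, dict) else int(markers)
    if start >= len(y) or start < 0:
        raise ValueError("empty diastolic window (series ends before diastole)")
    w = y[start:]
    i = int(np.argmax(w))
    return float(w[i]), start + i


def compute_car(result: SolveResult, spec: CellSpec | None = None,
                mesh: HexMesh | None = None) -> CellMetrics:
    """Cellular aspect ratio time courses from a cell-stage solution.

    The deformed half-axis along each direction is tracked at the outermost
    VIC-material node lying on that symmetry axis (the corner is the
    ellipsoid centre), so under a homogeneous deformation the measured CAR
    equals the closed-form ratio of stretched reference axes.
    """
    spec = spec or CellSpec()
    mesh = mesh or result.mesh
    if "vic" not in mesh.material_names:
        raise ValueError("mesh has no VIC material")
    vic_elems = mesh.material_of("vic")
    if vic_elems.size == 0:
        raise ValueError("VIC region is empty")
    vic_nodes = np.unique(mesh.cells[vic_elems])
    X = mesh.points[vic_nodes]
    tol = 1e-6 * float(np.max(mesh.bbox()[1]))
    lengths = []
    for ax in range(3):
        other = [a for a in range(3) if a != ax]
        on_axis = (np.abs(X[:, other[0]]) <= tol) & (np.abs(X[:, other[1]]) <= tol)
        if not on_axis.any():
            raise ValueError("no VIC nodes on a symmetry axis; refine the grid")
        cand = vic_nodes[on_axis]
        n_out = cand[np.argmax(mesh.points[cand, ax])]
        L_ref = mesh.points[n_out, ax]
        lengths.append(L_ref + result.u[:, n_out, ax])
    return CellMetrics(times=result.times, phases=list(result.phases),
                       axis_circ=lengths[0], axis_rad=lengths[1],
                       axis_norm=lengths[2], markers=dict(result.markers))


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares y = a x + b with R^2 and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if len(x) >= 3 else float("nan")
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2, p_value=p, n=len(x))


def layer_stress_report(result: SolveResult, mesh: HexMesh | None = None
                        ) -> pd.DataFrame:
    """Per-layer volume-weighted max principal Cauchy stress per time step."""
    mesh = mesh or result.mesh
    if result.cauchy is None:
        raise ValueError("SolveResult carries no stress fields")
    names = mesh.material_names or {"all": 0}
    sig_max = np.linalg.eigvalsh(result.cauchy)[..., -1]   # (T, E, G)
    rows = {"time": result.times, "phase": result.phases}
    for name, mid in sorted(names.items(), key=lambda kv: kv[1]):
        elems = np.flatnonzero(mesh.material == mid)
        if elems.size == 0:
            continue
        w = result.detJw[elems]
        rows[f"max_principal_{name}_MPa"] = (
            np.einsum("eg,teg->t", w, sig_max[:, elems]) / w.sum())
    return pd.DataFrame(rows)
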