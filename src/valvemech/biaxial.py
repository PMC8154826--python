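"""Virtual planar-biaxial testing and constitutive parameter identification.

A homogeneous material point is loaded along prescribed in-plane stretch
paths (circumferential x radial); the thickness stretch is found from the
traction-free condition sigma_nn = 0.  Nonlinear least squares over
(log C, b1, b2, b3) with K held fixed then recovers Fung parameters from
stress-stretch data — the virtual counterpart of fitting layer-wise biaxial
test curves.  Stresses are generated and fitted as second Piola-Kirchhoff
components conjugate to Green strain.
"""

from __future__ import annotations



from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .materials import FungMaterial, FungParams

__all__ = [
    "StretchProtocol",
    "BiaxialDataset",
    "FitReport",
    "simulate_biaxial",
    "fit_params",
    "residual_table",
    "thickness_stretch",
    "stretches_from_stress",
    "BiaxialSolveError",
]


class BiaxialSolveError(RuntimeError):
    pass


@dataclass
class StretchProtocol:
    """Named in-plane stretch paths; each path starts at (1, 1)."""

    paths: list[tuple[str, np.ndarray, np.ndarray]]

    def __post_init__(self):
        clean = []
        for label, lc, lr in self.paths:
            lc = np.asarray(lc, dtype=float)
            lr = np.asarray(lr, dtype=float)
            if lc.shape != lr.shape or lc.ndim != 1:
                raise ValueError(f"path {label!r}: stretch arrays must match")
            if np.any(lc <= 0) or np.any(lr <= 0):
                raise ValueError(f"path {label!r}: stretches must be positive")
            if not (np.isclose(lc[0], 1.0) and np.isclose(lr[0], 1.0)):
                raise ValueError(f"path {label!r} must start at (1, 1)")
            if np.any(np.diff(lc) < -1e-12) or np.any(np.diff(lr) < -1e-12):
                raise ValueError(f"path {label!r} must be monotone non-decreasing")
            clean.append((label, lc, lr))
        self.paths = clean

    @classmethod
    def default(cls, peak_green: float = 0.2, n: int = 30,
                ratios=((1.0, 1.0), (0.75, 1.0), (1.0, 0.75))) -> "StretchProtocol":
        """Three Green-strain-proportional paths (1:1, 0.75:1, 1:0.75)."""
        s = np.linspace(0.0, 1.0, n)
        paths = []
        for rc, rr in ratios:
            lc = np.sqrt(2 * rc * peak_green * s + 1.0)
            lr = np.sqrt(2 * rr * peak_green * s + 1.0)
            paths.append((f"{rc:g}:{rr:g}", lc, lr))
        return cls(paths)


@dataclass
class BiaxialDataset:
    """Per-path stress-stretch samples with declared measures."""

    df: pd.DataFrame          # columns: path_id, lambda_c, lambda_r, stress_c_MPa, stress_r_MPa
    stress_measure: str = "PK2"
    strain_measure: str = "stretch"
    metadata: dict = field(default_factory=dict)

    COLUMNS = ("path_id", "lambda_c", "lambda_r", "stress_c_MPa", "stress_r_MPa")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        vals = self.df[list(self.COLUMNS[1:])].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("dataset contains non-finite values")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def path_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["path_id"]))

    def to_csv(self, path_or_buf=None):
        return self.df.to_csv(path_or_buf, index=False, columns=list(self.COLUMNS))

    @classmethod
    def from_csv(cls, path_or_buf, **kw) -> "BiaxialDataset":
        df = pd.read_csv(path_or_buf)
        return cls(df=df, **kw)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _diag_F(lc, lr, ln):
    F = np.zeros(np.broadcast(lc, lr, ln).shape + (3, 3))
    F[..., 0, 0], F[..., 1, 1], F[..., 2, 2] = lc, lr, ln
    return F


def thickness_stretch(material: FungMaterial, lc, lr, tol: float = 1e-9,
                      max_iter: int = 60) -> np.ndarray:
    """Thickness stretch with traction-free normal: solve sigma_nn = 0.

    For a frame-aligned diagonal state sigma_nn = lambda_n^2 S_nn / J, so the
    root of S_nn is found by a vectorised, safeguarded Newton iteration
    starting from the incompressible guess 1/(lc*lr).
    """
    lc = np.atleast_1d(np.asarray(lc, dtype=float))
    lr = np.atleast_1d(np.asarray(lr, dtype=float))
    ln = 1.0 / (lc * lr)

    def snn(lnv):
        S = material.pk2(_diag_F(lc, lr, lnv))
        return S[..., 2, 2]

    def signn(lnv):
        return lnv * snn(lnv) / (lc * lr)   # lambda_n^2 S_nn / J

    for _ in range(max_iter):
        s = signn(ln)
        if np.abs(s).max() <= tol:
            return ln
        h = 1e-7 * np.maximum(ln, 1e-3)
        ds = (signn(ln + h) - signn(ln - h)) / (2 * h)
        step = np.where(np.abs(ds) > 0, -s / np.where(ds == 0, 1.0, ds), 0.0)
        step = np.clip(step, -0.2 * ln, 0.2 * ln)   # safeguard
        ln = np.maximum(ln + step, 1e-6)
    bad = int(np.argmax(np.abs(signn(ln))))
    raise BiaxialSolveError(
        f"thickness-stretch iteration failed at sample {bad} "
        f"(lambda_c={lc[bad]:g}, lambda_r={lr[bad]:g})")


def simulate_biaxial(params: FungParams, protocol: StretchProtocol | None = None,
                     q_form: str = "squared") -> BiaxialDataset:
    """PK2 in-plane stresses along each protocol path (deterministic)."""
    protocol = protocol or StretchProtocol.default()
    mat = FungMaterial(params, q_form=q_form)
    rows = []
    for label, lc, lr in protocol.paths:
        ln = thickness_stretch(mat, lc, lr)
        S = mat.pk2(_diag_F(lc, lr, ln))
        rows.append(pd.DataFrame({
            "path_id": label, "lambda_c": lc, "lambda_r": lr,
            "stress_c_MPa": S[..., 0, 0], "stress_r_MPa": S[..., 1, 1],
        }))
    df = pd.concat(rows, ignore_index=True)
    meta = {"params": {"C": params.C, "b1": params.b1, "b2": params.b2,
                       "b3": params.b3, "K": params.K,
                       "frame": params.frame.tolist()},
            "q_form": q_form}
    return BiaxialDataset(df=df, metadata=meta)


def stretches_from_stress(material, sigma_c: float, sigma_r: float,
                          tol: float = 1e-9, max_iter: int = 300) -> np.ndarray:
    """Stretches (lc, lr, ln) of a frame-aligned material point under target
    in-plane Cauchy stresses with a traction-free thickness direction.

    Damped Newton in (lc, lr) with the thickness stretch eliminated through
    :func:`thickness_stretch`; per-iteration stretch increments are capped,
    which walks reliably through the exponential toe region where the
    tangent is orders of magnitude below the target stress.
    """

    def sig_inplane(lam2):
        ln = thickness_stretch(material, lam2[0], lam2[1])[0]
        F = np.diag([lam2[0], lam2[1], ln])
        S = material.pk2(F)
        sig = F @ S @ F.T / np.linalg.det(F)
        return np.array([sig[0, 0], sig[1, 1]]), ln

    target = np.array([sigma_c, sigma_r])
    lam = np.array([1.0, 1.0])
    scale = max(1.0, float(np.abs(target).max()))
    ln = 1.0
    for _ in range(max_iter):
        s, ln = sig_inplane(lam)
        r = s - target
        if np.abs(r).max() <= tol * scale:
            return np.array([lam[0], lam[1], ln])
        J = np.empty((2, 2))
        for j in range(2):
            h = 1e-6 * lam[j]
            lp = lam.copy()
            lp[j] += h
            sp, _ = sig_inplane(lp)
            J[:, j] = (sp - s) / h
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            raise BiaxialSolveError("singular in-plane tangent") from None
        step = np.clip(step, -0.05, 0.05)
        lam = np.maximum(lam + step, 0.2)
    raise BiaxialSolveError(
        f"material-point solve did not reach ({sigma_c:g}, {sigma_r:g}) MPa")


# ---------------------------------------------------------------------------
# Parameter identification
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    success: bool
    residual_norm: float
    n_obs: int
    r_squared: dict[str, float]
    message: str = ""


def _predict(params: FungParams, lc, lr, q_form):
    mat = FungMaterial(params, q_form=q_form)
    ln = thickness_stretch(mat, lc, lr)
    S = mat.pk2(_diag_F(lc, lr, ln))
    return S[..., 0, 0], S[..., 1, 1]


def fit_params(data: BiaxialDataset, init: FungParams,
               fixed: dict | None = None, q_form: str = "squared"
               ) -> tuple[FungParams, FitReport]:
    """Identify (C, b1, b2, b3) from biaxial data by nonlinear least squares.

    C is fitted on a log scale (its magnitude spans three decades across the
    leaflet layers); K is held fixed (default: the value carried by ``init``).
    Both stress components of all paths are stacked into one residual.
    """
    if len(data) < 2:
        raise ValueError("need at least two samples to fit")
    K = float((fixed or {}).get("K", init.K))
    lc = data.df["lambda_c"].to_numpy(dtype=float)
    lr = data.df["lambda_r"].to_numpy(dtype=float)
    obs = np.concatenate([data.df["stress_c_MPa"].to_numpy(dtype=float),
                          data.df["stress_r_MPa"].to_numpy(dtype=float)])

    def unpack(x):
        return FungParams(C=float(np.exp(x[0])), b1=float(x[1]), b2=float(x[2]),
                          b3=float(x[3]), K=K, frame=init.frame)

    def residuals(x):
        try:
            sc, sr = _predict(unpack(x), lc, lr, q_form)
        except BiaxialSolveError:
            return np.full(2 * len(lc), 1e6)
        return np.concatenate([sc, sr]) - obs

    x0 = np.array([np.log(init.C), init.b1, init.b2, init.b3])
    sol = least_squares(residuals, x0, method="lm",
                        xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=2000)
    fitted = unpack(sol.x)

    r2 = {}
    sc, sr = _predict(fitted, lc, lr, q_form)
    for pid in data.path_ids:
        m = (data.df["path_id"] == pid).to_numpy()
        o = np.concatenate([data.df.loc[m, "stress_c_MPa"], data.df.loc[m, "stress_r_MPa"]])
        p = np.concatenate([sc[m], sr[m]])
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        ss_res = float(np.sum((o - p) ** 2))
        r2[pid] = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    report = FitReport(success=bool(sol.success), residual_norm=float(np.linalg.norm(sol.fun)),
                       n_obs=2 * len(lc), r_squared=r2, message=sol.message)
    return fitted, report


def residual_table(data: BiaxialDataset, params: FungParams,
                   q_form: str = "squared") -> pd.DataFrame:
    """Observed vs. predicted stresses per sample (for tables and figures)."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    lc = data.df["lambda_c"].to_numpy(dtype=float)
    lr = data.df["lambda_r"].to_numpy(dtype=float)
    sc, sr = _predict(params, lc, lr, q_form)
    out = data.df.copy()
    out["pred_stress_c_MPa"] = sc
    out["pred_stress_r_MPa"] = sr
    out["resid_c_MPa"] = out["stress_c_MPa"] - sc
    out["resid_r_MPa"] = out["stress_r_MPa"] - sr
    return out


def plot_fit(data: BiaxialDataset, params: FungParams, path=None,
             q_form: str = "squared"):
    """Predicted-vs-observed stress-stretch curves, one panel per path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = residual_table(data, params, q_form=q_form)
    pids = data.path_ids
    fig, axes = plt.subplots(1, len(pids), figsize=(4 * len(pids), 3.2), squeeze=False)
    for ax, pid in zip(axes[0], pids):
        sub = table[table["path_id"] == pid]
        for comp, lam in (("c", "lambda_c"), ("r", "lambda_r")):
            ax.plot(sub[lam], sub[f"stress_{comp}_MPa"], "o", ms=3,
                    label=f"data {comp}")
            ax.plot(sub[lam], sub[f"pred_stress_{comp}_MPa"], "-",
                    label=f"fit {comp}")
        ax.set_title(f"path {pid}")
        ax.set_xlabel("stretch")
        ax.set_ylabel("PK2 stress (MPa)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
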