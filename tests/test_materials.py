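"""Constitutive model tests: energies, stresses, tangents, stability."""

import numpy as np
import pytest
from scipy.linalg import sqrtm

from valvemech import materials as vm
from valvemech.materials import (DeformationState, FungMaterial, FungParams,
                                 InvalidDeformationError, IsoElasticParams,
                                 NeoHookeanMaterial, SVKMaterial, cauchy_stress,
                                 get_preset, iso_stress, pk2_stress,
                                 stability_check, strain_energy)

FUNG_NAMES = ["intact_leaflet", "fibrosa", "ventricularis"]

# fitted leaflet constants: C, b1, b2, b3, K
TABLE = {
    "intact_leaflet": (2.82e-3, 0.01, 2.84, 1.97, 50.0),
    "fibrosa": (3.48e-6, 5.49, 81.48, -0.08, 50.0),
    "ventricularis": (5.09e-6, 4.86, 5.02, -1.63e-3, 50.0),
}


def _rand_states(rng, n, scale=0.06):
    """Random symmetric Green strains (with positive 2E+I) and matching F."""
    A = rng.normal(scale=scale, size=(n, 3, 3))
    E = 0.5 * (A + np.swapaxes(A, 1, 2))
    F = np.array([np.real(sqrtm(2 * e + np.eye(3))) for e in E])
    keep = np.linalg.det(F) > 0.3
    return E[keep], F[keep]


def test_preset_catalog_constants(presets):
    for name, (C, b1, b2, b3, K) in TABLE.items():
        p = presets[name]
        assert (p.C, p.b1, p.b2, p.b3, p.K) == (C, b1, b2, b3, K)
    assert (presets["spongiosa"].E_mod, presets["spongiosa"].nu) == (0.02, 0.49)
    assert (presets["vic"].E_mod, presets["vic"].nu) == (9e-4, 0.45)
    assert (presets["aortic_wall"].E_mod, presets["aortic_wall"].nu) == (2.0, 0.3)


@pytest.mark.parametrize("name", FUNG_NAMES)
@pytest.mark.parametrize("q_form", ["squared", "as_printed"])
def test_energy_vanishes_at_identity(name, q_form):
    p = get_preset(name)
    assert strain_energy(p, DeformationState(np.eye(3)), q_form=q_form) == 0.0


def test_energy_matches_scalar_hand_calculation():
    """Equibiaxial isochoric state evaluated with plain floats."""
    p = get_preset("intact_leaflet")
    F = np.diag([1.1, 1.1, 1 / 1.21])
    Eff = Ess = (1.1**2 - 1) / 2
    Enn = ((1 / 1.21) ** 2 - 1) / 2
    for q_form, fiber in (("squared", p.b2 * Eff**2), ("as_printed", p.b2 * Eff)):
        Q = 2 * p.b1 * (Eff + Ess + Enn) + fiber + p.b3 * (Ess**2 + Enn**2)
        expected = p.C / 2 * (np.exp(Q) - 1)   # J = 1: no volumetric part
        got = strain_energy(p, DeformationState(F), q_form=q_form)
        assert got == pytest.approx(expected, rel=1e-12)


def test_energy_volumetric_closed_form():
    p = FungParams(C=1e-30, b1=0.0, b2=1.0, b3=1.0, K=50.0)
    J = 1.05
    F = np.diag([1.0, 1.0, J])
    expected = p.K * ((J**2 - 1) / 2 - np.log(J))
    assert strain_energy(p, DeformationState(F)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("name", FUNG_NAMES)
@pytest.mark.parametrize("q_form", ["squared", "as_printed"])
def test_pk2_matches_fd_gradient_of_energy(name, q_form):
    """Analytic PK2 vs central differences of U in E, 100+ random states."""
    mat = FungMaterial(get_preset(name), q_form=q_form)
    rng = np.random.default_rng(101)
    E, F = _rand_states(rng, 120)
    assert len(E) >= 100
    S = mat.pk2(F)
    h = 1e-7
    worst = 0.0
    for i in range(3):
        for j in range(3):
            dE = np.zeros((3, 3))
            dE[i, j] += h / 2
            dE[j, i] += h / 2
            Fp = np.array([np.real(sqrtm(2 * (e + dE) + np.eye(3))) for e in E])
            Fm = np.array([np.real(sqrtm(2 * (e - dE) + np.eye(3))) for e in E])
            S_fd = (mat.energy(Fp) - mat.energy(Fm)) / (2 * h)
            scale = np.abs(S).max(axis=(1, 2)) + 1e-12
            worst = max(worst, float(np.max(np.abs(S[:, i, j] - S_fd) / scale)))
    assert worst <= 1e-6


def test_pk2_zero_without_trace_term():
    p = FungParams(C=1e-3, b1=0.0, b2=2.0, b3=1.0, K=50.0)
    S = pk2_stress(p, DeformationState(np.eye(3)))
    assert np.abs(S).max() == 0.0


def test_small_strain_fiber_tangent_limit():
    """d(S_ff)/dE_ff at the reference state equals the symbolic linearisation."""
    p = get_preset("intact_leaflet")
    expected = p.C / 2 * (4 * p.b1**2 + 2 * p.b2) + 2 * p.K
    eps = 1e-7
    lam = np.sqrt(2 * eps + 1)
    S1 = pk2_stress(p, DeformationState(np.diag([lam, 1.0, 1.0])))
    S0 = pk2_stress(p, DeformationState(np.eye(3)))
    slope = (S1[0, 0] - S0[0, 0]) / eps
    assert slope == pytest.approx(expected, rel=1e-5)


def test_objectivity_under_rotation():
    rng = np.random.default_rng(7)
    p = get_preset("fibrosa")
    _, F = _rand_states(rng, 10)
    from scipy.stats import special_ortho_group
    for f in F:
        R = special_ortho_group.rvs(3, random_state=rng)
        u1 = strain_energy(p, DeformationState(f))
        u2 = strain_energy(p, DeformationState(R @ f))
        assert abs(u1 - u2) <= 1e-10 * max(1.0, abs(u1))
        s1 = cauchy_stress(p, DeformationState(f))
        s2 = cauchy_stress(p, DeformationState(R @ f))
        assert np.abs(s2 - R @ s1 @ R.T).max() <= 1e-10 * max(1.0, np.abs(s1).max())


def test_cauchy_pushforward_identity_for_diagonal_stretch():
    p = get_preset("intact_leaflet")
    F = np.diag([1.2, 1.05, 0.9])
    S = pk2_stress(p, DeformationState(F))
    sig = cauchy_stress(p, DeformationState(F))
    J = np.linalg.det(F)
    assert sig[0, 0] == pytest.approx(1.2**2 / J * S[0, 0], rel=1e-12)
    assert np.abs(sig - sig.T).max() <= 1e-12 * np.abs(sig).max()


def test_iso_stress_closed_forms():
    p = IsoElasticParams(E_mod=0.02, nu=0.49)
    lam, mu = p.lame
    assert np.abs(iso_stress(p, DeformationState(np.eye(3)))).max() == 0.0
    # pure volumetric Green strain: tr(S) = 3 eps (3 lam + 2 mu)
    eps = 0.01
    F = np.eye(3) * np.sqrt(2 * eps + 1)
    S = iso_stress(p, DeformationState(F))
    assert np.trace(S) == pytest.approx(3 * eps * (3 * lam + 2 * mu), rel=1e-12)
    # nu = 0: uniaxial Green strain decouples
    p0 = IsoElasticParams(E_mod=1.5, nu=0.0)
    F = np.diag([np.sqrt(2 * eps + 1), 1.0, 1.0])
    S = iso_stress(p0, DeformationState(F))
    assert S[0, 0] == pytest.approx(1.5 * eps, rel=1e-12)
    assert S[1, 1] == S[2, 2] == 0.0


@pytest.mark.parametrize("cls", [SVKMaterial, NeoHookeanMaterial])
def test_isotropic_tangent_matches_fd(cls):
    mat = cls(IsoElasticParams(E_mod=0.02, nu=0.49))
    rng = np.random.default_rng(3)
    F = np.eye(3) + rng.normal(scale=0.05, size=(3, 3))
    S0, D = mat.pk2_and_tangent(F)
    dF = rng.normal(size=(3, 3))
    h = 1e-6
    S_fd = (mat.pk2(F + h * dF) - mat.pk2(F - h * dF)) / (2 * h)
    dE = 0.5 * ((F.T @ dF) + (dF.T @ F))
    S_an = np.einsum("ijkl,kl->ij", D, dE)
    assert np.abs(S_an - S_fd).max() <= 1e-5 * np.abs(S_fd).max()


def test_neo_hookean_small_strain_consistent_with_svk():
    p = IsoElasticParams(E_mod=0.02, nu=0.45)
    nh, svk = NeoHookeanMaterial(p), SVKMaterial(p)
    eps = 1e-5
    F = np.eye(3) + eps * np.array([[0.3, 0.1, 0.0], [0.1, -0.2, 0.0], [0.0, 0.0, 0.1]])
    # agreement to first order in strain: difference is O(eps^2)
    assert np.abs(nh.pk2(F) - svk.pk2(F)).max() <= 10 * eps * np.abs(svk.pk2(F)).max()


def test_stability_scan_flags_constructed_instability():
    assert stability_check(get_preset("intact_leaflet"), (0.0, 0.2)) == []
    bad = FungParams(C=1.0, b1=0.0, b2=0.5, b3=-5.0, K=1e-3)
    assert len(stability_check(bad, (0.0, 0.4))) > 0
    assert stability_check(get_preset("fibrosa"), (0.0, 0.2), n=0) == []


def test_invalid_inputs_raise():
    with pytest.raises(InvalidDeformationError):
        DeformationState(np.diag([1.0, 1.0, -0.5]))
    with pytest.raises(InvalidDeformationError):
        DeformationState(np.full((3, 3), np.nan))
    with pytest.raises(ValueError):
        FungParams(C=-1.0, b1=0, b2=1, b3=1, K=50)
    with pytest.raises(ValueError):
        FungParams(C=1.0, b1=0, b2=1, b3=1, K=50,
                   frame=np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1.0]]))
    with pytest.raises(ValueError):
        IsoElasticParams(E_mod=1.0, nu=0.5)
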