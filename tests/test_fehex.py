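"""FE solver tests: assembly, Newton continuation, boundary conditions."""

import numpy as np
import pytest

from valvemech import fehex as fe
from valvemech import materials as vm
from valvemech.materials import (FungMaterial, FungParams, get_preset,
                                 material_from_preset)
from valvemech.mesh import HexMesh

INTACT = FungMaterial(get_preset("intact_leaflet"))


def _affine_history(mesh, A, nodes=None, n_steps=2):
    """Dirichlet history driving ``nodes`` along u = t * A x."""
    nodes = np.arange(mesh.n_nodes) if nodes is None else nodes
    times = np.linspace(0.0, 1.0, n_steps)
    vals = np.stack([t * (mesh.points[nodes] @ A.T) for t in times])
    return fe.BoundaryHistory(times=times,
                              dirichlet=[fe.DirichletBC(nodes=nodes, values=vals)])


def test_zero_state_zero_residual():
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    mat = material_from_preset("spongiosa")      # stress-free reference
    fint, _ = fe.assemble(mesh, {0: mat}, np.zeros((8, 3)))
    assert np.abs(fint).max() == 0.0


def test_single_element_internal_forces_match_surface_tractions():
    """Homogeneous F: nodal forces equal the closed-form PK1 face integrals."""
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    F = np.array([[1.1, 0.05, 0.0], [0.0, 1.02, 0.0], [0.0, 0.0, 0.93]])
    u = mesh.points @ (F - np.eye(3)).T
    fint, _ = fe.assemble(mesh, {0: INTACT}, u)
    S = INTACT.pk2(F[None])[0]
    P = F @ S
    expected = np.zeros((8, 3))
    from valvemech.mesh import FACE_NODES
    normals = np.array([[-1, 0, 0], [1, 0, 0], [0, -1, 0],
                        [0, 1, 0], [0, 0, -1], [0, 0, 1.0]])
    for face, n in zip(FACE_NODES, normals):
        for a in face:                       # uniform traction: area/4 per node
            expected[mesh.cells[0, a]] += 0.25 * P @ n
    assert np.abs(fint.reshape(8, 3) - expected).max() <= 1e-12


def test_tangent_matches_fd_of_residual():
    mesh = HexMesh.from_grid([0, 1, 2], [0, 1], [0, 1])
    rng = np.random.default_rng(5)
    u = rng.normal(scale=0.02, size=(mesh.n_nodes, 3))
    prob = fe.StaticProblem(mesh, {0: INTACT})
    f0, K = prob.assemble(u)
    d = rng.normal(size=u.shape)
    h = 1e-6
    fp, _ = prob.assemble(u + h * d, want_tangent=False)
    fm, _ = prob.assemble(u - h * d, want_tangent=False)
    fd = (fp - fm) / (2 * h)
    assert np.abs(K @ d.ravel() - fd).max() <= 1e-5 * np.abs(fd).max()


def test_homogeneous_patch_test_affine_interior():
    """Affine Dirichlet on the boundary reproduces the affine field inside."""
    g = np.linspace(0, 1, 4)
    mesh = HexMesh.from_grid(g, g, g)
    A = np.array([[0.08, 0.02, 0.0], [0.01, 0.05, 0.0], [0.0, 0.0, -0.06]])
    bnodes = np.unique(mesh.face_node_ids(mesh.boundary_faces()))
    history = _affine_history(mesh, A, nodes=bnodes)
    cfg = fe.SolverConfig(rtol=1e-12, atol=1e-16)
    res = fe.solve_static(mesh, {0: INTACT}, history, cfg)
    assert np.abs(res.u[-1] - mesh.points @ A.T).max() <= 1e-8


def test_single_element_gauss_stress_equals_material_point():
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    lam = np.diag([1.15, 1.15, 1 / 1.15**2])
    history = _affine_history(mesh, lam - np.eye(3), n_steps=4)
    res = fe.solve_static(mesh, {0: INTACT}, history)
    S = INTACT.pk2(lam[None])[0]
    sig = lam @ S @ lam.T / np.linalg.det(lam)
    assert np.abs(res.cauchy[-1][0] - sig).max() <= 1e-8


def test_traction_free_zero_bc_stays_undeformed():
    mesh = HexMesh.from_grid([0, 1, 2], [0, 1], [0, 1])
    bnodes = np.unique(mesh.face_node_ids(mesh.boundary_faces()))
    history = fe.BoundaryHistory(times=[0.0, 1.0],
                                 dirichlet=[fe.DirichletBC(nodes=bnodes)])
    res = fe.solve_static(mesh, {0: INTACT}, history)
    assert np.abs(res.u[-1]).max() <= 1e-10


def test_layered_stack_fibrosa_dominates():
    """1x1x3 layered stack under in-plane stretch: fibrosa carries the load."""
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 0.29, 0.59, 1.0])
    mesh.material[:] = [0, 1, 2]   # ventricularis, spongiosa, fibrosa (bottom-up)
    mats = {0: material_from_preset("ventricularis"),
            1: material_from_preset("spongiosa"),
            2: material_from_preset("fibrosa")}
    lam = np.diag([1.25, 1.25, 1 / 1.25**2])
    history = _affine_history(mesh, lam - np.eye(3), n_steps=6)
    res = fe.solve_static(mesh, {0: mats[0], 1: mats[1], 2: mats[2]}, history)
    smax = np.linalg.eigvalsh(res.cauchy[-1])[..., -1].mean(axis=1)
    assert smax[2] > 10 * smax[1]      # fibrosa >> spongiosa
    assert smax[2] > 10 * smax[0]      # fibrosa >> ventricularis


def test_follower_traction_basics():
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    faces = mesh.face_sets["xmax"]
    assert np.abs(fe.follower_traction(mesh, faces, 0.0, None)).max() == 0.0
    f = fe.follower_traction(mesh, faces, 2.5, None).reshape(-1, 3)
    assert np.allclose(f.sum(axis=0), [2.5, 0.0, 0.0], atol=1e-12)
    # deformed face area doubles -> follower force doubles
    u = mesh.points * np.array([0.0, 1.0, 1.0])
    f2 = fe.follower_traction(mesh, faces, 2.5, u).reshape(-1, 3)
    assert np.allclose(f2.sum(axis=0), [10.0, 0.0, 0.0], atol=1e-12)


def test_degenerate_face_raises():
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    u = np.zeros((8, 3))
    fn = mesh.face_node_ids(mesh.face_sets["xmax"])[0]
    u[fn] = -mesh.points[fn] + mesh.points[fn].mean(axis=0)  # collapse to a point
    with pytest.raises(fe.GeometryError):
        fe.follower_traction(mesh, mesh.face_sets["xmax"], 1.0, u)


def test_displacement_traction_round_trip():
    """sigma from a displacement-driven solve, reapplied as follower
    tractions with tied faces, reproduces the displacements."""
    g = np.linspace(0, 1, 3)
    mesh = HexMesh.from_grid(g, g, g)
    lam = np.diag([1.12, 1.08, 1 / (1.12 * 1.08)])
    res_d = fe.solve_static(mesh, {0: INTACT},
                            _affine_history(mesh, lam - np.eye(3), n_steps=4))
    sig = res_d.cauchy[-1].mean(axis=(0, 1))
    sym = [fe.apply_symmetry(mesh, ax, 0.0) for ax in ("x", "y", "z")]
    ties = [fe.TieBC(np.unique(mesh.face_node_ids(mesh.face_sets["xmax"])), 0),
            fe.TieBC(np.unique(mesh.face_node_ids(mesh.face_sets["ymax"])), 1),
            fe.TieBC(np.unique(mesh.face_node_ids(mesh.face_sets["zmax"])), 2)]
    T = 5
    history = fe.BoundaryHistory(
        times=np.linspace(0, 1, T), dirichlet=sym, ties=ties,
        tractions=[
            fe.TractionBC(mesh.face_sets["xmax"], np.linspace(0, sig[0, 0], T)),
            fe.TractionBC(mesh.face_sets["ymax"], np.linspace(0, sig[1, 1], T)),
            fe.TractionBC(mesh.face_sets["zmax"], np.linspace(0, sig[2, 2], T)),
        ])
    res_t = fe.solve_static(mesh, {0: INTACT}, history)
    err = np.abs(res_t.u[-1] - res_d.u[-1]).max() / np.abs(res_d.u[-1]).max()
    assert err <= 1e-4


def test_apply_symmetry_nodes_and_errors():
    mesh = HexMesh.from_grid([0, 1, 2], [0, 1], [0, 1])
    bc = fe.apply_symmetry(mesh, "x", 0.0)
    assert set(bc.nodes) == set(mesh.node_sets["xmin"])
    assert bc.comps.tolist() == [True, False, False]
    with pytest.raises(fe.GeometryError):
        fe.apply_symmetry(mesh, "x", 0.5)
    with pytest.raises(fe.GeometryError):
        fe.apply_symmetry(mesh, "w", 0.0)


def test_external_work_matches_stored_energy():
    """Quasi-static loading: trapezoidal reaction work ~ strain energy (<1%)."""
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    lam = np.diag([1.2, 1.1, 1 / (1.2 * 1.1)])
    T = 41
    history = _affine_history(mesh, lam - np.eye(3), n_steps=T)
    res = fe.solve_static(mesh, {0: INTACT}, history)
    W = sum(0.5 * (res.fint[s] + res.fint[s - 1]) @ (res.u[s] - res.u[s - 1]).ravel()
            for s in range(1, T))
    U = fe.StaticProblem(mesh, {0: INTACT}).total_energy(res.u[-1])
    assert W == pytest.approx(U, rel=0.01)


def test_history_validation_errors():
    mesh = HexMesh.from_grid([0, 1], [0, 1], [0, 1])
    with pytest.raises(ValueError):
        fe.BoundaryHistory(times=[0.0, 0.0])
    h = fe.BoundaryHistory(times=[0.0, 1.0],
                           dirichlet=[fe.DirichletBC(nodes=[99])])
    with pytest.raises(ValueError):
        h.validate(mesh)
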