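"""Shared fixtures: material presets and one organ->tissue->cell chain.

The tissue- and cell-stage solves are session-scoped because several test
modules interrogate the same converged states (layer stresses, stress
concentration, aspect ratios)."""

import numpy as np
import pytest

from valvemech import analyze, biaxial, materials, scales, surrogate
from valvemech.fehex import SolverConfig
from valvemech.materials import material_from_preset


@pytest.fixture(scope="session")
def presets():
    return materials.load_presets()


@pytest.fixture(scope="session")
def organ_default():
    return surrogate.generate_organ_patch()


@pytest.fixture(scope="session")
def tissue_chain(organ_default):
    """Layered tissue stage on the unrefined 75-element belly patch."""
    org = organ_default
    patch, U_patch, _ = scales.extract_patch(org.mesh, org.U)
    refined, pmap = scales.refine_patch(patch, (1, 1, 1))
    layered = scales.assign_layers(refined)
    mats = {layered.material_names[n]: material_from_preset(n)
            for n in ("fibrosa", "spongiosa", "ventricularis")}
    history = scales.interpolate_boundary_displacements(
        U_patch, layered, pmap, org.times, org.markers)
    result = scales.run_tissue_stage(layered, mats, history, SolverConfig(),
                                     n_pre=6, stride=3, U_patch=U_patch, pmap=pmap)
    sigma = scales.extract_fibrosa_stress(result, layered)
    return {"organ": org, "patch": patch, "U_patch": U_patch, "pmap": pmap,
            "mesh": layered, "materials": mats, "result": result, "sigma": sigma}


@pytest.fixture(scope="session")
def cell_spec_reduced():
    return scales.CellSpec.reduced()


@pytest.fixture(scope="session")
def cell_chain(tissue_chain, cell_spec_reduced):
    """Cell stage (ECM + VIC) driven by the tissue fibrosa stress curves."""
    cell = scales.build_cell_patch(cell_spec_reduced)
    mats = {cell.material_names["ecm"]: material_from_preset("fibrosa"),
            cell.material_names["vic"]: material_from_preset("vic")}
    result = scales.run_cell_stage(cell, mats, tissue_chain["sigma"],
                                   SolverConfig(), n_pre=6)
    return {"mesh": cell, "materials": mats, "result": result,
            "sigma": tissue_chain["sigma"]}


def boundary_stretches(cell_mesh, result, step=-1):
    """Mean stretch of the two loaded faces (tied, so the mean is exact)."""
    lx = float(cell_mesh.points[:, 0].max())
    ly = float(cell_mesh.points[:, 1].max())
    lc = 1.0 + result.u[step, cell_mesh.node_sets["xmax"], 0].mean() / lx
    lr = 1.0 + result.u[step, cell_mesh.node_sets["ymax"], 1].mean() / ly
    return lc, lr
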