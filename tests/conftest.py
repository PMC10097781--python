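"""Shared fixtures: deliberately coarse meshes and one reusable cycle.

FE fixtures use resolutions far below the production minimum element
count (via ``enforce_min_elements=False``) to keep the suite fast; the
geometry-family and oracle tests use production-scale meshes where the
check demands it.
"""

import numpy as np
import pytest

from helixlv import (
    ActiveParams,
    HelixConfig,
    PassiveParams,
    SolverConfig,
    WaveformSpec,
    fetal_geometry_spec,
    generate_idealized_lv,
    generate_volume_waveform,
    run_volume_constrained_cycle,
)
from helixlv.fibers import make_fiber_field


@pytest.fixture(scope="session")
def tiny_mesh():
    spec = fetal_geometry_spec("symmetric")
    return generate_idealized_lv(
        spec, n_circ=8, n_long=4, n_trans=1, enforce_min_elements=False
    )


@pytest.fixture(scope="session")
def coarse_mesh():
    spec = fetal_geometry_spec("symmetric")
    return generate_idealized_lv(
        spec, n_circ=10, n_long=5, n_trans=2, enforce_min_elements=False
    )


@pytest.fixture(scope="session")
def tiny_fibers(tiny_mesh):
    field, frames, e_nodal = make_fiber_field(tiny_mesh, HelixConfig(10.0, 123.0))
    return field


@pytest.fixture(scope="session")
def fetal_waveform():
    return generate_volume_waveform(WaveformSpec())


@pytest.fixture(scope="session")
def solver_config():
    return SolverConfig(steps_per_cycle=20)


@pytest.fixture(scope="session")
def tiny_cycle(tiny_mesh, tiny_fibers, fetal_waveform, solver_config):
    """One active volume-constrained cycle, shared across metric tests."""
    return run_volume_constrained_cycle(
        tiny_mesh, tiny_fibers, PassiveParams(), ActiveParams(),
        fetal_waveform, solver_config,
    )


@pytest.fixture(scope="session")
def tiny_passive_cycle(tiny_mesh, tiny_fibers, fetal_waveform, solver_config):
    """The same cycle with zero active tension (pure elastic response)."""
    return run_volume_constrained_cycle(
        tiny_mesh, tiny_fibers, PassiveParams(), ActiveParams(T0_LV=0.0),
        fetal_waveform, solver_config,
    )


@pytest.fixture(scope="session")
def sphere_inflation_vs_oracle():
    """FE inflation of a ~1500-element hemispherical shell vs the 1D oracle.

    Isotropic parameter limit; effective inner/outer radii are derived from
    the discrete cavity and wall volumes so both routes describe the same
    sphere.  Returns (factor, p_fe_kpa, p_oracle_kpa) triples.
    """
    import numpy as np

    from helixlv.mechanics import LVSolver
    from oracles import isotropic_fung_sphere_pressure

    spec = fetal_geometry_spec("hemisphere")
    mesh = generate_idealized_lv(spec, n_circ=16, n_long=8, n_trans=2,
                                 enforce_min_elements=False)
    passive = PassiveParams().isotropic_limit(b=8.0)
    fibers, _, _ = make_fiber_field(mesh, HelixConfig(0.0, 0.0))
    solver = LVSolver(mesh, fibers, passive, None,
                      SolverConfig(steps_per_cycle=20, epicardial_spring=1e-4))
    V0 = solver.cavity_volume()
    a_eff = (3.0 * (2.0 * V0 * 1000.0) / (4.0 * np.pi)) ** (1.0 / 3.0)
    wall = mesh.wall_volume()
    b_eff = (a_eff**3 + 3.0 * (2.0 * wall * 1000.0) / (4.0 * np.pi)) ** (1 / 3)

    rows = []
    for factor in (1.15, 1.25, 1.4):
        solver.solve_to_volume(V0 * factor)
        p_1d = isotropic_fung_sphere_pressure(
            a_eff, b_eff, 2.0 * V0 * factor * 1000.0, passive.C, passive.b_xx
        )
        rows.append((factor, solver.p_cav, p_1d))
    return {"mesh_cells": mesh.n_cells, "rows": rows}


@pytest.fixture(scope="session")
def unloaded_roundtrip(coarse_mesh):
    """Backward-displacement unloaded state at EDP = 5 mmHg, shared."""
    from helixlv import compute_cavity_volume, find_unloaded_state

    edv = compute_cavity_volume(coarse_mesh)
    out = find_unloaded_state(
        coarse_mesh, 5.0, PassiveParams(), SolverConfig(steps_per_cycle=20),
        edv_ml=edv,
    )
    return {"result": out, "mesh": coarse_mesh, "edv": edv}
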