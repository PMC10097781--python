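"""FE solver verification: tangents, oracles, round trips, objectivity."""

import numpy as np
import pytest

from helixlv import (
    ActiveParams,
    HelixConfig,
    PassiveParams,
    SolverConfig,
    compute_cavity_volume,
    fetal_geometry_spec,
    generate_idealized_lv,
)
from helixlv.fibers import make_fiber_field
from helixlv.mechanics import KPA_TO_MMHG, MMHG_TO_KPA, LVSolver, NewtonError

from oracles import isotropic_fung_sphere_pressure


@pytest.fixture(scope="module")
def tiny_solver(tiny_mesh, tiny_fibers):
    return LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), ActiveParams(),
                    SolverConfig(steps_per_cycle=20))


class TestAssembly:
    def test_zero_state_equilibrium(self, tiny_solver):
        s = tiny_solver
        r, _, _ = s.assemble(np.zeros((s.mesh.n_points, 3)),
                             np.zeros(s.n_p), 0.0, with_matrix=False)
        assert np.abs(r).max() < 1e-10

    def test_tangent_matches_residual_derivative(self, tiny_solver):
        s = tiny_solver
        rng = np.random.default_rng(0)
        u = 0.01 * rng.standard_normal((s.mesh.n_points, 3))
        u[np.unique(s.mesh.facets["base"]), 2] = 0.0
        pm = 0.05 * rng.standard_normal(s.n_p)
        r, _, K = s.assemble(u, pm, 0.1, t_act=50.0)
        x0 = np.concatenate([u.ravel(), pm])
        h = 1e-6
        for i in rng.choice(len(x0), 10, replace=False):
            dx = np.zeros_like(x0)
            dx[i] = h
            rp, _, _ = s.assemble((x0 + dx)[: s.n_u].reshape(-1, 3),
                                  (x0 + dx)[s.n_u:], 0.1, t_act=50.0,
                                  with_matrix=False)
            rm, _, _ = s.assemble((x0 - dx)[: s.n_u].reshape(-1, 3),
                                  (x0 - dx)[s.n_u:], 0.1, t_act=50.0,
                                  with_matrix=False)
            fd = (rp - rm) / (2 * h)
            col = np.asarray(K[:, i].todense()).ravel()
            assert np.abs(fd - col).max() < 1e-4 * (np.abs(col).max() + 1.0)

    def test_cavity_gradient_and_hessian_consistent(self, tiny_solver):
        s = tiny_solver
        rng = np.random.default_rng(1)
        u = 0.02 * rng.standard_normal((s.mesh.n_points, 3))
        g = s.cavity_volume_gradient(u)
        H = s.cavity_volume_hessian(u)
        h = 1e-6
        endo_dofs = (3 * np.unique(s.mesh.facets["endo"])[:, None]
                     + np.arange(3)).ravel()
        for i in rng.choice(endo_dofs, 6, replace=False):
            du = np.zeros((s.mesh.n_points, 3))
            du.ravel()[i] = h
            fd_g = (s.cavity_volume(u + du) - s.cavity_volume(u - du)) / (2 * h)
            assert fd_g * 1000 == pytest.approx(g[i], abs=1e-6)
            fd_H = (s.cavity_volume_gradient(u + du)
                    - s.cavity_volume_gradient(u - du)) / (2 * h)
            col = np.asarray(H[: s.n_u, i].todense()).ravel()
            assert np.abs(fd_H - col).max() < 1e-6


class TestInflation:
    def test_volume_at_current_state_gives_zero_pressure(self, tiny_mesh,
                                                         tiny_fibers):
        s = LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), None,
                     SolverConfig(steps_per_cycle=20))
        s.solve_to_volume(s.cavity_volume())
        assert abs(s.p_cav * KPA_TO_MMHG) < 0.01

    def test_pressure_volume_round_trip(self, tiny_mesh, tiny_fibers):
        s = LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), None,
                     SolverConfig(steps_per_cycle=20))
        V0 = s.cavity_volume()
        s.solve_to_pressure(5.0)
        assert s.cavity_volume() > V0
        s.solve_to_volume(V0)
        assert abs(s.p_cav) * KPA_TO_MMHG < 0.02
        assert np.sqrt((s.u**2).mean()) < 1e-6

    def test_passive_pv_curve_monotone(self, tiny_mesh, tiny_fibers):
        s = LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), None,
                     SolverConfig(steps_per_cycle=20))
        V0 = s.cavity_volume()
        pressures = []
        for f in (1.05, 1.15, 1.25, 1.35):
            s.solve_to_volume(V0 * f)
            pressures.append(s.p_cav)
        assert np.all(np.diff(pressures) > 0)

    def test_incompressible_during_passive_inflation(self, tiny_mesh,
                                                     tiny_fibers):
        s = LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), None,
                     SolverConfig(steps_per_cycle=20))
        s.solve_to_pressure(5.0)
        assert s.check_incompressibility() < 0.01

    def test_unreachable_volume_raises(self, tiny_mesh, tiny_fibers):
        s = LVSolver(tiny_mesh, tiny_fibers, PassiveParams(), None,
                     SolverConfig(steps_per_cycle=20, max_substeps=2,
                                  newton_maxit=8))
        with pytest.raises(NewtonError):
            s.solve_to_volume(20.0 * s.cavity_volume())


class TestThickSphereOracle:
    def test_isotropic_inflation_matches_radial_quadrature(
        self, sphere_inflation_vs_oracle
    ):
        """FE hemisphere shell vs the 1D incompressible-sphere oracle."""
        data = sphere_inflation_vs_oracle
        assert data["mesh_cells"] >= 1400
        for factor, p_fe, p_1d in data["rows"]:
            assert p_fe == pytest.approx(p_1d, rel=0.02), f"factor {factor}"


class TestObjectivity:
    def test_rotation_about_long_axis_preserves_pv_response(self, tiny_mesh):
        """Rigidly rotating mesh + fibers leaves the P-V relation unchanged."""
        theta = 0.7
        c, sn = np.cos(theta), np.sin(theta)
        R = np.array([[c, -sn, 0], [sn, c, 0], [0, 0, 1.0]])

        def inflate(mesh):
            fibers, _, _ = make_fiber_field(mesh, HelixConfig(10.0, 123.0))
            s = LVSolver(mesh, fibers, PassiveParams(), None,
                         SolverConfig(steps_per_cycle=20))
            s.solve_to_volume(1.15 * s.cavity_volume())
            return s.p_cav

        rotated = tiny_mesh.copy()
        rotated.points = tiny_mesh.points @ R.T
        assert inflate(rotated) == pytest.approx(inflate(tiny_mesh), rel=1e-6)


class TestStiffnessMonotonicity:
    def test_doubling_stiffness_reduces_inflation_displacement(self, tiny_mesh):
        def disp_norm(C):
            fibers, _, _ = make_fiber_field(tiny_mesh, HelixConfig(10.0, 123.0))
            s = LVSolver(tiny_mesh, fibers, PassiveParams(C=C), None,
                         SolverConfig(steps_per_cycle=20))
            s.solve_to_pressure(5.0)
            return np.linalg.norm(s.u)

        assert disp_norm(2 * 0.876) < disp_norm(0.876)
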