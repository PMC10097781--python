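"""Outcome metrics, strain error, helix maps, optima, and SSIM."""

import numpy as np
import pytest

from helixlv import (
    HelixConfig,
    StrainSummary,
    compute_stroke_work,
    find_optimal_point,
    map_ssim,
    strain_error,
)
from helixlv.metrics import (
    HelixMap,
    compute_biomech_metrics,
    compute_global_strains,
    compute_peak_myofiber_stress,
    compute_transmural_strain_variance,
    sweep_helix_map,
)


class TestStrokeWork:
    def test_rectangle_loop_closed_form(self):
        # p in [0, 10] mmHg, V in [1, 2] ml -> 10 mmHg*ml = 1.3332 mJ
        V = np.array([1.0, 2.0, 2.0, 1.0, 1.0])
        p = np.array([0.0, 0.0, 10.0, 10.0, 0.0])
        assert compute_stroke_work(V, p) == pytest.approx(1.3332, abs=2e-4)

    def test_degenerate_constant_volume_loop(self):
        V = np.full(5, 1.5)
        p = np.array([0.0, 5.0, 10.0, 5.0, 0.0])
        assert compute_stroke_work(V, p) == 0.0

    def test_reversed_orientation_warns_same_magnitude(self):
        V = np.array([1.0, 1.0, 2.0, 2.0, 1.0])
        p = np.array([0.0, 10.0, 10.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="orientation"):
            w = compute_stroke_work(V, p)
        assert w == pytest.approx(1.3332, abs=2e-4)

    def test_open_loop_rejected(self):
        V = np.array([1.0, 2.0, 2.0, 1.5])
        p = np.array([0.0, 0.0, 10.0, 8.0])
        with pytest.raises(ValueError, match="not closed"):
            compute_stroke_work(V, p)

    def test_matches_time_integral_of_p_dv(self, tiny_cycle):
        """Shoelace area equals the trapezoidal integral of p dV to 0.5%."""
        loop = tiny_cycle.loop
        w_shoelace = compute_stroke_work(loop)
        w_int = -np.trapezoid(loop.pressure_mmhg, loop.volume_ml) * 0.133322
        assert abs(w_int) == pytest.approx(w_shoelace, rel=0.005)


class TestFieldMetrics:
    def test_hydrostatic_state_fiber_projection(self, tiny_cycle):
        """sigma = p*I projects to p on any fiber direction (zero strain)."""
        solver = tiny_cycle.solver
        u0 = np.zeros((solver.mesh.n_points, 3))
        pm = np.full(solver.n_p, 2.5)  # kPa
        sig_ff = solver.cauchy_fiber_stress(u0, pm, None)
        assert np.allclose(sig_ff, 2.5, atol=1e-10)

    def test_peak_stress_positive_during_active_cycle(self, tiny_cycle):
        assert compute_peak_myofiber_stress(tiny_cycle) > 1.0  # kPa

    def test_identical_ed_es_gives_zero_burden_and_strains(self, tiny_cycle):
        class Frozen:
            solver = tiny_cycle.solver
            states = [tiny_cycle.states[0], tiny_cycle.states[0]]
            ed_index = 0
            es_index = 1

        from helixlv.metrics import compute_deformational_burden

        assert compute_deformational_burden(Frozen) == 0.0
        gs = compute_global_strains(Frozen)
        assert gs.eps_long == pytest.approx(0.0, abs=1e-12)
        assert gs.eps_circ == pytest.approx(0.0, abs=1e-12)

    def test_burden_scales_linearly_with_stiffness(self, tiny_cycle):
        from dataclasses import replace

        from helixlv.metrics import compute_deformational_burden

        base = compute_deformational_burden(tiny_cycle)

        class Doubled:
            solver = tiny_cycle.solver
            states = tiny_cycle.states
            ed_index = tiny_cycle.ed_index
            es_index = tiny_cycle.es_index

        old = tiny_cycle.solver.passive
        try:
            tiny_cycle.solver.passive = replace(old, C=2 * old.C)
            assert compute_deformational_burden(Doubled) == pytest.approx(
                2 * base, rel=1e-9
            )
        finally:
            tiny_cycle.solver.passive = old

    def test_transmural_variance_nonnegative_finite(self, tiny_cycle):
        v = compute_transmural_strain_variance(tiny_cycle)
        assert 0.0 <= v < 1.0

    def test_empty_slab_rejected(self, tiny_cycle):
        with pytest.raises(ValueError, match="slab"):
            compute_transmural_strain_variance(tiny_cycle,
                                               slab_half_width_fraction=1e-9)

    def test_full_metric_bundle_finite(self, tiny_cycle):
        m = compute_biomech_metrics(tiny_cycle)
        for v in m.to_dict().values():
            assert np.isfinite(v)


class TestStrainError:
    def test_identical_summaries_zero(self):
        a = StrainSummary(0.09, 0.10)
        assert strain_error(a, a) == 0.0

    def test_symmetry(self):
        a = StrainSummary(0.09, 0.10)
        b = StrainSummary(0.08, 0.12)
        assert strain_error(a, b) == strain_error(b, a)

    def test_reported_case1_value(self):
        """Best-match configuration strain pairs give ER = 6.409e-5."""
        fe = StrainSummary(eps_long=0.0898, eps_circ=0.0905)
        echo = StrainSummary(eps_long=0.0895, eps_circ=0.0825)
        assert strain_error(fe, echo) == pytest.approx(6.409e-5, abs=1e-12)

    def test_unit_mismatch_rejected(self):
        a = StrainSummary(0.09, 0.10)
        b = StrainSummary(9.0, 10.0, units="percent")
        with pytest.raises(ValueError, match="unit"):
            strain_error(a, b)


class TestHelixMaps:
    @staticmethod
    def paraboloid(tb, td):
        return -((tb - 5.0) ** 2) - (td - 100.0) ** 2

    def test_single_point_grid(self):
        maps = sweep_helix_map(
            lambda c: {"m": self.paraboloid(c.tau_bar, c.tau_diff)},
            [10.0], [100.0],
        )
        assert maps["m"].values.shape == (1, 1)
        assert maps["m"].values[0, 0] == self.paraboloid(10.0, 100.0)

    def test_interpolant_reproduces_node_values(self):
        tb = np.arange(-20.0, 40.0, 5.0)
        td = np.arange(80.0, 130.0, 5.0)
        maps = sweep_helix_map(
            lambda c: {"m": self.paraboloid(c.tau_bar, c.tau_diff)}, tb, td
        )
        hm = maps["m"]
        for i in (0, 3, len(tb) - 1):
            for j in (0, 2, len(td) - 1):
                assert hm.evaluate(tb[i], td[j]) == pytest.approx(
                    hm.values[i, j], abs=1e-9
                )

    def test_optimum_recovered_within_half_grid_spacing(self):
        tb = np.arange(-20.0, 41.0, 5.0)
        td = np.arange(80.0, 131.0, 5.0)
        maps = sweep_helix_map(
            lambda c: {"m": self.paraboloid(c.tau_bar, c.tau_diff)}, tb, td
        )
        opt = find_optimal_point(maps["m"], "max")
        assert abs(opt.tau_bar - 5.0) < 0.5
        assert abs(opt.tau_diff - 100.0) < 0.5
        assert not opt.on_boundary

    def test_monotone_surface_flags_boundary(self):
        tb = np.arange(0.0, 31.0, 10.0)
        td = np.arange(0.0, 31.0, 10.0)
        maps = sweep_helix_map(
            lambda c: {"m": c.tau_bar + 0.1 * c.tau_diff}, tb, td
        )
        opt = find_optimal_point(maps["m"], "max")
        assert opt.on_boundary
        assert opt.tau_bar == pytest.approx(30.0, abs=1e-3)

    def test_min_max_duality(self):
        tb = np.arange(-20.0, 41.0, 10.0)
        td = np.arange(80.0, 131.0, 10.0)
        pos = sweep_helix_map(
            lambda c: {"m": self.paraboloid(c.tau_bar, c.tau_diff)}, tb, td
        )["m"]
        neg = HelixMap(pos.tau_bar, pos.tau_diff, -pos.values)
        a = find_optimal_point(pos, "max")
        b = find_optimal_point(neg, "min")
        assert a.tau_bar == pytest.approx(b.tau_bar, abs=1e-6)
        assert a.value == pytest.approx(-b.value, abs=1e-9)

    def test_flat_map_rejected(self):
        hm = HelixMap(np.array([0.0, 10.0]), np.array([0.0, 10.0]),
                      np.ones((2, 2)))
        with pytest.raises(ValueError, match="optimum"):
            find_optimal_point(hm, "max")

    def test_failed_points_masked_and_limited(self):
        def patchy(c):
            if c.tau_bar == 0.0 and c.tau_diff == 0.0:
                raise RuntimeError("solver blew up")
            return {"m": c.tau_bar + c.tau_diff}

        maps = sweep_helix_map(patchy, [0.0, 10.0, 20.0], [0.0, 10.0, 20.0])
        assert np.isnan(maps["m"].values[0, 0])
        assert maps["m"].mask.sum() == 8

        def always_fail(c):
            raise RuntimeError("nope")

        with pytest.raises(RuntimeError, match="grid points"):
            sweep_helix_map(always_fail, [0.0, 10.0], [0.0, 10.0])


class TestSSIM:
    def _map(self, values):
        n = values.shape[0]
        return HelixMap(np.arange(n) * 10.0, np.arange(values.shape[1]) * 10.0,
                        values)

    def test_identical_maps_score_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((7, 7))
        assert map_ssim(self._map(v), self._map(v.copy())) == 1.0

    def test_small_noise_scores_near_one(self):
        rng = np.random.default_rng(1)
        v = np.add.outer(np.linspace(0, 1, 9), np.linspace(0, 2, 9))
        noisy = v + 1e-5 * rng.standard_normal(v.shape)
        assert map_ssim(self._map(v), self._map(noisy)) > 0.999

    def test_dissimilar_maps_score_lower(self):
        rng = np.random.default_rng(2)
        a = np.add.outer(np.linspace(0, 1, 9), np.linspace(0, 2, 9))
        b = rng.random((9, 9))
        assert map_ssim(self._map(a), self._map(b)) < 0.8

    def test_grid_mismatch_rejected(self):
        a = self._map(np.random.default_rng(0).random((5, 5)))
        b = HelixMap(np.arange(5) * 11.0, np.arange(5) * 10.0, a.values)
        with pytest.raises(ValueError, match="grid"):
            map_ssim(a, b)
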