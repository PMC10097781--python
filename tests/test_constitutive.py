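"""Fung passive law and calcium-activation active tension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helixlv import ActiveParams, PassiveParams
from helixlv.constitutive import (
    StrainOverflowError,
    activation_timecourse,
    active_stress,
    eca50,
    fung_exponent,
    passive_energy,
    passive_stress,
    passive_tangent,
    relaxation_duration,
)


def random_small_strains(n, rng, scale=0.08):
    A = scale * rng.standard_normal((n, 3, 3))
    return 0.5 * (A + np.swapaxes(A, 1, 2))


class TestPassive:
    def test_zero_strain_zero_energy_zero_stress(self):
        p = PassiveParams()
        E = np.zeros((3, 3))
        assert passive_energy(E, p) == 0.0
        assert np.allclose(passive_stress(E, p), 0.0)

    def test_uniaxial_closed_forms(self):
        p = PassiveParams()
        e = 0.1
        E = np.zeros((3, 3))
        E[0, 0] = e
        w_expected = 0.5 * p.C * np.expm1(p.b_ff * e**2)
        s_expected = p.C * p.b_ff * e * np.exp(p.b_ff * e**2)
        assert passive_energy(E, p) == pytest.approx(w_expected, rel=1e-12)
        S = passive_stress(E, p)
        assert S[0, 0] == pytest.approx(s_expected, rel=1e-12)
        assert np.allclose(S[1:, 1:], 0.0)

    def test_transverse_isotropy_sheet_normal_swap(self):
        p = PassiveParams()
        rng = np.random.default_rng(7)
        E = random_small_strains(20, rng)
        swapped = E[:, [0, 2, 1]][:, :, [0, 2, 1]]  # s <-> n
        assert np.allclose(passive_energy(E, p), passive_energy(swapped, p))

    def test_transverse_isotropy_random_rotation(self):
        p = PassiveParams()
        rng = np.random.default_rng(3)
        E = random_small_strains(10, rng)
        for theta in rng.uniform(0, 2 * np.pi, size=4):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])  # (s, n) plane
            Erot = np.einsum("ai,nij,bj->nab", R, E, R)
            assert np.allclose(
                passive_energy(Erot, p), passive_energy(E, p), rtol=1e-10
            )

    def test_energy_stress_consistency_100_random_states(self):
        """dW/dE matches passive_stress to 1e-6 relative (central FD)."""
        p = PassiveParams()
        rng = np.random.default_rng(42)
        E = random_small_strains(100, rng)
        S = passive_stress(E, p)
        h = 1e-7
        for i in range(3):
            for j in range(i, 3):
                dE = np.zeros((3, 3))
                dE[i, j] = dE[j, i] = h  # symmetric perturbation
                fd = (passive_energy(E + dE, p) - passive_energy(E - dE, p)) / (
                    2 * h
                )
                expected = S[:, i, j] if i == j else S[:, i, j] + S[:, j, i]
                scale = np.abs(expected).max() + 1e-12
                assert np.abs(fd - expected).max() / scale < 1e-6

    def test_tangent_matches_stress_derivative(self):
        p = PassiveParams()
        rng = np.random.default_rng(11)
        E = random_small_strains(5, rng)
        C4 = passive_tangent(E, p)
        h = 1e-7
        for k in range(3):
            for l in range(k, 3):
                dE = np.zeros((3, 3))
                dE[k, l] = dE[l, k] = h  # symmetric perturbation
                fd = (passive_stress(E + dE, p) - passive_stress(E - dE, p)) / (
                    2 * h
                )
                an = C4[:, :, :, k, l] + C4[:, :, :, l, k] if k != l else (
                    C4[:, :, :, k, k]
                )
                assert np.abs(fd - an).max() < 1e-4 * (np.abs(an).max() + 1)

    def test_overflow_guard_names_the_state(self):
        p = PassiveParams()
        E = np.zeros((3, 3))
        E[0, 0] = 5.0
        with pytest.raises(StrainOverflowError, match="exceeds the cap"):
            fung_exponent(E, p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PassiveParams(C=-1.0)
        with pytest.raises(ValueError):
            PassiveParams(b_ff=-0.1)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-0.3, 0.3), st.floats(-0.3, 0.3), st.floats(-0.3, 0.3))
    def test_energy_nonnegative_and_zero_only_at_zero(self, a, b, c):
        p = PassiveParams()
        E = np.diag([a, b, c])
        w = passive_energy(E, p)
        assert w >= 0.0
        if max(abs(a), abs(b), abs(c)) > 1e-12:
            assert w > 0.0


class TestActivation:
    def test_timecourse_branch_values(self):
        p = ActiveParams()
        l = 2.0
        assert activation_timecourse(0.0, l, p).Ct == 0.0
        assert activation_timecourse(p.t0, l, p).Ct == pytest.approx(1.0)
        t_r = float(relaxation_duration(l, p))
        late = activation_timecourse(min(p.t0 + t_r + 1, p.cycle_length - 1e-9),
                                     l, p)
        assert late.Ct == pytest.approx(0.0, abs=1e-12)

    def test_continuity_at_branch_points(self):
        p = ActiveParams()
        l = 2.0
        t_r = float(relaxation_duration(l, p))
        eps = 1e-9
        below = activation_timecourse(p.t0 - eps, l, p).Ct
        above = activation_timecourse(p.t0 + eps, l, p).Ct
        assert below == pytest.approx(1.0, abs=1e-12)
        assert above == pytest.approx(1.0, abs=1e-12)
        end_lo = activation_timecourse(p.t0 + t_r - eps, l, p).Ct
        end_hi = activation_timecourse(p.t0 + t_r + eps, l, p).Ct
        assert end_lo == pytest.approx(0.0, abs=1e-12)
        assert end_hi == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_duration_direct_evaluation(self):
        p = ActiveParams(m=50.0, b_time=40.0)
        assert relaxation_duration(2.0, p) == pytest.approx(140.0)

    def test_nonpositive_relaxation_raises(self):
        p = ActiveParams(m=50.0, b_time=-200.0)
        with pytest.raises(ValueError, match="relaxation"):
            activation_timecourse(10.0, 2.0, p)

    def test_eca50_domain_error_below_l0(self):
        p = ActiveParams()
        with pytest.raises(ValueError, match="ECa50"):
            eca50(p.l0, p)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.0, 399.999), st.floats(1.7, 2.3))
    def test_ct_bounded_unit_interval(self, t, l):
        p = ActiveParams()
        Ct = activation_timecourse(t, l, p).Ct
        assert 0.0 <= Ct <= 1.0


class TestActiveStress:
    def test_zero_when_inactive(self):
        p = ActiveParams()
        assert active_stress(0.0, 2.0, p) == pytest.approx(0.0)
        assert active_stress(0.0, p.l0 - 0.05, p) == 0.0

    def test_half_maximal_when_ca_equals_eca50(self):
        p = ActiveParams()
        # pick l so that ECa50(l) == Ca0
        l = p.l0 + np.log1p((p.Ca0_max / p.Ca0) ** 2) / p.B_len
        assert eca50(l, p) == pytest.approx(p.Ca0)
        got = active_stress(p.t0, l, p)
        assert got == pytest.approx(p.T0_LV / 2.0, rel=1e-9)

    def test_saturation_limit_large_length(self):
        p = ActiveParams(m=524.5, b_time=-800.0)
        # large l -> ECa50 -> 0 -> P_act -> T0 * Ct
        got = active_stress(p.t0, 3.5, p)
        assert got == pytest.approx(p.T0_LV, rel=1e-3)

    def test_monotone_in_ca0_and_t0lv(self):
        t, l = 120.0, 2.0
        base = active_stress(t, l, ActiveParams())
        assert active_stress(t, l, ActiveParams(Ca0=5.0)) > base
        assert active_stress(t, l, ActiveParams(T0_LV=50.0)) > base

    def test_bounded_by_maximum_tension(self):
        p = ActiveParams()
        t = np.linspace(0, p.cycle_length, 100, endpoint=False)
        for ti in t:
            val = float(active_stress(ti, 2.1, p))
            assert 0.0 <= val <= p.T0_LV + 1e-12
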