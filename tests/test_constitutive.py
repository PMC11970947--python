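"""Closed-form rheology, drag and waveform checks against hand-computed values."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tumorperf import constitutive as c


class TestHematocritPolynomials:
    @pytest.mark.parametrize("gdot", [0.5, 2.0, 6.0, 50.0])
    def test_pure_plasma_identity(self, gdot):
        assert c.coeff_a(0.0, gdot) == pytest.approx(1.0, abs=1e-14)
        assert c.coeff_b(0.0, gdot) == pytest.approx(1.0, abs=1e-14)

    def test_high_shear_values_at_45_percent(self):
        # cubic evaluations done by hand
        assert c.coeff_a(0.45, 10.0) == pytest.approx(9.109, abs=5e-4)
        assert c.coeff_b(0.45, 10.0) == pytest.approx(0.7491, abs=5e-5)

    def test_low_shear_branch_at_45_percent(self):
        expected = 70.782 * 0.45 ** 3 - 22.454 * 0.45 ** 2 + 9.7193 * 0.45 + 1
        assert c.coeff_a(0.45, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_branch_switch_is_discontinuous_but_finite(self):
        lo = c.coeff_b(0.45, 6.0 - 1e-9)
        hi = c.coeff_b(0.45, 6.0)
        assert np.isfinite(lo) and np.isfinite(hi)
        assert abs(lo - hi) < 1.0  # a bounded jump, not a blow-up

    def test_low_shear_b_clamped_near_zero_shear(self):
        # k = ln(ln g)/ln g is undefined for g <= 1; clamped evaluation must
        # stay finite and keep b <= 1 (bounded viscosity)
        b = c.coeff_b(0.45, 0.0)
        assert np.isfinite(b) and b <= 1.0


class TestMixtureViscosity:
    def test_pure_plasma_is_unity(self):
        assert c.relative_mixture_viscosity(0.0, 123.0) == pytest.approx(1.0)

    def test_zero_shear_reduces_to_prefactor(self):
        assert c.relative_mixture_viscosity(0.45, 0.0) == pytest.approx(
            c.coeff_a(0.45, 0.0))

    def test_shear_thinning_below_prefactor(self):
        mu = c.relative_mixture_viscosity(0.45, 100.0)
        expected = c.coeff_a(0.45, 100.0) * (
            1 + (0.11 * 100) ** 2) ** ((c.coeff_b(0.45, 100.0) - 1) / 2)
        assert mu == pytest.approx(expected, rel=1e-12)
        assert mu < c.coeff_a(0.45, 100.0)

    @given(psi=st.floats(0.30, 0.55), g1=st.floats(6.0, 999.0),
           dg=st.floats(1e-3, 500.0))
    def test_nonincreasing_in_shear(self, psi, g1, dg):
        g2 = min(g1 + dg, 1000.0)
        assert (c.relative_mixture_viscosity(psi, g2)
                <= c.relative_mixture_viscosity(psi, g1) + 1e-12)

    @given(g=st.floats(6.0, 1000.0), p1=st.floats(0.0, 0.54),
           dp=st.floats(1e-4, 0.2))
    def test_increasing_in_hematocrit(self, g, p1, dp):
        p2 = min(p1 + dp, 0.55)
        assert (c.relative_mixture_viscosity(p2, g)
                >= c.relative_mixture_viscosity(p1, g) - 1e-12)


class TestRbcViscosity:
    def test_round_trip_identity(self):
        vf = {"plasma": 0.55, "rbc": 0.44, "wbc": 0.01}
        eta = c.rbc_viscosity(vf, 50.0)
        assert eta > 0
        mu_back = (0.44 * eta + 0.55 * 0.001 + 0.01 * 0.011) / 0.001
        assert mu_back == pytest.approx(
            c.relative_mixture_viscosity(0.44, 50.0), abs=1e-12)

    def test_pure_rbc_limit(self):
        vf = {"plasma": 1e-9, "rbc": 1.0 - 1e-9, "wbc": 0.0}
        eta = c.rbc_viscosity(vf, 50.0)
        mu = c.relative_mixture_viscosity(1.0 - 1e-9, 50.0)
        assert eta == pytest.approx(mu * 0.001, rel=1e-6)

    def test_floor_guard(self, caplog):
        # extreme shear drives the correlation below the plasma bound
        vf = {"plasma": 0.55, "rbc": 0.44, "wbc": 0.01}
        eta = c.rbc_viscosity(vf, 1e6, floor=1e-6)
        assert eta == pytest.approx(1e-6)

    def test_zero_hematocrit_rejected(self):
        with pytest.raises(ValueError):
            c.rbc_viscosity({"plasma": 1.0, "rbc": 0.0, "wbc": 0.0}, 10.0)


class TestShapeFactor:
    def test_values(self):
        assert c.shape_factor(0.0) == pytest.approx(1.5)
        assert c.shape_factor(400.0) == 1.0
        assert c.shape_factor(300.0) == pytest.approx(
            1.5 * (1 + 33.0 ** 2) ** 0.058997, rel=1e-9)
        assert c.shape_factor(300.0) == pytest.approx(2.266, abs=5e-3)


class TestDrag:
    def test_smooth_branch(self):
        assert c.drag_coefficient(1.0) == pytest.approx(27.6)

    def test_newton_branch(self):
        assert c.drag_coefficient(2000.0) == 0.44

    def test_branches_nearly_continuous_at_1000(self):
        gap = abs(c.drag_coefficient(1000.0) - 0.44)
        assert gap < 0.01

    @given(re=st.floats(1e-12, 1e-4))
    def test_stokes_product_limit(self, re):
        assert c.drag_coefficient(re) * re == pytest.approx(24.0, rel=1e-2)

    def test_particle_reynolds(self):
        re = c.particle_reynolds(1030.0, 7e-6, 1.5, 1e-3, 1e-3)
        assert re == pytest.approx(0.0108, abs=2e-4)
        assert c.particle_reynolds(1030.0, 7e-6, 3.0, 1e-3, 1e-3) == (
            pytest.approx(2 * re))
        assert c.particle_reynolds(1030.0, 7e-6, 1.5, 0.0, 1e-3) == 0.0


class TestExchangeCoefficient:
    def test_vanishing_dispersed_phase(self):
        assert c.exchange_coefficient(1030, 1e-3, 7e-6, 1.5, 0.55, 0.0,
                                      1e-3) == 0.0

    def test_small_slip_matches_stokes_closed_form(self):
        closed = 18 * 0.55 * 0.44 * 1e-3 / (7e-6 ** 2 * 1.5 ** 2)
        brute = c.exchange_coefficient(1030, 1e-3, 7e-6, 1.5, 0.55, 0.44, 1e-9)
        assert brute == pytest.approx(closed, rel=1e-4)

    def test_finite_and_pair_symmetric(self):
        a = c.exchange_coefficient(1030, 1e-3, 7e-6, 1.5, 0.55, 0.44, 1e-3)
        b = c.exchange_coefficient(1030, 1e-3, 7e-6, 1.5, 0.44, 0.55, 1e-3)
        assert 0 < a < np.inf
        # alpha is one coefficient for the pair: swapping which phase is
        # "experiencing" the force only swaps Psi_cp and Psi_dp
        assert a == pytest.approx(b)


class TestWaveform:
    def test_periodicity(self):
        wf = c.default_waveform()
        t = np.linspace(0, 3 * wf.period, 57)
        np.testing.assert_allclose(c.inlet_velocity(t, wf),
                                   c.inlet_velocity(t + wf.period, wf),
                                   atol=1e-12)

    def test_zero_harmonics_give_constant_mean(self):
        wf = c.InletWaveform(0.735, 0.01, (), ())
        t = np.linspace(0, 1.0, 11)
        np.testing.assert_allclose(c.inlet_velocity(t, wf), 0.01)

    def test_default_pulse_is_nonnegative(self):
        wf = c.default_waveform()
        t = np.linspace(0, wf.period, 20001)
        u = c.inlet_velocity(t, wf)
        assert u.min() >= 0.0
        assert u.mean() == pytest.approx(wf.mean_velocity, rel=1e-3)
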