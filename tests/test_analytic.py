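"""Closed-form thin-channel flow, design formula, and the Newtonian duct series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from oocflow.analytic import (
    ShearStressScaling,
    design_correction_factor,
    design_flow_rate,
    flow_rate_correction,
    mid_wall_shear_correction,
    newtonian_rect_series,
    rescale_solution_to_flow_rate,
    shear_stress_from_flow_rate,
    thin_channel_flow_rate,
    thin_channel_pressure_gradient,
    thin_channel_velocity,
    thin_channel_wall_shear,
)
from oocflow.errors import InvalidModelError
from oocflow.geometry import ChannelGeometry, DriveSpec
from oocflow.rheology import PowerLawFluid
from oocflow.units import ul_per_min_to_m3_per_s

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

STUDY_GEOM = ChannelGeometry(w=1.2e-3, h=1.25e-3)
Q_4UL = ul_per_min_to_m3_per_s(4.0)

fluid_strategy = st.builds(
    PowerLawFluid, K=st.floats(1e-4, 1.0), n=st.floats(0.2, 1.5)
)


class TestThinChannel:
    def test_no_slip_and_symmetry(self):
        fluid = PowerLawFluid(K=0.028, n=0.31)
        h, G = 1e-3, 5.0
        assert thin_channel_velocity(0.0, G, fluid, h) == 0.0
        assert thin_channel_velocity(h, G, fluid, h) == 0.0
        z = np.linspace(0, h, 11)
        u = thin_channel_velocity(z, G, fluid, h)
        np.testing.assert_allclose(u, u[::-1], rtol=1e-12)
        assert np.argmax(u) == 5

    def test_newtonian_parabola(self):
        mu, h, G = 1e-3, 1e-3, 10.0
        fluid = PowerLawFluid(K=mu, n=1.0)
        u_mid = thin_channel_velocity(h / 2, G, fluid, h)
        assert u_mid == pytest.approx(G * h**2 / (8 * mu), rel=1e-12)

    def test_out_of_gap_rejected(self):
        fluid = PowerLawFluid(K=0.01, n=0.5)
        with pytest.raises(ValueError):
            thin_channel_velocity(-1e-6, 1.0, fluid, 1e-3)

    def test_quadrature_matches_flow_rate_formula(self):
        fluid = PowerLawFluid(K=0.005, n=0.54)
        geom = ChannelGeometry(w=5e-3, h=0.5e-3)
        G = 20.0
        q_quad, _ = quad(lambda z: thin_channel_velocity(z, G, fluid, geom.h), 0, geom.h)
        q_formula = thin_channel_flow_rate(G, fluid, geom)
        assert geom.w * q_quad == pytest.approx(q_formula, rel=1e-8)

    def test_flow_rate_power_law_homogeneity(self):
        fluid = PowerLawFluid(K=0.016, n=0.51)
        geom = ChannelGeometry(w=5e-3, h=0.5e-3)
        q1 = thin_channel_flow_rate(10.0, fluid, geom)
        q2 = thin_channel_flow_rate(20.0, fluid, geom)
        assert q2 / q1 == pytest.approx(2.0 ** (1.0 / fluid.n), rel=1e-12)

    def test_pressure_gradient_round_trip_closed_form_and_root_find(self):
        fluid = PowerLawFluid(K=0.005, n=0.54)
        geom = ChannelGeometry(w=1.2e-3, h=1.25e-3)
        with pytest.warns(UserWarning, match="aspect"):
            g = thin_channel_pressure_gradient(Q_4UL, fluid, geom)
            assert thin_channel_flow_rate(g, fluid, geom) == pytest.approx(Q_4UL, rel=1e-10)
            g_root = brentq(
                lambda G: thin_channel_flow_rate(G, fluid, geom) - Q_4UL, 1e-6, 1e4
            )
        assert g_root == pytest.approx(g, rel=1e-8)

    def test_wall_shear_value_at_study_conditions(self):
        # parallel-plate approximation of the 1.2 x 1.25 mm channel at
        # 4 uL/min for the body-temperature medium: ~2.5 mPa. The full 2-D
        # solve gives ~3.2 mPa because w ~ h badly violates w >> h.
        fluid = PowerLawFluid(K=0.005, n=0.54)
        tau = thin_channel_wall_shear(DriveSpec(flow_rate=Q_4UL), fluid, STUDY_GEOM)
        assert tau == pytest.approx(2.485e-3, rel=1e-3)

    def test_pressure_driven_form_is_fluid_independent(self):
        geom = ChannelGeometry(w=5e-3, h=0.5e-3)
        drive = DriveSpec(pressure_gradient=40.0)
        taus = {
            thin_channel_wall_shear(drive, PowerLawFluid(K=K, n=n), geom)
            for K, n in [(0.01, 0.3), (1e-3, 1.0), (0.05, 0.7)]
        }
        assert taus == {40.0 * geom.h / 2}

    def test_newtonian_flow_rate_form(self):
        mu = 1e-3
        geom = ChannelGeometry(w=5e-3, h=0.5e-3)
        q = 1e-10
        tau = thin_channel_wall_shear(DriveSpec(flow_rate=q), PowerLawFluid(K=mu, n=1.0), geom)
        assert tau == pytest.approx(6 * mu * q / (geom.h**2 * geom.w), rel=1e-12)

    @given(fluid=fluid_strategy, G=st.floats(0.1, 100.0))
    def test_two_wall_shear_forms_agree(self, fluid, G):
        geom = ChannelGeometry(w=4e-3, h=0.5e-3)
        q = thin_channel_flow_rate(G, fluid, geom)
        tau_p = thin_channel_wall_shear(DriveSpec(pressure_gradient=G), fluid, geom)
        tau_q = thin_channel_wall_shear(DriveSpec(flow_rate=q), fluid, geom)
        assert tau_q == pytest.approx(tau_p, rel=1e-10)


class TestDesignFormula:
    def test_newtonian_wide_channel_limit(self):
        mu, tau = 1e-3, 0.01
        geom = ChannelGeometry(w=0.5, h=0.5e-3)  # w/h = 1000
        q = design_flow_rate(tau, PowerLawFluid(K=mu, n=1.0), geom)
        q_plate = geom.h**2 * geom.w * tau / (6 * mu)
        assert q == pytest.approx(q_plate, rel=1e-3)

    def test_monotone_in_target_with_slope_one_over_n(self):
        fluid = PowerLawFluid(K=0.028, n=0.31)
        geom = ChannelGeometry(w=3e-3, h=0.5e-3)
        taus = np.geomspace(1e-3, 1.0, 7)
        qs = np.array([design_flow_rate(t, fluid, geom) for t in taus])
        assert np.all(np.diff(qs) > 0)
        slopes = np.diff(np.log(qs)) / np.diff(np.log(taus))
        np.testing.assert_allclose(slopes, 1.0 / fluid.n, rtol=1e-10)

    def test_correction_factor_bounds_and_monotonicity(self):
        aspects = np.linspace(1.05, 40.0, 60)
        g = np.array([design_correction_factor(a) for a in aspects])
        assert np.all(g > 0) and np.all(g <= 1.0)
        assert np.all(np.diff(g) > 0)
        # approaches unity like 1 - (192/pi^5)/(w/h)
        assert design_correction_factor(2000.0) == pytest.approx(1.0, abs=5e-4)

    def test_correction_components(self):
        # F and S are both reductions relative to the parallel-plate limit
        assert 0 < flow_rate_correction(1.5) < mid_wall_shear_correction(1.5) < 1

    def test_preconditions(self):
        fluid = PowerLawFluid(K=0.01, n=0.5)
        with pytest.raises(InvalidModelError):
            design_flow_rate(0.01, fluid, ChannelGeometry(w=0.5e-3, h=1e-3))
        with pytest.raises(ValueError):
            design_flow_rate(-1.0, fluid, ChannelGeometry(w=2e-3, h=0.5e-3))


class TestNewtonianSeries:
    def test_term_doubling_converged(self):
        geom = ChannelGeometry(w=1.2e-3, h=1.25e-3)
        s50 = newtonian_rect_series(DriveSpec(pressure_gradient=1.0), 1e-3, geom, 50)
        s100 = newtonian_rect_series(DriveSpec(pressure_gradient=1.0), 1e-3, geom, 100)
        assert abs(s100.Q - s50.Q) / s50.Q < 1e-8
        assert abs(s100.tau_max("top") - s50.tau_max("top")) / s50.tau_max("top") < 1e-8

    def test_symmetry(self):
        geom = ChannelGeometry(w=2e-3, h=1e-3)
        s = newtonian_rect_series(DriveSpec(pressure_gradient=5.0), 1e-3, geom)
        y = np.linspace(0, geom.w, 21)
        z = np.linspace(0, geom.h, 17)
        u = s.velocity(y, z)
        np.testing.assert_allclose(u, u[:, ::-1], atol=1e-12 * u.max())
        np.testing.assert_allclose(u, u[::-1, :], atol=1e-12 * u.max())

    def test_wide_channel_limit_flow_rate(self):
        # the side walls cost (192/pi^5)(h/w) of the parallel-plate flow:
        # 1.25% at w/h = 50, vanishing as the channel widens
        for aspect, tol in [(50.0, 0.014), (1000.0, 7e-4)]:
            geom = ChannelGeometry(w=aspect * 1e-3, h=1e-3)
            s = newtonian_rect_series(DriveSpec(pressure_gradient=3.0), 1e-3, geom)
            q_plate = 3.0 * geom.h**3 * geom.w / (12 * 1e-3)
            deficit = (q_plate - s.Q) / q_plate
            assert 0 < deficit < tol

    def test_square_duct_conductance_constant(self):
        # dimensionless conductance Q mu / (G a^4) = 0.035144 for a square duct
        a = 1e-3
        s = newtonian_rect_series(DriveSpec(pressure_gradient=1.0), 1e-3, ChannelGeometry(w=a, h=a))
        assert s.Q * 1e-3 / a**4 == pytest.approx(0.035144, rel=5e-4)

    def test_flow_rate_drive(self):
        geom = ChannelGeometry(w=1.2e-3, h=1.25e-3)
        s = newtonian_rect_series(DriveSpec(flow_rate=Q_4UL), 9.3e-4, geom)
        assert s.Q == pytest.approx(Q_4UL, rel=1e-12)

    def test_wall_shear_vanishes_at_corners(self):
        geom = ChannelGeometry(w=2e-3, h=1e-3)
        s = newtonian_rect_series(DriveSpec(pressure_gradient=5.0), 1e-3, geom, n_terms=400)
        prof = s.wall_shear_profile("top", [0.0, 1e-6, geom.w / 2])
        assert prof[0] < 0.02 * prof[2]
        assert prof[1] < prof[2]


class TestScalingLaw:
    def test_matches_thin_channel_form(self):
        fluid = PowerLawFluid(K=0.016, n=0.51)
        geom = ChannelGeometry(w=5e-3, h=0.5e-3)
        scaling = ShearStressScaling.from_thin_channel(fluid, geom)
        q = 1e-10
        assert scaling.tau(q) == pytest.approx(
            thin_channel_wall_shear(DriveSpec(flow_rate=q), fluid, geom), rel=1e-12
        )

    def test_flow_rate_homogeneity(self):
        # doubling Q multiplies tau by 2**n for a power-law fluid,
        # i.e. tau is linear in Q only in the Newtonian case
        scaling = ShearStressScaling(K_tau=3.0, n=0.31)
        assert scaling.tau(2e-10) / scaling.tau(1e-10) == pytest.approx(2**0.31)
        newt = ShearStressScaling(K_tau=3.0, n=1.0)
        assert newt.tau(2e-10) / newt.tau(1e-10) == pytest.approx(2.0)

    def test_inverse(self):
        scaling = ShearStressScaling(K_tau=2.5, n=0.54)
        q = 7e-11
        assert scaling.flow_rate(scaling.tau(q)) == pytest.approx(q, rel=1e-12)

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError):
            shear_stress_from_flow_rate(1e-10, None)


class TestRescale:
    def test_identity(self, plug_solution):
        out = rescale_solution_to_flow_rate(plug_solution, plug_solution.Q)
        np.testing.assert_array_equal(out.u, plug_solution.u)
        assert out.pressure_gradient == plug_solution.pressure_gradient

    def test_newtonian_pressure_linear_in_flow(self, lit_solution):
        out = rescale_solution_to_flow_rate(lit_solution, 2 * lit_solution.Q)
        assert out.pressure_gradient == pytest.approx(
            2 * lit_solution.pressure_gradient, rel=1e-12
        )

    def test_power_law_pressure_scaling(self, plug_solution):
        c = 3.0
        out = rescale_solution_to_flow_rate(plug_solution, c * plug_solution.Q)
        assert out.pressure_gradient == pytest.approx(
            c**0.31 * plug_solution.pressure_gradient, rel=1e-12
        )

    def test_nonpositive_target_rejected(self, plug_solution):
        with pytest.raises(ValueError):
            rescale_solution_to_flow_rate(plug_solution, 0.0)
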