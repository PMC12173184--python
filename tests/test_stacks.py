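"""Velocity-stack assembly, wall location, and measured wall shear stress."""

import numpy as np
import pytest

from oocflow.errors import InsufficientDataError, InvalidModelError
from oocflow.rheology import PowerLawFluid
from oocflow.stacks import (
    ChannelBoundsEstimate,
    VelocityStack,
    assemble_velocity_stack,
    compare_profiles,
    locate_channel_walls,
    read_stack,
    wall_shear_from_stack,
    write_stack,
)
from oocflow.solver import wall_shear_map
from oocflow.synthetic import NoiseModel, generate_velocity_stack

QUIET = NoiseModel(layer_fluctuation_frac=0.0, velocity_sd=0.0, width_jitter_frac=0.0)


class TestAssemble:
    def test_sorts_layers(self):
        prof = np.zeros(5)
        stack = assemble_velocity_stack(
            [(2e-4, prof), (0.0, prof), (1e-4, prof)], delta_y=37e-6
        )
        np.testing.assert_allclose(stack.z, [0.0, 1e-4, 2e-4])

    def test_averages_2d_layers_over_x(self):
        field = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])  # (x, y)
        stack = assemble_velocity_stack(
            [(0.0, field), (1e-4, field), (2e-4, field)], delta_y=37e-6
        )
        np.testing.assert_allclose(stack.u[0], [2.0, 3.0, 4.0])

    def test_too_few_layers(self):
        with pytest.raises(InsufficientDataError):
            assemble_velocity_stack([(0.0, np.zeros(4)), (1e-4, np.zeros(4))])

    def test_duplicate_z_rejected(self):
        p = np.zeros(4)
        with pytest.raises(InvalidModelError):
            assemble_velocity_stack([(0.0, p), (0.0, p), (1e-4, p)])

    def test_inconsistent_grids_rejected(self):
        with pytest.raises(InvalidModelError):
            assemble_velocity_stack([(0.0, np.zeros(4)), (1e-4, np.zeros(5)), (2e-4, np.zeros(4))])

    def test_reproduces_solver_samples(self, body_temp_solution):
        # layers built directly from solver rows reproduce the solver values
        sol = body_temp_solution
        rows = range(0, sol.z.size, 2)
        stack = assemble_velocity_stack(
            [(sol.z[i], sol.u[i, :]) for i in rows], delta_y=sol.dy
        )
        np.testing.assert_array_equal(stack.u, sol.u[list(rows), :])


class TestLocateWalls:
    def test_noiseless_height_estimate(self, body_temp_solution):
        stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, QUIET)
        bounds = locate_channel_walls(stack, 1e-9)
        h = body_temp_solution.geometry.h
        assert abs(bounds.height - h) <= 2 * 33e-6
        assert abs(bounds.z_top - h) <= 33e-6
        assert abs(bounds.z_bottom) <= 33e-6

    def test_all_quiet_stack_rejected(self):
        stack = VelocityStack(
            z=np.arange(5) * 33e-6,
            y=np.arange(8) * 37e-6,
            u=np.zeros((5, 8)),
            delta_z=33e-6,
            delta_y=37e-6,
        )
        with pytest.raises(InvalidModelError):
            locate_channel_walls(stack, 1e-6)

    def test_width_error_with_wall_jitter(self, body_temp_solution):
        # rigid per-layer wall jitter of 5% of the width: the median-based
        # estimate stays consistent with the few-percent wall uncertainty
        errs = []
        for seed in range(5):
            noise = NoiseModel(layer_fluctuation_frac=0.0, velocity_sd=0.0, seed=seed)
            stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, noise)
            bounds = locate_channel_walls(stack, 1e-9)
            errs.append(abs(bounds.width - body_temp_solution.geometry.w)
                        / body_temp_solution.geometry.w)
        assert max(errs) < 0.05


class TestWallShearFromStack:
    def test_exact_on_linear_profile(self):
        # Newtonian near-wall layer: u = gamma0 * (z_top - z)
        gamma0, z_top = 0.5, 1e-3
        z = np.arange(0, z_top + 33e-6, 33e-6)
        y = np.arange(10) * 37e-6
        u = np.clip(gamma0 * (z_top - z), 0, None)[:, None] * np.ones(y.size)
        u[0, :] = 0.0
        stack = VelocityStack(z=z, y=y, u=u, delta_z=33e-6, delta_y=37e-6)
        bounds = ChannelBoundsEstimate(z_bottom=0.0, z_top=z_top, y_left=0.0, y_right=y[-1])
        mu = 9.3e-4
        fluid = PowerLawFluid(K=mu, n=1.0)
        for order in (1, 2):
            m = wall_shear_from_stack(stack, bounds, fluid, order=order)
            assert m.tau_max == pytest.approx(mu * gamma0, rel=1e-9)

    def test_noiseless_recovery_within_discretisation_bound(self, body_temp_solution):
        stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, QUIET)
        bounds = locate_channel_walls(stack, 1e-9)
        m = wall_shear_from_stack(stack, bounds, body_temp_solution.fluid)
        tau_true = wall_shear_map(body_temp_solution, "top").tau_max
        assert abs(m.tau_max - tau_true) / tau_true < 0.15

    def test_recovery_improves_under_layer_refinement(self, body_temp_solution):
        tau_true = wall_shear_map(body_temp_solution, "top").tau_max
        errs = []
        for dz in (33e-6, 16.5e-6, 8.25e-6):
            stack = generate_velocity_stack(body_temp_solution, dz, 37e-6, QUIET)
            bounds = locate_channel_walls(stack, 1e-9)
            m = wall_shear_from_stack(stack, bounds, body_temp_solution.fluid)
            errs.append(abs(m.tau_max - tau_true) / tau_true)
        assert errs[0] > errs[1] > errs[2]

    def test_noisy_recovery_within_measurement_envelope(self, body_temp_solution):
        # full noise model: recovered tau_max within the ~25% measurement
        # error envelope in at least 90% of seeds
        tau_true = wall_shear_map(body_temp_solution, "top").tau_max
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            stack = generate_velocity_stack(
                body_temp_solution, 33e-6, 37e-6, NoiseModel(seed=seed)
            )
            bounds = locate_channel_walls(stack, 2e-6)
            m = wall_shear_from_stack(stack, bounds, body_temp_solution.fluid)
            ok += abs(m.tau_max - tau_true) / tau_true <= 0.25
        assert ok >= 0.9 * n_seeds

    def test_invariant_under_extra_quiet_layers(self, body_temp_solution):
        m = {}
        for guards in (1, 3):
            stack = generate_velocity_stack(
                body_temp_solution, 33e-6, 37e-6, QUIET, guard_layers=guards
            )
            bounds = locate_channel_walls(stack, 1e-9)
            m[guards] = wall_shear_from_stack(stack, bounds, body_temp_solution.fluid).tau_max
        assert m[1] == pytest.approx(m[3], rel=1e-12)

    def test_needs_two_interior_layers(self):
        z = np.array([0.0, 5e-4, 1e-3])
        y = np.arange(5) * 37e-6
        u = np.ones((3, 5)) * 1e-5
        stack = VelocityStack(z=z, y=y, u=u, delta_z=5e-4, delta_y=37e-6)
        bounds = ChannelBoundsEstimate(z_bottom=6e-4, z_top=1.05e-3, y_left=0, y_right=y[-1])
        with pytest.raises(InsufficientDataError):
            wall_shear_from_stack(stack, bounds, PowerLawFluid(K=1e-3, n=1.0))


class TestCompareProfiles:
    def test_self_comparison_noiseless(self, body_temp_solution):
        stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, QUIET)
        bounds = locate_channel_walls(stack, 1e-9)
        # stack coordinates already sit in the solution frame
        reports = compare_profiles(stack, body_temp_solution)
        for rep in reports:
            assert rep["max_rel_dev"] < 1e-3
            assert rep["within_band"]

    def test_layer_fluctuations_stay_inside_band(self, body_temp_solution):
        noise = NoiseModel(velocity_sd=0.0, width_jitter_frac=0.0, seed=3)
        stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, noise)
        reports = compare_profiles(stack, body_temp_solution)
        for rep in reports:
            assert 0.001 < rep["max_rel_dev"] <= 0.10
            assert rep["within_band"]

    def test_mismatched_fluid_flagged_at_centreline(self, lit_solution, plug_solution):
        # a Newtonian measured stack against a strongly shear-thinning model:
        # the plug-flow flattening shows up as an out-of-band centreline deviation
        stack = generate_velocity_stack(lit_solution, 33e-6, 37e-6, QUIET)
        reports = compare_profiles(stack, plug_solution, y_fractions=(0.5,))
        assert not reports[0]["within_band"]
        assert reports[0]["max_rel_dev"] > 0.15

    def test_disjoint_domains_rejected(self, body_temp_solution):
        stack = generate_velocity_stack(body_temp_solution, 33e-6, 37e-6, QUIET)
        shifted = VelocityStack(
            z=stack.z + 1.0,
            y=stack.y,
            u=stack.u,
            delta_z=stack.delta_z,
            delta_y=stack.delta_y,
        )
        with pytest.raises(InvalidModelError):
            compare_profiles(shifted, body_temp_solution)


class TestStackIO:
    def test_round_trip_bit_exact(self, tmp_path, body_temp_solution):
        stack = generate_velocity_stack(
            body_temp_solution, 33e-6, 37e-6, NoiseModel(seed=7)
        )
        p1 = tmp_path / "stack.csv"
        p2 = tmp_path / "stack2.csv"
        write_stack(stack, p1)
        back = read_stack(p1)
        write_stack(back, p2)
        assert p1.read_text() == p2.read_text()
        assert back.metadata["seed"] == "7"
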