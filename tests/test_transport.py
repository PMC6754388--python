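"""Kinetics, FTCS solver, scenarios, calibration, and sensitivity."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erfc

import oxymat as om
from oxymat.transport import (ConfigurationError, ModelState,
                              interface_slope_from_arrays, stability_number)


class TestParProfile:
    def test_surface_value(self, kinetics):
        par = om.compute_par_profile(kinetics, om.Grid1D())
        assert par.values[0] == pytest.approx(1500.0)

    def test_geometric_attenuation_at_node_100(self, kinetics):
        # 1% loss per 0.071 mm step: node 100 sits exactly 100 steps down
        par = om.compute_par_profile(kinetics, om.Grid1D(0.071, 282))
        assert par.values[100] == pytest.approx(1500.0 * 0.99**100, rel=1e-9)
        assert par.values[100] == pytest.approx(549.04, abs=0.01)

    def test_zero_attenuation_gives_constant_profile(self, kinetics):
        kin = replace(kinetics, par_attenuation_fraction=0.0)
        par = om.compute_par_profile(kin, om.Grid1D(0.1, 50))
        assert np.all(par.values == 1500.0)

    def test_non_commensurate_spacing_is_continuous(self, kinetics):
        # spacing not a multiple of the 0.071 mm rule: continuous exponent
        par = om.compute_par_profile(kinetics, om.Grid1D(0.1, 10))
        expected = 1500.0 * 0.99 ** (0.1 / 0.071)
        assert par.values[1] == pytest.approx(expected, rel=1e-12)
        assert np.all(np.diff(par.values) <= 0)


class TestMichaelisMentenRates:
    def test_production_anchors(self, kinetics):
        assert om.production_rate(0.0, kinetics) == 0.0
        assert om.production_rate(1000.0, kinetics) == pytest.approx(1.05)
        assert om.production_rate(1500.0, kinetics) == pytest.approx(1.26)

    def test_respiration_anchors(self, kinetics):
        assert om.respiration_rate(0.0, kinetics) == 0.0
        assert om.respiration_rate(250.0, kinetics) == pytest.approx(0.875)
        assert om.respiration_rate(1000.0, kinetics) == pytest.approx(1.4)

    @pytest.mark.parametrize("fn", [om.production_rate, om.respiration_rate])
    def test_negative_input_rejected(self, fn, kinetics):
        with pytest.raises(ValueError):
            fn(-1.0, kinetics)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0.0, 1e6), y=st.floats(0.0, 1e6))
    def test_rates_monotone_and_bounded(self, kinetics, x, y):
        lo, hi = sorted([x, y])
        for fn, vmax in [(om.production_rate, kinetics.vmax_prod),
                         (om.respiration_rate, kinetics.vmax_resp)]:
            assert 0.0 <= fn(lo, kinetics) <= fn(hi, kinetics) < vmax


class TestParameterValidation:
    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ConfigurationError):
            om.KineticParameters(vmax_prod=-1.0)

    def test_attenuation_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            om.KineticParameters(par_attenuation_fraction=1.0)

    def test_porosity_bounds(self):
        with pytest.raises(ConfigurationError):
            om.TransportParameters(porosity=0.0)

    def test_grid_needs_three_nodes(self):
        with pytest.raises(ConfigurationError):
            om.Grid1D(0.1, 2)


class TestStabilityGuard:
    def test_default_configuration_accepted(self, transport_params):
        s = stability_number(transport_params, om.Grid1D(), 1.0)
        assert s == pytest.approx(0.198, abs=0.001)

    def test_violation_rejected_with_number_named(self, transport_params):
        grid = om.Grid1D(0.071, 100)
        state = ModelState(np.full(100, 230.0), step_size=10.0)  # s = 1.98
        with pytest.raises(ConfigurationError, match="1.98"):
            om.advance_one_step(state, om.KineticParameters(),
                                transport_params, grid,
                                om.BoundaryConditions())


class TestSingleStep:
    def test_uniform_field_zero_kinetics_unchanged(self, transport_params):
        kin = om.KineticParameters(vmax_prod=0.0, vmax_resp=0.0)
        grid = om.Grid1D(0.5, 21)
        state = ModelState(np.full(21, 230.0), step_size=10.0)
        bc = om.BoundaryConditions(top=230.0, bottom=230.0)
        new = om.advance_one_step(state, kin, transport_params, grid, bc)
        assert np.allclose(new.o2, 230.0)
        assert new.time == 10.0

    def test_linear_profile_zero_kinetics_interior_unchanged(
            self, transport_params):
        # second difference of a linear field vanishes
        kin = om.KineticParameters(vmax_prod=0.0, vmax_resp=0.0)
        grid = om.Grid1D(0.5, 21)
        field = 230.0 - 5.0 * grid.depths_mm
        state = ModelState(field.copy(), step_size=10.0)
        bc = om.BoundaryConditions(top=230.0, bottom=float(field[-1]))
        new = om.advance_one_step(state, kin, transport_params, grid, bc)
        assert np.allclose(new.o2[1:-1], field[1:-1], atol=1e-12)


class TestSteadyState:
    def test_zero_kinetics_equilibrium(self, transport_params):
        kin = om.KineticParameters(vmax_prod=0.0, vmax_resp=0.0)
        grid = om.Grid1D(0.5, 21)
        bc = om.BoundaryConditions(top=230.0, bottom=230.0)
        res = om.run_to_steady_state(
            ModelState(np.full(21, 230.0), step_size=10.0), kin,
            transport_params, grid, bc)
        assert res.converged
        assert np.allclose(res.final_state.o2, 230.0)
        assert res.efflux_top == pytest.approx(0.0, abs=1e-9)

    def test_paper_fixed_mode_runs_exactly_1200_steps(
            self, kinetics, transport_params):
        grid = om.Grid1D()     # native 0.071 mm grid, 1-s steps
        res = om.run_to_steady_state(
            ModelState(np.full(grid.n_nodes, 230.0)), kinetics,
            transport_params, grid, om.BoundaryConditions(),
            mode="paper_fixed_1200")
        assert res.iterations == 1200

    def test_nonconvergence_is_flagged_not_silent(
            self, kinetics, transport_params, small_grid):
        res = om.run_to_steady_state(
            ModelState(np.full(small_grid.n_nodes, 230.0), step_size=20.0),
            kinetics, transport_params, small_grid, om.BoundaryConditions(),
            max_iterations=5)
        assert not res.converged
        assert res.iterations == 5

    def test_production_only_efflux_equals_integrated_production(
            self, transport_params, small_grid):
        # single sink (top boundary): everything produced must exit the top
        kin = om.KineticParameters(vmax_resp=0.0)
        res = om.simulate_scenario(kin, transport_params, small_grid,
                                   "oxic_day", dt=20.0, tolerance=1e-5)
        prod_si = res.prod_profile * 1e-6
        integral = transport_params.porosity * np.trapezoid(
            prod_si, small_grid.depths_mm * 1e-3) * 1e3 * 86400
        assert res.flux_bottom == 0.0
        assert res.efflux_top == pytest.approx(integral, rel=0.005)

    def test_conservation_with_respiration(self, oxic_result, small_grid,
                                           transport_params):
        # independent trapezoidal integral of the returned rate profiles
        net_si = (oxic_result.prod_profile - oxic_result.resp_profile) * 1e-6
        integral = transport_params.porosity * np.trapezoid(
            net_si, small_grid.depths_mm * 1e-3) * 1e3 * 86400
        total_out = oxic_result.efflux_top + oxic_result.flux_bottom
        assert total_out == pytest.approx(integral, rel=0.005)

    def test_grid_refinement_changes_efflux_under_2pct(
            self, kinetics, transport_params):
        effluxes = []
        for dx, dt in [(0.4, 40.0), (0.2, 10.0)]:
            grid = om.Grid1D.from_depth(10.0, dx)
            res = om.simulate_scenario(kinetics, transport_params, grid,
                                       "oxic_day", dt=dt, tolerance=1e-5)
            effluxes.append(res.efflux_top)
        assert effluxes[1] == pytest.approx(effluxes[0], rel=0.02)


class TestDiffusionOracle:
    def test_step_initial_condition_matches_erfc_solution(
            self, transport_params):
        # pure diffusion into an initially O2-free mat, fixed top at 230 uM:
        # C(z, t) = C0 * erfc(z / (2 sqrt(D t))), semi-infinite domain
        kin = om.KineticParameters(vmax_prod=0.0, vmax_resp=0.0)
        grid = om.Grid1D.from_depth(20.0, 0.142)
        dt, t_end, c0 = 5.0, 600.0, 230.0
        state = ModelState(np.zeros(grid.n_nodes), step_size=dt)
        bc = om.BoundaryConditions(top=c0, bottom="no_flux")
        state.o2[0] = c0
        for _ in range(int(t_end / dt)):
            state = om.advance_one_step(state, kin, transport_params, grid, bc)
        z_m = grid.depths_mm * 1e-3
        analytic = c0 * erfc(z_m / (2 * np.sqrt(1e-9 * t_end)))
        assert np.max(np.abs(state.o2 - analytic)) < 0.01 * c0


class TestInterfaceSlope:
    def test_two_point_slope(self):
        s = interface_slope_from_arrays(np.array([0.0, 0.071]),
                                        np.array([230.0, 220.0]))
        assert s == pytest.approx(-140.845, abs=0.01)

    def test_uniform_profile_zero_slope(self):
        z = np.linspace(0, 5, 20)
        assert interface_slope_from_arrays(z, np.full(20, 100.0)) == \
            pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("window", [2, 3, 5, 10])
    def test_linear_segment_slope_window_independent(self, window):
        z = np.linspace(0, 5, 20)
        s = interface_slope_from_arrays(z, 230.0 - 12.5 * z, window=window)
        assert s == pytest.approx(-12.5, rel=1e-9)

    def test_window_exceeding_profile_rejected(self):
        with pytest.raises(ValueError):
            interface_slope_from_arrays(np.array([0.0, 1.0]),
                                        np.array([1.0, 2.0]), window=3)


class TestScenarios:
    def test_unknown_scenario_rejected(self, kinetics, transport_params,
                                       small_grid):
        with pytest.raises(ConfigurationError, match="scenario"):
            om.simulate_scenario(kinetics, transport_params, small_grid,
                                 "dusk")

    def test_night_without_oxygen_source_stays_zero(
            self, kinetics, transport_params, small_grid):
        res = om.simulate_scenario(kinetics, transport_params, small_grid,
                                   "night", top_oxic_um=0.0, initial_um=0.0,
                                   dt=20.0)
        assert np.allclose(res.final_state.o2, 0.0)
        assert res.efflux_top == pytest.approx(0.0, abs=1e-9)

    def test_anoxic_atmosphere_raises_efflux(self, kinetics, transport_params,
                                             small_grid, oxic_result):
        anoxic = om.simulate_scenario(kinetics, transport_params, small_grid,
                                      "anoxic_day", dt=20.0)
        assert anoxic.efflux_top >= oxic_result.efflux_top

    def test_efflux_nonincreasing_in_top_boundary(
            self, kinetics, transport_params, small_grid):
        effluxes = [om.simulate_scenario(kinetics, transport_params,
                                         small_grid, "oxic_day",
                                         top_oxic_um=c, dt=20.0).efflux_top
                    for c in (0.0, 115.0, 230.0)]
        assert effluxes[0] >= effluxes[1] >= effluxes[2]

    def test_net_producer_exports_oxygen_through_top(
            self, transport_params, small_grid):
        # strong production: O2 peaks inside the mat, falls toward the air
        kin = om.KineticParameters(vmax_prod=4.0, vmax_resp=0.5)
        res = om.simulate_scenario(kin, transport_params, small_grid,
                                   "oxic_day", dt=20.0)
        assert res.areal_net_production > 0
        assert res.interface_slope > 0  # O2 rises with depth at the top
        assert res.efflux_top > 0


class TestCalibration:
    def test_noiseless_round_trip_recovers_truth(
            self, kinetics, transport_params, deep_grid):
        bc = om.BoundaryConditions(top=230.0)
        spec = om.SyntheticProfileSpec(kinetics, transport_params, deep_grid,
                                       bc, noise_sd=0.0, seed=0, dt=60.0,
                                       tolerance=1e-4)
        prof = om.gen_o2_profile(spec)
        start = replace(kinetics, vmax_prod=1.0, vmax_resp=1.0)
        fitted, diag = om.calibrate_vmax(prof, start, transport_params,
                                         deep_grid, bc, dt=60.0)
        assert fitted.vmax_prod == pytest.approx(2.1, rel=0.01)
        assert fitted.vmax_resp == pytest.approx(1.75, rel=0.01)
        assert diag["success"]

    def test_anoxic_zero_profile_drives_production_to_zero(
            self, kinetics, transport_params, small_grid):
        bc = om.BoundaryConditions(top=0.0)
        zeros = om.DepthProfile(small_grid.depths_mm,
                                np.zeros(small_grid.n_nodes))
        start = replace(kinetics, vmax_prod=1.0, vmax_resp=1.0)
        fitted, _ = om.calibrate_vmax(zeros, start, transport_params,
                                      small_grid, bc, dt=20.0, tolerance=1e-4)
        assert fitted.vmax_prod == pytest.approx(0.0, abs=0.02)

    def test_too_few_points_rejected(self, kinetics, transport_params,
                                     small_grid):
        p = om.DepthProfile([0.0, 1.0, 2.0], [230.0, 200.0, 180.0])
        with pytest.raises(ValueError, match="5"):
            om.calibrate_vmax(p, kinetics, transport_params, small_grid,
                              om.BoundaryConditions())


class TestSensitivity:
    def test_scan_reports_all_parameters_and_directions(
            self, kinetics, transport_params):
        grid = om.Grid1D.from_depth(6.0, 0.5)
        table = om.sensitivity_scan(kinetics, transport_params, grid,
                                    perturbation=0.1, dt=60.0,
                                    tolerance=1e-4)
        assert len(table) == 12  # 5 params x 2 directions + 2 PAR-decay levels
        assert not table["undefined_pct"].any()
        assert np.isfinite(table["pct_change"]).all()

    def test_linear_response_when_boundary_is_only_sink(
            self, transport_params):
        # no respiration, no-flux bottom: efflux is linear in vmax_prod
        grid = om.Grid1D.from_depth(6.0, 0.5)
        kin = om.KineticParameters(vmax_resp=0.0)
        base = om.simulate_scenario(kin, transport_params, grid, "oxic_day",
                                    dt=60.0, tolerance=1e-6)
        up = om.simulate_scenario(replace(kin, vmax_prod=2.1 * 1.1),
                                  transport_params, grid, "oxic_day",
                                  dt=60.0, tolerance=1e-6)
        assert up.efflux_top == pytest.approx(1.1 * base.efflux_top, rel=0.001)

    def test_zero_perturbation_rejected(self, kinetics, transport_params,
                                        small_grid):
        with pytest.raises(ValueError):
            om.sensitivity_scan(kinetics, transport_params, small_grid,
                                perturbation=0.0)
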