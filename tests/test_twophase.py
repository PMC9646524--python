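"""Tests for the two-phase confined-migration model and its solver."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from viscocell import twophase as tp


class TestAdhesionProfile:
    def test_quadratic_minimum_at_midcell(self):
        assert tp.adhesion_profile(0.5, 0.3, "quadratic") == pytest.approx(0.3)

    @pytest.mark.parametrize("x", [0.0, 1.0])
    @pytest.mark.parametrize("b", [0.1, 0.3, 0.9])
    def test_quadratic_endpoints_are_one(self, x, b):
        assert tp.adhesion_profile(x, b, "quadratic") == pytest.approx(1.0)

    def test_quartic_midpoint_value(self):
        assert tp.adhesion_profile(0.5, 0.25, "quartic") == pytest.approx(0.296875)

    def test_quartic_minimum_at_rear(self):
        x = np.linspace(0, 1, 101)
        prof = tp.adhesion_profile(x, 0.25, "quartic")
        assert prof[0] == pytest.approx(0.25)
        assert prof[-1] == pytest.approx(1.0)
        assert np.all(np.diff(prof) >= 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            tp.adhesion_profile(1.2, 0.3)


class TestChannelGeometry:
    def test_hydraulic_resistance_values(self):
        assert tp.hydraulic_resistance(0.0, 100.0, 3.5) == 0.0
        assert tp.hydraulic_resistance(1e-3, 200.0, 3.5) == pytest.approx(
            2.0 * tp.hydraulic_resistance(1e-3, 100.0, 3.5)
        )
        ratio = tp.hydraulic_resistance(8e-3, 75.0, 3.5) / tp.hydraulic_resistance(
            0.77e-3, 115.0, 3.5
        )
        assert ratio == pytest.approx((8 * 75) / (0.77 * 115), rel=1e-12)

    def test_hydraulic_resistance_rejects_bad_width(self):
        with pytest.raises(ValueError):
            tp.hydraulic_resistance(1e-3, 100.0, 0.0)

    @pytest.mark.parametrize(
        ("L0", "L", "expected"), [(200.0, 85.0, 115.0), (200.0, 125.0, 75.0), (50.0, 50.0, 0.0)]
    )
    def test_effective_channel_length(self, L0, L, expected):
        assert tp.effective_channel_length(L0, L) == expected

    def test_cell_longer_than_channel_rejected(self):
        with pytest.raises(ValueError):
            tp.effective_channel_length(100.0, 101.0)

    def test_cross_section(self):
        assert tp.channel_cross_section_area(3.5, 10.0) == pytest.approx(35.0)


class TestMembraneRelations:
    def test_water_flux_equilibrium_is_zero(self):
        # osmotic–hydraulic balance: Δp = RT Δc
        assert tp.water_flux(1e-4, 500.0, 0.0, 340.2, 340.0, 2500.0) == pytest.approx(0.0)

    def test_water_flux_impermeable_membrane(self):
        assert tp.water_flux(0.0, 1e4, 0.0, 400.0, 340.0, 2500.0) == 0.0

    def test_water_flux_hyperosmotic_interior_is_inward(self):
        assert tp.water_flux(1e-4, 0.0, 0.0, 350.0, 340.0, 2500.0) > 0

    def test_face_pressures_static_cell(self):
        assert tp.face_pressures(5.0, 2.0, 1.0, 1.0, 0.0, 0.0, 0.0) == (5.0, 2.0)

    def test_face_pressures_no_resistance(self):
        assert tp.face_pressures(5.0, 2.0, 0.0, 0.0, 0.1, 0.02, 0.02) == (5.0, 2.0)

    def test_face_pressures_resistance_opposes_motion(self):
        pf, pb = tp.face_pressures(0.0, 0.0, 1.0, 1.0, 0.1, 0.0, 0.0)
        assert pf > pb


class TestNetworkVelocity:
    def test_no_adhesion_uniform_network_moves_with_cytosol(self):
        assert tp.network_velocity(0.3, 0.0, 0.02, 300.0, 200.0, 0.0) == pytest.approx(0.02)

    def test_strong_anchoring_freezes_network(self):
        v = tp.network_velocity(0.3, 0.0, 0.02, 300.0, 200.0, 1e12)
        assert abs(v) < 1e-10

    def test_swelling_gradient_pushes_network_rearward(self):
        assert tp.network_velocity(0.3, 0.01, 0.0, 300.0, 200.0, 50.0) < 0

    def test_degenerate_theta_flagged(self):
        with pytest.warns(UserWarning, match="theta_n"):
            v = tp.network_velocity(0.0, 0.01, 0.02, 300.0, 200.0, 0.0)
        assert v == pytest.approx(0.02)


def test_polarized_ion_fluxes_ratio():
    for gamma in (1.67, 2.84, 1.0):
        jf, jb = tp.polarized_ion_fluxes(-8.0, gamma)
        assert abs(jf / jb) == pytest.approx(gamma)
        assert jf * jb < 0  # opposite transport directions


def test_knockdown_is_idempotent(core_params):
    once = tp.knockdown_nhe1(core_params)
    assert tp.knockdown_nhe1(once) == once
    assert once.J_active_b == 0.0 and once.J_active_f == 0.0


class TestSteadyState:
    def test_residuals_below_tolerance(self, lv_solution, hv_solution):
        for sol in (lv_solution, hv_solution):
            assert sol.residuals["actin_mass_rel"] < 1e-6
            assert sol.residuals["force_balance_rel"] < 1e-6
            assert sol.residuals["vc_variation_rel"] < 1e-8
            assert sol.residuals["max_bc_mismatch"] < 1e-8

    def test_fields_physical(self, hv_solution):
        assert np.all(hv_solution.theta_n >= 0)
        assert np.all(hv_solution.theta_c >= 0)
        assert np.all(hv_solution.c >= 0)

    def test_total_actin_content(self, lv_solution, core_params):
        total = np.trapezoid(
            lv_solution.theta_n + lv_solution.theta_c, lv_solution.grid
        )
        expected = tp.LV_REGIME.L_cell * core_params.theta_star
        assert total == pytest.approx(expected, rel=1e-3)

    def test_symmetric_configuration_is_still(self, core_params):
        """A fully symmetric cell cannot move: |v0| below solver tolerance."""
        sym = replace(
            core_params,
            J_active_f=core_params.J_active_b,
            J_actin_b0=core_params.J_actin_f0,
        )
        regime = replace(tp.LV_REGIME, name="custom", gamma_polar=1.0)
        sol = tp.solve_steady_state(sym, regime)
        assert abs(sol.v0) < 1e-8

    def test_elevated_viscosity_regime_is_faster(self, lv_solution, hv_solution):
        assert hv_solution.v0 > lv_solution.v0 > 0

    def test_factin_more_polarized_at_elevated_viscosity(self, lv_solution, hv_solution):
        assert (
            hv_solution.front_rear_theta_n_ratio
            > lv_solution.front_rear_theta_n_ratio
            > 1.0
        )

    def test_knockdown_slows_both_regimes_more_so_at_high_viscosity(
        self, lv_solution, hv_solution, knockdown_solutions
    ):
        drop_lv = 1.0 - knockdown_solutions["LV"].v0 / lv_solution.v0
        drop_hv = 1.0 - knockdown_solutions["HV"].v0 / hv_solution.v0
        assert knockdown_solutions["LV"].v0 < lv_solution.v0
        assert knockdown_solutions["HV"].v0 < hv_solution.v0
        assert drop_hv > drop_lv

    def test_grid_convergence(self, core_params, hv_solution):
        coarse = tp.solve_steady_state(core_params, tp.HV_REGIME, n_grid=101)
        assert abs(coarse.v0 - hv_solution.v0) / abs(hv_solution.v0) < 0.01

    def test_monotone_in_polarization_ratio(self, core_params):
        v0s = [
            tp.solve_steady_state(
                core_params, replace(tp.LV_REGIME, name="custom", gamma_polar=g)
            ).v0
            for g in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        assert all(a <= b for a, b in zip(v0s, v0s[1:]))

    def test_rejects_coarse_grid_request(self, core_params):
        with pytest.raises(ValueError):
            tp.solve_steady_state(core_params, tp.LV_REGIME, n_grid=10)


class TestViscositySweep:
    def test_single_value_matches_direct_solve(self, core_params, hv_solution):
        rows = tp.speed_vs_viscosity(core_params, tp.HV_REGIME, [8.0])
        assert rows[0]["converged"]
        assert rows[0]["v0_um_s"] == pytest.approx(hv_solution.v0, rel=1e-9)

    def test_row_per_viscosity_and_monotone(self, core_params):
        cps = [0.77, 2.0, 5.0, 8.0]
        rows = tp.speed_vs_viscosity(core_params, tp.HV_REGIME, cps)
        assert len(rows) == len(cps)
        v0s = [r["v0_um_s"] for r in rows]
        assert all(r["converged"] for r in rows)
        assert all(a <= b for a, b in zip(v0s, v0s[1:]))

    def test_rejects_nonpositive_viscosity(self, core_params):
        with pytest.raises(ValueError):
            tp.speed_vs_viscosity(core_params, tp.HV_REGIME, [0.0])
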