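"""Transport solver, supply surface, stress-onset limit and thresholds."""

import numpy as np
import pytest

from critsoil import (
    PlantTraits,
    build_supply_surface,
    conductance_partition,
    critical_thresholds,
    critical_vpd,
    fit_root_length,
    solve_transport,
    stress_onset_limit,
    water_retention,
)
from critsoil.constants import mpa_to_head
from critsoil.supply import (
    PlantLimitedAtSaturationError,
    _psi_leaf_closed,
    _psi_leaf_implicit,
    _psi_root_for_T,
    _sol_from_trajectory,
    soil_supply,
    supply_trajectory,
)


class TestSolveTransport:
    def test_hydrostatic_no_flow(self, table, traits):
        st = solve_transport(table.get("loam"), traits, -0.3, -0.3)
        assert st.T == 0.0
        assert st.psi_leaf == pytest.approx(-0.3)

    def test_wet_soil_leaf_potential_at_t_pot(self, table, traits):
        # transpiring at T_pot with the default conductance anchoring pulls
        # the leaf to psi_leaf_max = -1 MPa in wet soil
        soil = table.get("loam")
        pr = float(_psi_root_for_T(soil, traits, -1e-6, 4.0))
        st = solve_transport(soil, traits, -1e-6, pr)
        assert st.T == pytest.approx(4.0, rel=1e-9)
        assert st.psi_leaf == pytest.approx(-1.0, abs=0.01)

    def test_doubling_root_length_halves_soil_potential_drop(self, table, traits):
        from dataclasses import replace

        from critsoil.soil import matric_flux_potential

        soil = table.get("sandy loam")
        for psi_soil in (-0.05, -0.2):
            drops = []
            for fac in (1.0, 2.0):
                # fixed radial geometry: the Phi balance is linear in 1/L_root
                tr = replace(traits, L_root=traits.L_root * fac)
                pr = float(_psi_root_for_T(soil, tr, psi_soil, 0.5))
                phi_s = matric_flux_potential(soil, mpa_to_head(psi_soil))
                phi_r = matric_flux_potential(soil, mpa_to_head(pr))
                drops.append(phi_s - phi_r)
            assert drops[0] == pytest.approx(2.0 * drops[1], rel=1e-9)

    def test_precondition_violations(self, table, traits):
        with pytest.raises(ValueError):
            solve_transport(table.get("loam"), traits, -0.5, -0.1)

    def test_closed_form_matches_bracketed_solver(self, traits):
        rng = np.random.default_rng(7)
        for _ in range(100):
            psi_root = float(rng.uniform(-3.5, -0.01))
            t_max = traits.K_plant_max * 5.0
            T = float(rng.uniform(0.0, t_max))
            closed = float(_psi_leaf_closed(traits, psi_root, T))
            scalar = _psi_leaf_implicit(traits, psi_root, T)
            # both satisfy the implicit equation; compare on the same branch
            if closed > psi_root - T / (traits.k_floor_frac * traits.K_plant_max) + 1e-9:
                assert closed == pytest.approx(scalar, abs=1e-8)


class TestSupplySurface:
    def test_wet_node_planar_within_one_percent(self, table, traits):
        surf = build_supply_surface(
            table.get("loam"), traits, np.linspace(-1e-4, -10, 120), n_trajectory=1500
        )
        T, pl, _ = surf.trajectories[0]
        m = T <= surf.T_pot
        A = np.column_stack([pl[m], np.ones(m.sum())])
        coef, *_ = np.linalg.lstsq(A, T[m], rcond=None)
        assert np.max(np.abs(A @ coef - T[m])) < 0.01 * surf.T_pot

    def test_dry_node_saturates(self, table, traits):
        T, pl, _ = supply_trajectory(table.get("sand"), traits, -4.0, n=3000)
        deriv = np.abs(np.diff(T) / np.diff(pl))
        assert deriv[-1] < 0.01 * np.nanmax(deriv)

    def test_deterministic(self, table, traits):
        grid = np.linspace(-1e-3, -5, 110)
        a = build_supply_surface(table.get("clay"), traits, grid)
        b = build_supply_surface(table.get("clay"), traits, grid)
        assert np.array_equal(a.sol_T, b.sol_T)

    def test_grid_density_enforced(self, table, traits):
        with pytest.raises(ValueError):
            build_supply_surface(table.get("clay"), traits, np.linspace(-1e-3, -5, 20))

    def test_monotone_along_drying(self, table, traits):
        surf = build_supply_surface(
            table.get("sandy loam"), traits, -np.logspace(-4, 1, 150)
        )
        # non-increasing up to deep-dry numerical jitter (T_sol ~ 1e-3 mm/d)
        assert np.all(np.diff(surf.sol_T) <= 0.01)
        sol = stress_onset_limit(surf)
        assert sol.shape == (150, 3)


class TestStressOnsetLimit:
    def test_linear_trajectory_sol_at_end(self):
        T = np.linspace(0, 5, 100)
        psi = -T / 4.0
        t_sol, _ = _sol_from_trajectory(T, psi)
        assert t_sol == T[-1]

    @pytest.mark.parametrize("cls", ["sand", "loam", "clay"])
    @pytest.mark.parametrize("psi_soil", [-0.05, -0.5, -2.0])
    def test_matches_denser_brute_force_scan(self, table, traits, cls, psi_soil):
        soil = table.get(cls)
        coarse = _sol_from_trajectory(*supply_trajectory(soil, traits, psi_soil, n=800)[:2])
        dense = _sol_from_trajectory(*supply_trajectory(soil, traits, psi_soil, n=8000)[:2])
        assert coarse[0] == pytest.approx(dense[0], abs=0.05)

    def test_texture_contrast_at_moderate_drying(self, table, traits):
        # steep conductivity loss limits the loamy sand long before the clay
        sols = {}
        for cls in ("loamy sand", "clay"):
            T, pl, _ = supply_trajectory(table.get(cls), traits, -0.1)
            sols[cls] = _sol_from_trajectory(T, pl)[0]
        assert sols["loamy sand"] < sols["clay"]


class TestCriticalThresholds:
    def test_theta_psi_consistency_through_retention(self, table, traits, fast_kwargs):
        est = critical_thresholds(table.get("sandy loam"), traits, **fast_kwargs)
        theta = water_retention(table.get("sandy loam"), mpa_to_head(est.psi_crit))
        assert est.theta_crit == pytest.approx(theta, abs=1e-6)
        assert est.psi_crit < 0
        assert 0 < est.theta_crit < table.get("sandy loam").theta_s

    def test_thresholds_between_field_capacity_and_plant_bound(
        self, table, traits, fast_kwargs
    ):
        plant_bound = traits.psi_onset + 4.0 / traits.K_plant_max
        for p in table:
            est = critical_thresholds(p, traits, **fast_kwargs)
            assert plant_bound - 0.05 < est.psi_crit < -0.004

    def test_drier_threshold_for_smaller_demand(self, table, traits, fast_kwargs):
        soil = table.get("loam")
        psis = [
            critical_thresholds(soil, traits, T_pot=tp, **fast_kwargs).psi_crit
            for tp in (4.0, 1.0, 0.25)
        ]
        assert psis[0] > psis[1] > psis[2]

    def test_plant_limited_at_saturation_reports_critical_vpd(self, table):
        # a plant that loses conductance early cannot meet T_pot even in
        # saturated soil: onset at -0.9 MPa caps the SOL at 3.6 mm/d
        weak = PlantTraits(psi_x_star=-1.3)
        with pytest.raises(PlantLimitedAtSaturationError) as exc:
            critical_thresholds(table.get("loam"), weak, n_psi=120, n_trajectory=500)
        assert exc.value.critical_vpd_kpa == pytest.approx(1.5 * 3.6 / 4.0, rel=0.05)


class TestConductancePartition:
    def test_harmonic_identity(self, table, traits):
        rng = np.random.default_rng(11)
        soil = table.get("loam")
        for _ in range(100):
            psi_soil = float(rng.uniform(-0.5, -0.001))
            T = float(rng.uniform(0.1, 3.0))
            k_soil, k_plant, k_total = conductance_partition(soil, traits, psi_soil, T)
            assert 1.0 / k_total == pytest.approx(
                1.0 / k_soil + 1.0 / k_plant, rel=1e-10
            )

    def test_wet_soil_dominance(self, table, traits):
        k_soil, k_plant, _ = conductance_partition(table.get("sand"), traits, -0.001, 4.0)
        assert k_soil / k_plant > 100.0

    def test_soil_still_conducts_at_threshold(self, table, traits, fast_kwargs):
        soil = table.get("loamy sand")
        est = critical_thresholds(soil, traits, **fast_kwargs)
        k_soil, k_plant, _ = conductance_partition(soil, traits, est.psi_crit, 4.0)
        assert k_soil > k_plant

    def test_zero_flow_undefined(self, table, traits):
        with pytest.raises(ValueError):
            conductance_partition(table.get("loam"), traits, -0.1, 0.0)


class TestCriticalVPD:
    def test_anchor_consistency(self, table, traits, fast_kwargs):
        soil = table.get("sandy loam")
        est = critical_thresholds(soil, traits, **fast_kwargs)
        vpd, capped = critical_vpd(soil, traits, est.theta_crit)
        assert not capped
        assert vpd == pytest.approx(1.5, abs=0.05)

    def test_monotone_in_theta(self, table, traits):
        soil = table.get("sandy loam")
        thetas = np.linspace(0.08, soil.theta_s * 0.999, 12)
        vpds = [critical_vpd(soil, traits, t, n_trajectory=1000)[0] for t in thetas]
        assert all(b >= a - 1e-6 for a, b in zip(vpds, vpds[1:]))

    def test_dry_soil_low_critical_vpd(self, table, traits):
        vpd, _ = critical_vpd(table.get("sandy loam"), traits, 0.06)
        assert vpd < 0.5


class TestFitRootLength:
    def test_noiseless_self_consistency(self, table, traits):
        soils = [table.get(c) for c in ("sand", "loam", "clay loam", "clay")]
        obs = [
            (critical_thresholds(s, traits, n_psi=200, n_trajectory=800), s)
            for s in soils
        ]
        L, diag = fit_root_length(obs, traits, n_coarse=12)
        assert L == pytest.approx(traits.L_root, rel=0.02)
        assert diag["objective"] < 0.01

    def test_single_observation_interpolates(self, table, traits):
        soil = table.get("loam")
        est = critical_thresholds(soil, traits, n_psi=200, n_trajectory=800)
        L, diag = fit_root_length([(est, soil)], traits, n_coarse=12)
        assert diag["objective"] < 1e-3

    def test_empty_observations_rejected(self, traits):
        with pytest.raises(ValueError):
            fit_root_length([], traits)
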