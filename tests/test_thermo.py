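"""Hydration-shell thermodynamics: chemical potentials, roots, fits."""

import numpy as np
import pytest

from silksol.constants import T_ZERO_C
from silksol.salt_activity import KCL_TABLE, NACL_TABLE, activity_from_salt
from silksol.synthetic import gen_cloud_points
from silksol.thermo import (
    FITTED_SHELL,
    ICE_CURVE,
    WATER_CURVE,
    CloudPointDatum,
    HydrationShellParams,
    QuadraticMuCurve,
    delta_thermo,
    enthalpy_penalty_at_gelation,
    fit_hydration_model,
    fit_quadratic_mu,
    gelation_temperature_freezing,
    gelation_temperature_heating,
    hbond_displacement_enthalpy,
    mu_hydration,
    mu_ice,
    mu_solution,
    mu_water,
    reference_mu_table,
)


def grid_scan_root(fn, lo, hi, step=0.01):
    """Independent oracle: finest sign change on a fixed grid."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.array([fn(t) for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = sign_change[0]
    # linear interpolation inside the bracketing step
    f0, f1 = vals[i], vals[i + 1]
    return float(grid[i] + step * f0 / (f0 - f1))


class TestMuCurves:
    def test_constant_terms(self):
        assert mu_ice(0.0) == pytest.approx(10.286)
        assert mu_water(0.0) == pytest.approx(8.038)

    def test_quadratic_evaluations(self):
        assert mu_water(25.0) == pytest.approx(-84.50, abs=0.01)
        assert mu_ice(-6.0) == pytest.approx(-125.41, abs=0.01)

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            mu_water(150.0)


class TestMuSolution:
    def test_unit_activity_is_pure_water(self):
        for t in (-5.0, 0.0, 25.0, 60.0):
            assert mu_solution(t, 1.0) == mu_water(t)

    def test_reduced_activity(self):
        # -84.50 + R * 298.15 * ln 0.9
        assert mu_solution(25.0, 0.9) == pytest.approx(-345.7, abs=0.1)

    def test_monotone_in_activity(self):
        acts = np.linspace(0.5, 1.0, 20)
        mus = [mu_solution(25.0, a) for a in acts]
        assert np.all(np.diff(mus) > 0)

    def test_rejects_nonpositive_activity(self):
        with pytest.raises(ValueError):
            mu_solution(25.0, 0.0)


class TestMuHydration:
    def test_reference_temperature_value(self):
        # dH0 - T0 dS0 at T = 0 degC
        assert mu_hydration(0.0, FITTED_SHELL) == pytest.approx(-124.33, abs=0.01)

    def test_subzero_value(self):
        assert mu_hydration(-6.0, FITTED_SHELL) == pytest.approx(-126.97, abs=0.05)

    def test_zero_cp_is_linear_in_kelvin(self):
        p = HydrationShellParams(-100.0, -0.5, 1e-9)
        temps = np.linspace(-10.0, 40.0, 6)
        mus = mu_hydration(temps, p)
        assert np.allclose(np.diff(mus, 2), 0.0, atol=1e-6)

    def test_heat_capacity_consistency(self):
        # dH_hyd/dT must equal cp_shell (shell enthalpy is linear in T)
        p = FITTED_SHELL

        def enthalpy(t_c):
            t_k = t_c + T_ZERO_C
            s = p.dS0 + p.cp_shell * np.log(t_k / p.T0)
            return mu_hydration(t_c, p) + t_k * s

        h = 0.5
        for t in (-10.0, 0.0, 25.0, 60.0):
            deriv = (enthalpy(t + h) - enthalpy(t - h)) / (2 * h)
            assert deriv == pytest.approx(p.cp_shell, rel=1e-9)

    def test_continuity_and_smoothness(self):
        t = np.linspace(-29.0, 99.0, 2000)
        mu = mu_hydration(t, FITTED_SHELL)
        assert np.all(np.isfinite(mu))
        assert np.max(np.abs(np.diff(mu, 2))) < 0.1  # no kinks at this scale


class TestFitQuadraticMu:
    def test_exact_quadratic_recovery(self):
        truth = QuadraticMuCurve(3.0, -1.5, 0.02)
        data = [(t, truth(t)) for t in np.linspace(-10, 60, 12)]
        fit = fit_quadratic_mu(data)
        assert fit.c0 == pytest.approx(3.0, abs=1e-9)
        assert fit.c1 == pytest.approx(-1.5, abs=1e-10)
        assert fit.c2 == pytest.approx(0.02, abs=1e-11)

    def test_reference_water_table_matches_printed_curve(self):
        fit = fit_quadratic_mu(reference_mu_table("water", 0.0, 70.0), "water")
        assert fit.c2 == pytest.approx(WATER_CURVE.c2, rel=0.10)
        t = np.linspace(0.0, 70.0, 50)
        assert np.max(np.abs(fit(t) - WATER_CURVE(t))) <= 25.0  # J/mol

    def test_reference_ice_table_matches_printed_curve(self):
        fit = fit_quadratic_mu(reference_mu_table("ice", -25.0, 0.0, 2.5), "ice")
        assert fit.c1 == pytest.approx(ICE_CURVE.c1, rel=0.02)
        assert fit.c2 == pytest.approx(ICE_CURVE.c2, rel=0.10)
        t = np.linspace(-25.0, 0.0, 50)
        assert np.max(np.abs(fit(t) - ICE_CURVE(t))) <= 25.0  # J/mol

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_quadratic_mu([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestDeltaThermo:
    def test_gibbs_energy_at_reference(self):
        assert delta_thermo(0.0, FITTED_SHELL).dG == pytest.approx(-124.33, abs=0.01)

    def test_enthalpy_entropy_compensation(self):
        # dH and T dS both negative and nearly parallel over 10-60 degC
        temps = np.linspace(10.0, 60.0, 11)
        dh = np.array([delta_thermo(t, FITTED_SHELL).dH for t in temps])
        tds = np.array([delta_thermo(t, FITTED_SHELL).TdS for t in temps])
        assert np.all(dh < 0) and np.all(tds < 0)
        gap = dh - tds
        assert np.max(np.abs(gap)) < 0.15 * np.max(np.abs(dh))

    def test_zero_delta_cp_linear(self):
        p = HydrationShellParams(-100.0, -0.5, 75.7, cp_water_ref=75.7)
        temps = np.array([0.0, 20.0, 40.0, 60.0])
        dg = np.array([delta_thermo(t, p).dG for t in temps])
        assert np.allclose(np.diff(dg, 2), 0.0, atol=1e-9)


class TestGelationRoots:
    def test_heating_root_matches_published_model(self):
        root = gelation_temperature_heating(FITTED_SHELL)
        assert root == pytest.approx(67.6, abs=0.05)

    def test_heating_root_vs_grid_scan_oracle(self):
        oracle = grid_scan_root(
            lambda t: delta_thermo(t, FITTED_SHELL).dG, 0.0, 100.0
        )
        assert gelation_temperature_heating(FITTED_SHELL) == pytest.approx(
            oracle, abs=0.02
        )

    def test_always_stable_parameters_have_no_root(self):
        p = HydrationShellParams(-100.0, 0.1, 75.7, cp_water_ref=75.7)  # dCp = 0
        assert gelation_temperature_heating(p) is None

    def test_freezing_root_matches_published_model(self):
        root = gelation_temperature_freezing(FITTED_SHELL)
        assert root == pytest.approx(-6.07, abs=0.05)

    def test_freezing_root_vs_grid_scan_oracle(self):
        oracle = grid_scan_root(
            lambda t: mu_hydration(t, FITTED_SHELL) - ICE_CURVE(t), -25.0, 0.0
        )
        assert gelation_temperature_freezing(FITTED_SHELL) == pytest.approx(
            oracle, abs=0.02
        )

    def test_no_ice_crossing_when_curve_shifted(self):
        low_ice = QuadraticMuCurve(-5000.0, ICE_CURVE.c1, ICE_CURVE.c2, "ice")
        assert gelation_temperature_freezing(FITTED_SHELL, ice=low_ice) is None

    def test_root_decreases_with_delta_cp(self):
        # a larger heat-capacity deficit destabilises the shell earlier
        roots = []
        for dcp in (10.0, 14.0, 17.8, 22.0, 26.0):
            p = HydrationShellParams(-69.7, 0.2, 57.9, cp_water_ref=57.9 + dcp)
            roots.append(gelation_temperature_heating(p))
        assert all(a > b for a, b in zip(roots, roots[1:]))


class TestEnthalpyPenalty:
    def test_value_at_gelation(self):
        assert enthalpy_penalty_at_gelation(FITTED_SHELL) == pytest.approx(1.27, abs=0.01)

    def test_definition_of_root(self):
        t_star = gelation_temperature_heating(FITTED_SHELL)
        d = delta_thermo(t_star, FITTED_SHELL)
        assert d.dH == pytest.approx(d.TdS, rel=1e-6)

    def test_propagates_missing_root(self):
        p = HydrationShellParams(-100.0, 0.1, 75.7, cp_water_ref=75.7)
        with pytest.raises(ValueError):
            enthalpy_penalty_at_gelation(p)


class TestSaltActivity:
    def test_zero_concentration(self):
        assert activity_from_salt("NaCl", 0.0) == 1.0

    def test_linear_interpolation_midpoint(self):
        m = NACL_TABLE.molality
        a = NACL_TABLE.water_activity
        mid = (m[3] + m[4]) / 2.0
        assert activity_from_salt("NaCl", mid) == pytest.approx((a[3] + a[4]) / 2.0)

    def test_saturated_nacl_activity(self):
        # ~75 % relative humidity over concentrated brine
        assert activity_from_salt("NaCl", 6.0) == pytest.approx(0.76, abs=0.01)

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError):
            activity_from_salt("KCl", 10.0)

    def test_unknown_salt(self):
        with pytest.raises(ValueError):
            activity_from_salt("CaCl2", 1.0)

    def test_mass_fraction_conversion(self):
        # 5.85 % w/w NaCl ~ 1.063 mol/kg
        m = NACL_TABLE.molality_from_mass_fraction(5.85, 58.44)
        assert m == pytest.approx(1.063, abs=0.01)


class TestFitHydrationModel:
    def test_noiseless_exact_recovery(self):
        data, _ = gen_cloud_points(temp_noise_sd=0.0, seed=0)
        report = fit_hydration_model(
            data, init=HydrationShellParams(-50.0, 0.5, 50.0)
        )
        assert report.converged
        assert report.params.dH0 == pytest.approx(FITTED_SHELL.dH0, rel=1e-4)
        assert report.params.dS0 == pytest.approx(FITTED_SHELL.dS0, rel=1e-4)
        assert report.params.cp_shell == pytest.approx(FITTED_SHELL.cp_shell, rel=1e-4)

    def test_fixed_cp_mode(self):
        data, _ = gen_cloud_points(temp_noise_sd=0.0, seed=0)
        report = fit_hydration_model(
            data, init=HydrationShellParams(-50.0, 0.5, 57.9), fit_cp=False
        )
        assert report.params.cp_shell == 57.9
        assert report.params.dH0 == pytest.approx(FITTED_SHELL.dH0, rel=1e-3)

    def test_too_few_points(self):
        data = [CloudPointDatum(t, 0.99) for t in (10.0, 30.0, 50.0)]
        with pytest.raises(ValueError):
            fit_hydration_model(data)

    def test_degenerate_span_rejected(self):
        data = [CloudPointDatum(20.0 + i, 0.99 - 0.01 * i) for i in range(5)]
        with pytest.raises(ValueError):
            fit_hydration_model(data)

    def test_deterministic_given_init(self):
        data, _ = gen_cloud_points(temp_noise_sd=0.3, seed=4)
        init = HydrationShellParams(-50.0, 0.5, 50.0)
        p1 = fit_hydration_model(data, init=init).params
        p2 = fit_hydration_model(data, init=init).params
        assert (p1.dH0, p1.dS0, p1.cp_shell) == (p2.dH0, p2.dS0, p2.cp_shell)


class TestCloudPointGeneration:
    def test_salting_out_monotonicity(self):
        data, _ = gen_cloud_points(temp_noise_sd=0.0, seed=0)
        by_activity = sorted(data, key=lambda d: d.water_activity)
        temps = [d.temperature for d in by_activity]
        assert all(a < b for a, b in zip(temps, temps[1:]))

    def test_empty_concentration_list(self):
        data, missing = gen_cloud_points(concentrations=(), seed=0)
        assert data == [] and missing == []

    def test_no_crossing_reported(self):
        # very low activity pushes the crossing below -10 degC
        data, missing = gen_cloud_points(
            table=NACL_TABLE, concentrations=(6.0,), temp_noise_sd=0.0, seed=0
        )
        assert data == [] and missing == [6.0]

    def test_kcl_crossings_differ_from_nacl(self):
        na, _ = gen_cloud_points(temp_noise_sd=0.0, seed=0)
        k, _ = gen_cloud_points(table=KCL_TABLE, temp_noise_sd=0.0, seed=0)
        assert na[1].temperature != k[1].temperature


def test_hbond_displacement_enthalpy_midpoint_and_range():
    # donor + one acceptor share of the -9.45 kJ/mol solution enthalpy
    assert hbond_displacement_enthalpy() == pytest.approx(5.8, abs=0.1)
    for ratio in (1.6, 1.75, 1.9):
        assert hbond_displacement_enthalpy(acceptor_to_donor=ratio) == pytest.approx(
            5.8, abs=0.15
        )
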