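"""Pressure, density roots, chemical potentials, activities, molality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from saftgmie import (GammaMieEoS, activity_asymmetric, activity_water,
                      build_component, ln_fugacity_coeff, make_fixture,
                      molality_from_x, mu_residual, pressure, solve_density,
                      water, x_from_molality)
from saftgmie.constants import ANGSTROM, K_B, N_A, R_GAS
from saftgmie import mie, thermo

ONE = np.array([1.0])


class TestPressure:
    def test_ideal_gas_exact(self, ideal_eos):
        T, V = 300.0, 0.02
        assert pressure(ideal_eos, T, V, ONE) == pytest.approx(
            R_GAS * T / V, rel=1e-12)

    def test_low_density_compressibility(self, lj_eos):
        T = 600.0
        rho_star = 1e-8
        V = N_A * (3.0 * ANGSTROM) ** 3 / rho_star
        Z = pressure(lj_eos, T, V, ONE) * V / (R_GAS * T)
        assert Z == pytest.approx(1.0, abs=1e-6)

    def test_virial_slope_matches_b2_quadrature(self, lj_eos):
        """Low-density slope of Z - 1 against the exact second virial
        coefficient of the Mie potential, at high T where the third-order
        expansion has converged."""
        sig, eps = 3.0, 150.0
        T = 5.0 * eps
        f = lambda r: (np.exp(-mie.mie_potential(r, sig, eps, 12.0, 6.0) / T)
                       - 1.0) * r ** 2
        b2 = -2 * np.pi * quad(f, 1e-8, 60 * sig, limit=500)[0]  # A^3
        rho_star = 1e-4
        rho = rho_star / sig ** 3  # 1/A^3
        V = N_A * (sig * ANGSTROM) ** 3 / rho_star
        Z = pressure(lj_eos, T, V, ONE) * V / (R_GAS * T)
        assert (Z - 1) / rho == pytest.approx(b2, rel=2e-2)


class TestDensitySolve:
    def test_ideal_gas_density(self, ideal_eos):
        T, P = 300.0, 1e5
        rho = solve_density(ideal_eos, T, P, ONE)
        assert rho == pytest.approx(P / (R_GAS * T), rel=1e-10)

    def test_root_self_consistency(self, water_eos):
        T, P = 298.15, 1e5
        rho = solve_density(water_eos, T, P, ONE, phase="liquid")
        assert pressure(water_eos, T, 1 / rho, ONE) == pytest.approx(
            P, rel=1e-8)

    def test_matches_dense_grid_scan(self, water_eos):
        T, P = 298.15, 1e5
        rho = solve_density(water_eos, T, P, ONE, phase="liquid")
        grid = np.linspace(0.5 * rho, 1.2 * rho, 4000)
        p = np.array([pressure(water_eos, T, 1 / r, ONE) for r in grid])
        best = grid[np.argmin(np.abs(p - P))]
        assert rho == pytest.approx(best, rel=1e-3)

    def test_phase_hints_order_roots(self, water_eos):
        T, P = 350.0, 1e4
        rho_l = solve_density(water_eos, T, P, ONE, phase="liquid")
        rho_v = solve_density(water_eos, T, P, ONE, phase="vapor")
        assert rho_l > 100 * rho_v


class TestChemicalPotential:
    def test_pure_ideal_gas_fugacity(self, ideal_eos):
        assert ln_fugacity_coeff(ideal_eos, 300.0, 1e5, ONE)[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_mu_matches_finite_difference(self, water_eos):
        T = 298.15
        rho = solve_density(water_eos, T, 1e5, ONE, phase="liquid")
        V = 1 / rho
        mu = mu_residual(water_eos, T, V, ONE)[0]
        h = 1e-6
        ap = water_eos.a_residual_total(T, V, np.array([1.0 + h]))
        am = water_eos.a_residual_total(T, V, np.array([1.0 - h]))
        assert mu == pytest.approx(N_A * (ap - am) / (2 * h) / N_A, rel=1e-6)

    def test_fugacity_intensive_under_scaling(self, water_eos):
        T, V = 298.15, 1.9e-5
        mu1 = mu_residual(water_eos, T, V, np.array([1.0]))
        mu2 = mu_residual(water_eos, T, 2 * V, np.array([2.0]))
        assert mu1[0] == pytest.approx(mu2[0], rel=1e-10)

    def test_gibbs_duhem_binary(self, db):
        groups, _ = db
        eth = build_component("ethanol", {"CH3": 1, "CH2OH": 1}, groups)
        eos = GammaMieEoS([water(), eth])
        res = thermo.gibbs_duhem_residual(eos, 298.15, 1e5,
                                          np.array([0.7, 0.3]))
        assert res < 1e-6

    def test_gibbs_duhem_ternary(self, db):
        groups, _ = db
        eth = build_component("ethanol", {"CH3": 1, "CH2OH": 1}, groups)
        gly = build_component("glycine", {"NH2": 1, "CH2": 1, "COOH": 1},
                              groups)
        eos = GammaMieEoS([water(), eth, gly])
        rng = np.random.default_rng(7)
        for _ in range(2):
            x = rng.dirichlet([8.0, 2.0, 1.0])
            res = thermo.gibbs_duhem_residual(eos, 298.15, 1e5, x)
            assert res < 1e-6


class TestMolality:
    def test_one_molal_mole_fraction(self):
        x = x_from_molality(np.array([0.0, 1.0]), np.array([True, False]),
                            np.array([18.015e-3, 75.07e-3]))
        assert x[1] == pytest.approx(1.0 / (1.0 + 1.0 / 18.015e-3 * 1e-3
                                            * 1000), rel=1e-6)
        assert x[1] == pytest.approx(0.01770, abs=2e-5)

    def test_zero_solute(self):
        m = molality_from_x(np.array([1.0, 0.0]), np.array([True, False]),
                            np.array([18.015e-3, 75.07e-3]))
        assert m[1] == 0.0

    @given(st.lists(st.floats(1e-6, 10.0), min_size=2, max_size=2))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_round_trip_property(self, solutes):
        mask = np.array([True, False, False])
        mw = np.array([18.015e-3, 75.07e-3, 58.44e-3])
        x = np.array([20.0, *solutes])
        x = x / x.sum()
        m = molality_from_x(x, mask, mw)
        x2 = x_from_molality(m, mask, mw)
        assert np.allclose(x, x2, rtol=1e-12)

    def test_zero_solvent_rejected(self):
        with pytest.raises(Exception):
            molality_from_x(np.array([0.0, 1.0]), np.array([True, False]),
                            np.array([18.015e-3, 75.07e-3]))


class TestActivities:
    def test_pure_water_activity_is_one(self, db):
        groups, _ = db
        gly = build_component("glycine", {"NH2": 1, "CH2": 1, "COOH": 1},
                              groups)
        eos = GammaMieEoS([water(), gly])
        rec = activity_water(eos, 298.15, 1e5, np.array([1.0, 0.0]))
        assert rec.activity == pytest.approx(1.0, rel=1e-10)
        assert rec.gamma == pytest.approx(1.0, rel=1e-10)

    def test_asymmetric_gamma_is_one_at_reference(self, db):
        groups, _ = db
        gly = build_component("glycine", {"NH2": 1, "CH2": 1, "COOH": 1},
                              groups)
        eos = GammaMieEoS([water(), gly])
        x_ref = thermo._reference_composition(eos, np.array([0.9, 0.1]))
        rec = activity_asymmetric(eos, 298.15, 1e5, x_ref, 1)
        assert rec.gamma == pytest.approx(x_ref[0], rel=1e-6)
        # gamma tilde = x_solvent * phi ratio; at the reference the phi ratio
        # is exactly 1

    def test_interactions_off_gives_raoult(self):
        """Two identical components: an ideal mixture in every convention."""
        fx = make_fixture("lj-like-mie")
        c1 = build_component("a", {"LJ": 1}, fx["groups"])
        c2 = build_component("b", {"LJ": 1}, fx["groups"])
        eos = GammaMieEoS([c1, c2], groups=fx["groups"], db=fx["db"])
        T, P = 110.0, 5e4
        x = np.array([0.65, 0.35])
        ln_phi = ln_fugacity_coeff(eos, T, P, x, phase="liquid")
        assert ln_phi[0] == pytest.approx(ln_phi[1], rel=1e-10)

    def test_water_activity_drops_with_solute(self, db):
        groups, _ = db
        gly = build_component("glycine", {"NH2": 1, "CH2": 1, "COOH": 1},
                              groups)
        eos = GammaMieEoS([water(), gly])
        a1 = activity_water(eos, 298.15, 1e5, np.array([0.99, 0.01])).activity
        a2 = activity_water(eos, 298.15, 1e5, np.array([0.95, 0.05])).activity
        assert a2 < a1 < 1.0
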