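"""MSA ion term, Born term, permittivity and sphere mappings."""

import numpy as np
import pytest

from saftgmie import GammaMieEoS, build_component, ion, make_fixture, water
from saftgmie import electrolyte as el
from saftgmie.constants import ANGSTROM, E_CHARGE, EPS_0, K_B, N_A, PI
from saftgmie.eos import DomainError
from saftgmie.parameters import GroupSpec


@pytest.fixture(scope="module")
def rpm():
    fx = make_fixture("rpm-electrolyte")
    return fx


class TestMapping:
    def test_single_segment_group_maps_to_itself(self):
        g = GroupSpec("X+", 1, 1.0, 3.2477, 10.0, 6.0, 50.0, charge=1,
                      sigma_born=3.4750)
        comp = build_component("x", {"X+": 1}, {"X+": g})
        m = el.map_ions([comp], [g], np.array([[1.0]]), "G")
        assert m.sigma_msa[0] == pytest.approx(3.2477 * ANGSTROM)
        assert m.sigma_born[0] == pytest.approx(3.4750 * ANGSTROM)

    def test_two_segment_group_equal_volume_sphere(self):
        g = GroupSpec("Y+", 2, 1.0, 3.0, 10.0, 6.0, 50.0, charge=1,
                      sigma_born=3.3)
        comp = build_component("y", {"Y+": 1}, {"Y+": g})
        m = el.map_ions([comp], [g], np.array([[1.0]]), "G")
        assert m.sigma_msa[0] == pytest.approx(2 ** (1 / 3) * 3.0 * ANGSTROM)

    def test_zwitterion_excluded_from_both_mappings(self):
        from saftgmie import amino_acid
        zw = amino_acid("glycine", "zwitterion")
        specs = [g for g, _ in zw.groups]
        nu = np.array([[c for _, c in zw.groups]])
        for mode in ("G", "M"):
            m = el.map_ions([zw], specs, nu, mode)
            assert len(m.entities) == 0


class TestPermittivity:
    def test_vacuum_limit(self, rpm):
        eos = GammaMieEoS(rpm["components"], groups=rpm["groups"],
                          db=rpm["db"])
        n = np.array([1.0, 0.0, 0.0])
        assert eos.relative_permittivity(298.15, 1e8, n) == \
            pytest.approx(1.0, abs=1e-11)

    def test_single_solvent_formula(self, rpm):
        eos = GammaMieEoS(rpm["components"], groups=rpm["groups"],
                          db=rpm["db"])
        T, V = 298.15, 3e-5
        n = np.array([1.0, 0.0, 0.0])
        d_ii = 100.0e-30 * (1500.0 / T - 1.0)
        expected = 1.0 + (N_A / V) * d_ii
        assert eos.relative_permittivity(T, V, n) == pytest.approx(expected)

    def test_binary_solvent_mean(self):
        """With d_12 = (d_11 + d_22)/2 the equimolar blend averages exactly."""
        s1 = GroupSpec("S1", 1, 1.0, 0.0, 12.0, 6.0, 0.0)
        s2 = GroupSpec("S2", 1, 1.0, 0.0, 12.0, 6.0, 0.0)
        groups = {"S1": s1, "S2": s2}
        c1 = build_component("w1", {"S1": 1}, groups, solvent=True,
                             dielectric=(80.0, 1200.0))
        c2 = build_component("w2", {"S2": 1}, groups, solvent=True,
                             dielectric=(40.0, 900.0))
        T, V = 300.0, 3e-5
        D = el.relative_permittivity(T, V, np.array([0.5, 0.5]), [c1, c2],
                                     [0, 1])
        d11 = 80.0e-30 * (1200.0 / T - 1)
        d22 = 40.0e-30 * (900.0 / T - 1)
        expected = 1.0 + (N_A / V) * 0.5 * (d11 + d22)
        assert D == pytest.approx(expected, rel=1e-14)

    def test_salt_free_fractions_ignore_ions(self, rpm):
        eos = GammaMieEoS(rpm["components"], groups=rpm["groups"],
                          db=rpm["db"])
        T, V = 298.15, 3e-5
        no_salt = eos.relative_permittivity(T, V, np.array([1.0, 0.0, 0.0]))
        with_salt = eos.relative_permittivity(T, V,
                                              np.array([1.0, 0.05, 0.05]))
        assert with_salt == pytest.approx(no_salt)


class TestScreening:
    def test_no_ions_gives_zero(self):
        scr = el.solve_screening(np.array([0.0]), np.array([1.0]),
                                 np.array([4e-10]), 78.0, 298.15)
        assert scr.gamma == 0.0
        assert el.a_ion(np.array([0.0]), np.array([1.0]), np.array([4e-10]),
                        78.0, 298.15, scr) == 0.0

    @pytest.mark.parametrize("molar", [1e-6, 1e-3, 0.1, 1.0])
    def test_restricted_primitive_model_closed_form(self, molar):
        sig = 4.0e-10
        rho = molar * 1000 * N_A
        rho_e = np.array([rho, rho])
        Z = np.array([1.0, -1.0])
        scr = el.solve_screening(rho_e, Z, np.array([sig, sig]), 78.4, 298.15)
        kd = el.debye_kappa(rho_e, Z, 78.4, 298.15)
        closed = (np.sqrt(1 + 2 * kd * sig) - 1) / (2 * sig)
        assert scr.gamma == pytest.approx(closed, rel=1e-8)

    def test_debye_limit(self):
        """Gamma -> kappa_D / 2 within 0.1% at ionic strength 1e-6."""
        sig = 4.0e-10
        rho = 1e-6 * 1000 * N_A
        rho_e = np.array([rho, rho])
        Z = np.array([1.0, -1.0])
        scr = el.solve_screening(rho_e, Z, np.array([sig, sig]), 78.4, 298.15)
        kd = el.debye_kappa(rho_e, Z, 78.4, 298.15)
        assert scr.gamma == pytest.approx(kd / 2, rel=1e-3)

    def test_ion_term_debye_hueckel_limiting_law(self):
        """A_ion/(N kT) -> -kappa^3/(12 pi rho) within 1% at I = 1e-6."""
        sig = 4.0e-10
        rho = 1e-6 * 1000 * N_A
        rho_e = np.array([rho, rho])
        Z = np.array([1.0, -1.0])
        D, T = 78.4, 298.15
        scr = el.solve_screening(rho_e, Z, np.array([sig, sig]), D, T)
        a = el.a_ion(rho_e, Z, np.array([sig, sig]), D, T, scr)
        kd = el.debye_kappa(rho_e, Z, D, T)
        assert a == pytest.approx(-kd ** 3 / (12 * PI), rel=1e-2)
        assert a < 0


class TestBorn:
    def test_vacuum_gives_zero(self):
        assert el.a_born(np.array([1.0]), np.array([1.0]),
                         np.array([3e-10]), 1.0, 298.15) == 0.0

    def test_classical_charging_energy(self):
        """One +1 ion, Born diameter 3 A, D = 78: classical cavity energy."""
        D, T = 78.0, 298.15
        per_ion = el.a_born(np.array([1.0]), np.array([1.0]),
                            np.array([3.0e-10]), D, T)
        radius = 1.5e-10
        classical = -(E_CHARGE ** 2 / (8 * PI * EPS_0 * radius)) * (1 - 1 / D)
        assert per_ion * K_B * T == pytest.approx(classical, rel=1e-12)


class TestFullModel:
    def test_model_g_equals_model_m_for_monatomic_ions(self):
        comps = [water(), ion("sodium"), ion("chloride")]
        x = np.array([0.96, 0.02, 0.02])
        V = 2.0e-5
        pg = GammaMieEoS(comps, mapping="G").a_residual(298.15, V, x,
                                                        parts=True)
        pm = GammaMieEoS(comps, mapping="M").a_residual(298.15, V, x,
                                                        parts=True)
        assert pg["ion"] == pytest.approx(pm["ion"], rel=1e-12)
        assert pg["born"] == pytest.approx(pm["born"], rel=1e-12)

    def test_permittivity_independent_of_mapping(self):
        comps = [water(), ion("sodium"), ion("chloride")]
        x = np.array([0.96, 0.02, 0.02])
        dg = GammaMieEoS(comps, mapping="G").relative_permittivity(
            298.15, 2e-5, x)
        dm = GammaMieEoS(comps, mapping="M").relative_permittivity(
            298.15, 2e-5, x)
        assert dg == dm

    def test_relabelled_identical_ions_invariant(self):
        comps = [water(), ion("sodium"), ion("chloride")]
        eos = GammaMieEoS(comps)
        V = 2.0e-5
        a1 = eos.a_residual(298.15, V, np.array([0.96, 0.02, 0.02]),
                            parts=True)
        comps2 = [water(), ion("chloride"), ion("sodium")]
        eos2 = GammaMieEoS(comps2)
        a2 = eos2.a_residual(298.15, V, np.array([0.96, 0.02, 0.02]),
                             parts=True)
        assert a1["ion"] + a1["born"] == pytest.approx(
            a2["ion"] + a2["born"], rel=1e-12)

    def test_non_electroneutral_input_rejected(self):
        comps = [water(), ion("sodium"), ion("chloride")]
        eos = GammaMieEoS(comps)
        with pytest.raises(DomainError):
            eos.a_residual(298.15, 2e-5, np.array([0.96, 0.03, 0.01]))

    def test_zwitterion_contributes_nothing_electrostatic(self):
        from saftgmie import amino_acid
        comps = [water(), amino_acid("glycine", "zwitterion")]
        eos = GammaMieEoS(comps)
        parts = eos.a_residual(298.15, 2e-5, np.array([0.97, 0.03]),
                               parts=True)
        assert parts["ion"] == 0.0
        assert parts["born"] == 0.0
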