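"""Free-energy terms against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from saftgmie import GammaMieEoS, build_component, make_fixture
from saftgmie.constants import ANGSTROM, N_A, PI
from saftgmie.eos import DomainError
from saftgmie.parameters import GroupSpec, InteractionDB
from saftgmie import mie

ONE = np.array([1.0])


def _volume_for_rho_star(rho_star, sigma_A, mseg=1.0):
    """Volume of one mole of molecules at segment density rho_s sigma^3."""
    rho_s = rho_star / (sigma_A * ANGSTROM) ** 3
    return N_A * mseg / rho_s


class TestIdeal:
    def test_unit_de_broglie_density_gives_minus_one(self, lj_eos):
        # rho Lambda^3 = 1 (Lambda^3 = 1 m^3): a_ideal = -1
        V = N_A / 1.0
        assert lj_eos.a_ideal(300.0, V, ONE) == pytest.approx(-1.0)

    def test_equimolar_binary_at_unit_density(self):
        fx = make_fixture("lj-like-mie")
        g = fx["groups"]["LJ"]
        c1 = build_component("a", {"LJ": 1}, fx["groups"])
        c2 = build_component("b", {"LJ": 1}, fx["groups"])
        eos = GammaMieEoS([c1, c2], groups=fx["groups"], db=fx["db"])
        x = np.array([0.5, 0.5])
        V = N_A / 1.0  # each partial density = 0.5
        expected = 2 * 0.5 * np.log(0.5) - 1.0
        assert eos.a_ideal(300.0, V, x) == pytest.approx(expected)

    def test_rho_e_gives_zero(self, lj_eos):
        V = N_A / np.e
        assert lj_eos.a_ideal(300.0, V, ONE) == pytest.approx(0.0, abs=1e-12)


class TestMonomer:
    def test_ideal_gas_limit(self, lj_eos):
        V = _volume_for_rho_star(1e-12, 3.0)
        assert abs(lj_eos.a_mono(300.0, V, ONE)) < 1e-10

    def test_hard_sphere_equals_carnahan_starling(self, hs_eos):
        d = 3.0 * ANGSTROM
        for eta in (0.05, 0.2, 0.4, 0.5):
            V = N_A * PI * d ** 3 / (6 * eta)
            cs = (4 * eta - 3 * eta ** 2) / (1 - eta) ** 2
            assert hs_eos.a_mono(300.0, V, ONE) == pytest.approx(cs, rel=1e-10)

    def test_eps_zero_has_no_perturbation_terms(self, hs_eos):
        V = _volume_for_rho_star(0.5, 3.0)
        total, parts = hs_eos.a_mono(300.0, V, ONE, parts=True)
        assert parts[1] == parts[2] == parts[3] == 0.0
        assert total == parts[0]

    def test_a1_matches_low_density_quadrature(self, lj_eos):
        """First-order term vs 2 pi rho beta int_sigma u g_HS r^2 dr with the
        exact first-order hard-sphere RDF, at rho sigma^3 <= 0.05."""
        sig, eps, lr, la = 3.0, 150.0, 12.0, 6.0
        T = 300.0
        d = float(mie.bh_diameter(T, sig, eps, lr, la))
        u = lambda r: mie.mie_potential(r, sig, eps, lr, la)
        w = lambda r: (4 * PI / 3) * d ** 3 * (
            1 - 0.75 * (r / d) + (r / d) ** 3 / 16) * (r / d < 2)
        I0 = quad(lambda r: u(r) * r ** 2, sig, 80 * sig, limit=400)[0]
        I1 = quad(lambda r: u(r) * w(r) * r ** 2, sig, 2.5 * d, limit=400)[0]
        for rho_star in (0.01, 0.05):
            rho = rho_star / sig ** 3  # 1/A^3
            V = _volume_for_rho_star(rho_star, sig)
            _, parts = lj_eos.a_mono(T, V, ONE, parts=True)
            beta_a1_oracle = 2 * PI * rho * (I0 + rho * I1) / T
            assert parts[1] == pytest.approx(beta_a1_oracle, rel=3e-3)

    def test_overpacked_state_raises(self, hs_eos):
        d = 3.0 * ANGSTROM
        V = N_A * PI * d ** 3 / (6 * 1.01)
        with pytest.raises(DomainError):
            hs_eos.a_mono(300.0, V, ONE)


class TestChain:
    def test_single_unit_segment_has_no_chain_term(self, lj_eos):
        V = _volume_for_rho_star(0.5, 3.0)
        assert lj_eos.a_chain(300.0, V, ONE) == 0.0

    def test_two_segment_prefactor(self):
        """nu* = 2, S = 1 molecule: a_chain = -x ln g exactly."""
        g = GroupSpec("D", 2, 1.0, 3.0, 12.0, 6.0, 150.0)
        comp = build_component("dimer", {"D": 1}, {"D": g})
        eos = GammaMieEoS([comp], groups={"D": g}, db=InteractionDB())
        T, V = 300.0, _volume_for_rho_star(0.5, 3.0, mseg=2.0)
        pk = eos._packing(T, V, ONE)
        g_mie, act = eos._g_mie(T, pk)
        expected = -1.0 * np.log(g_mie[0])
        assert eos.a_chain(T, V, ONE) == pytest.approx(float(expected.real),
                                                       rel=1e-12)
        assert g_mie[0].real > 1.0  # dense fluid: positive contact correlation

    def test_chain_vanishes_at_zero_density(self):
        g = GroupSpec("D", 2, 1.0, 3.0, 12.0, 6.0, 150.0)
        comp = build_component("dimer", {"D": 1}, {"D": g})
        eos = GammaMieEoS([comp], groups={"D": g}, db=InteractionDB())
        V = _volume_for_rho_star(1e-10, 3.0, mseg=2.0)
        assert abs(eos.a_chain(300.0, V, ONE)) < 1e-7


def _two_site_eos(eps_hb=1500.0, k_hb=50.0):
    g = GroupSpec("A2", 1, 1.0, 3.0, 12.0, 6.0, 200.0,
                  sites={"H": 1, "e1": 1})
    db = InteractionDB()
    db.set_association("A2", "H", "A2", "e1", eps_hb, k_hb)
    comp = build_component("a2", {"A2": 1}, {"A2": g})
    return GammaMieEoS([comp], groups={"A2": g}, db=db)


class TestAssociation:
    def test_no_entries_gives_unit_fractions(self, lj_eos):
        V = _volume_for_rho_star(0.5, 3.0)
        X = lj_eos.solve_association(300.0, V, ONE)
        assert X.size == 0
        assert lj_eos.a_assoc(300.0, V, ONE) == 0.0

    def test_zero_bond_strength_gives_unit_fractions(self):
        eos = _two_site_eos(eps_hb=0.0, k_hb=0.0)
        V = _volume_for_rho_star(0.5, 3.0)
        X = eos.solve_association(300.0, V, ONE)
        assert np.allclose(X, 1.0)

    @pytest.mark.parametrize("rho_star", [0.05, 0.2, 0.4, 0.7])
    def test_two_site_closed_form(self, rho_star):
        """X = (-1 + sqrt(1 + 4 rho Delta)) / (2 rho Delta)."""
        eos = _two_site_eos()
        T = 300.0
        V = _volume_for_rho_star(rho_star, 3.0)
        pk = eos._packing(T, V, ONE)
        delta = eos._delta_matrix(T, pk)[0, 1]
        rd = pk["rho"] * delta
        X = eos.solve_association(T, V, ONE, pk=pk)
        closed = (-1 + np.sqrt(1 + 4 * rd)) / (2 * rd)
        assert X == pytest.approx(closed, rel=1e-12)

    def test_matches_undamped_fixed_point_iteration(self):
        eos = _two_site_eos()
        T, V = 300.0, _volume_for_rho_star(0.5, 3.0)
        pk = eos._packing(T, V, ONE)
        X = eos.solve_association(T, V, ONE, pk=pk)
        delta = eos._delta_matrix(T, pk)
        rho_slot = pk["rho"] * (pk["x"] @ eos.slot_mult)
        coupling = delta * rho_slot[None, :]
        Xi = np.ones(len(X))
        for _ in range(20000):
            Xi = 1.0 / (1.0 + coupling @ Xi)
        assert X == pytest.approx(Xi, rel=1e-10)

    def test_bonding_increases_with_density(self):
        """Doubling the density strictly decreases the unbonded fraction."""
        eos = _two_site_eos()
        T = 300.0
        X1 = eos.solve_association(T, _volume_for_rho_star(0.2, 3.0), ONE)
        X2 = eos.solve_association(T, _volume_for_rho_star(0.4, 3.0), ONE)
        assert np.all(X2 < X1)

    def test_a_assoc_direct_value(self):
        """Contribution formula at a hand-set X on a one-site molecule."""
        g = GroupSpec("B1", 1, 1.0, 3.0, 12.0, 6.0, 100.0, sites={"H": 1})
        comp = build_component("b1", {"B1": 1}, {"B1": g})
        eos = GammaMieEoS([comp], groups={"B1": g}, db=InteractionDB())
        V = _volume_for_rho_star(0.3, 3.0)
        val = eos.a_assoc(300.0, V, ONE, X=np.array([0.5]))
        assert val == pytest.approx(np.log(0.5) + 0.25)


class TestLimitsAndSmoothness:
    def test_total_residual_vanishes_in_ideal_gas_limit(self, lj_eos,
                                                        water_eos):
        V = _volume_for_rho_star(1e-8, 3.0)
        assert abs(lj_eos.a_residual(300.0, V, ONE)) < 1e-6
        # water's association gives a large second virial coefficient; the
        # residual still vanishes linearly in density
        a1 = water_eos.a_residual(298.15, _volume_for_rho_star(1e-8, 3.0063),
                                  ONE)
        a2 = water_eos.a_residual(298.15, _volume_for_rho_star(1e-9, 3.0063),
                                  ONE)
        assert abs(a1) < 1e-5
        assert a2 == pytest.approx(a1 / 10, rel=1e-3)

    def test_free_energy_smooth_in_T_and_V(self, water_eos):
        T0, V0 = 320.0, _volume_for_rho_star(0.6, 3.0063)
        for rel in (1e-4, 1e-5):
            hT = T0 * rel
            d2T = (water_eos.a_residual(T0 + hT, V0, ONE)
                   - 2 * water_eos.a_residual(T0, V0, ONE)
                   + water_eos.a_residual(T0 - hT, V0, ONE)) / hT ** 2
            hV = V0 * rel
            d2V = (water_eos.a_residual(T0, V0 + hV, ONE)
                   - 2 * water_eos.a_residual(T0, V0, ONE)
                   + water_eos.a_residual(T0, V0 - hV, ONE)) / hV ** 2
            assert np.isfinite(d2T) and np.isfinite(d2V)
        # first derivatives stable between step sizes
        for h1, h2 in [(1e-5, 1e-6)]:
            g1 = (water_eos.a_residual(T0 * (1 + h1), V0, ONE)
                  - water_eos.a_residual(T0 * (1 - h1), V0, ONE)) / (2 * h1 * T0)
            g2 = (water_eos.a_residual(T0 * (1 + h2), V0, ONE)
                  - water_eos.a_residual(T0 * (1 - h2), V0, ONE)) / (2 * h2 * T0)
            assert g1 == pytest.approx(g2, rel=1e-5)

    def test_breakdown_sums_to_total(self, water_eos):
        V = _volume_for_rho_star(0.7, 3.0063)
        parts = water_eos.free_energy_breakdown(298.15, V, ONE)
        total = parts.pop("total")
        assert total == pytest.approx(sum(parts.values()), rel=1e-12)
        assert parts["ion"] == 0.0 and parts["born"] == 0.0
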