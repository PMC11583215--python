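"""Helmholtz free-energy model for mixtures of fused Mie-segment molecules.

The total free energy is assembled as

    A = A_ideal + A_mono + A_chain + A_assoc + A_ion + A_Born

with the monomer term a third-order Barker-Henderson perturbation expansion
about a hard-sphere reference, the chain term the first-order Wertheim (TPT1)
connectivity correction evaluated with molecularly averaged Mie parameters,
the association term the Wertheim mass-action contribution of embedded
short-range sites, and, for mixtures containing net-charged species, the
mean-spherical-approximation ion term and the Born solvation term.

All residual-energy code paths accept complex volume / mole numbers so that
pressure and chemical potentials can be evaluated by complex-step
differentiation (exact to machine precision; no step-size trade-off).
"""

from __future__ import annotations

import numpy as np

from . import electrolyte, mie
from .constants import ANGSTROM, K_B, N_A, PI
from .parameters import (
    SITE_TYPES, Component, default_db, resolve_association, resolve_unlike,
)


class DomainError(ValueError):
    """State outside the physical domain of the model (e.g. overpacked)."""


class ConvergenceError(RuntimeError):
    """An internal solver failed to converge."""


_CHANNELS = ("a", "r", "aa", "ar", "rr")


class GammaMieEoS:
    """Equation of state for a fixed list of components.

    Parameters
    ----------
    components:
        Sequence of :class:`~saftgmie.parameters.Component`.
    groups, db:
        Parameter database; defaults to the packaged tables.
    mapping:
        ``"G"`` (group) or ``"M"`` (molecular) sphere mapping for the
        electrostatic terms of net-charged chain species.
    """

    def __init__(self, components, groups=None, db=None, mapping="G"):
        if groups is None or db is None:
            g0, d0 = default_db()
            groups = groups or g0
            db = db or d0
        self.components = list(components)
        self.db = db
        if mapping not in ("G", "M"):
            raise ValueError("mapping must be 'G' or 'M'")
        self.mapping = mapping

        # --- group bookkeeping -------------------------------------------
        specs = []
        seen = {}
        for comp in self.components:
            for g, _ in comp.groups:
                if g.name not in seen:
                    seen[g.name] = len(specs)
                    specs.append(g)
        self.group_specs = specs
        ng = len(specs)
        nc = len(self.components)
        self.nu = np.zeros((nc, ng))
        for i, comp in enumerate(self.components):
            for g, count in comp.groups:
                self.nu[i, seen[g.name]] += count

        self.nu_star = np.array([g.nu_star for g in specs], float)
        self.shape = np.array([g.shape_factor for g in specs], float)
        self.sigma = np.array([g.sigma for g in specs]) * ANGSTROM
        self.eps_K = np.array([g.epsilon_over_kB for g in specs])
        self.lam_r = np.array([g.lambda_r for g in specs])
        self.lam_a = np.array([g.lambda_a for g in specs])
        self.z_group = np.array([g.charge for g in specs], float)
        self.seg_weight = self.nu_star * self.shape
        self.mseg = self.nu @ self.seg_weight  # effective segments / molecule
        self.z_comp = np.array([c.net_charge for c in self.components], float)
        self.molar_mass = np.array([c.molar_mass for c in self.components])

        # --- pair matrices ------------------------------------------------
        eps_kl = np.zeros((ng, ng))
        lr_kl = np.zeros((ng, ng))
        la_kl = np.zeros((ng, ng))
        sig_kl = np.zeros((ng, ng))
        for k in range(ng):
            for l in range(ng):
                e, lr, la, s, _ = resolve_unlike(specs[k], specs[l], db)
                eps_kl[k, l], lr_kl[k, l], la_kl[k, l] = e, lr, la
                sig_kl[k, l] = s * ANGSTROM
        self.eps_kl, self.lam_r_kl, self.lam_a_kl = eps_kl, lr_kl, la_kl
        self.sigma_kl = sig_kl
        with np.errstate(divide="ignore", invalid="ignore"):
            self.C_kl = mie.mie_prefactor(lr_kl, la_kl)
            self.alpha_kl = self.C_kl * (1.0 / (la_kl - 3.0) - 1.0 / (lr_kl - 3.0))
        self._pair_lam = {
            "a": la_kl, "r": lr_kl,
            "aa": 2 * la_kl, "ar": la_kl + lr_kl, "rr": 2 * lr_kl,
        }
        self._pair_c = {ch: mie.zeta_coeffs(lam) for ch, lam in self._pair_lam.items()}
        self.f_chi = [mie.f_alpha(k, self.alpha_kl) for k in (1, 2, 3)]
        self.f_a3 = [mie.f_alpha(k, self.alpha_kl) for k in (4, 5, 6)]

        # --- chain (molecular averages, composition independent) ----------
        with np.errstate(invalid="ignore"):
            zfrac = (self.nu * self.seg_weight) / np.where(
                self.mseg[:, None] > 0, self.mseg[:, None], 1.0)
        self.zfrac = zfrac
        self.sigbar3 = np.einsum("ik,il,kl->i", zfrac, zfrac, sig_kl ** 3)
        self.epsbar = np.einsum("ik,il,kl->i", zfrac, zfrac, eps_kl)
        self.lambar_a = np.einsum("ik,il,kl->i", zfrac, zfrac, la_kl)
        self.lambar_r = np.einsum("ik,il,kl->i", zfrac, zfrac, lr_kl)
        self._chain_active = (np.abs(self.mseg - 1.0) > 1e-14) & (self.sigbar3 > 0)
        lam_ok = np.where(self.lambar_r > self.lambar_a, self.lambar_r,
                          self.lambar_a + 1.0)
        self.lambar_r = np.where(self._chain_active, self.lambar_r, lam_ok)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.Cbar = mie.mie_prefactor(self.lambar_r, self.lambar_a)
            self.alphabar = self.Cbar * (1.0 / (self.lambar_a - 3.0)
                                         - 1.0 / (self.lambar_r - 3.0))
        self._chain_lam = {
            "a": self.lambar_a, "r": self.lambar_r, "aa": 2 * self.lambar_a,
            "ar": self.lambar_a + self.lambar_r, "rr": 2 * self.lambar_r,
        }
        self._chain_c = {ch: mie.zeta_coeffs(lam)
                         for ch, lam in self._chain_lam.items()}

        # --- association ---------------------------------------------------
        slots = []
        for k, g in enumerate(specs):
            for a in SITE_TYPES:
                if g.sites.get(a, 0) > 0:
                    slots.append((k, a, g.sites[a]))
        self.site_slots = slots
        ns = len(slots)
        self.eps_hb = np.zeros((ns, ns))
        self.k_hb = np.zeros((ns, ns))
        self.assoc_mask = np.zeros((ns, ns), bool)
        self.tstar_eps = np.ones((ns, ns))
        for p, (k, a, _) in enumerate(slots):
            for q, (l, b, _) in enumerate(slots):
                res = resolve_association(specs[k], a, specs[l], b, db)
                if res is not None:
                    self.eps_hb[p, q] = res[0]
                    self.k_hb[p, q] = res[1] * ANGSTROM ** 3
                    self.assoc_mask[p, q] = True
                    self.tstar_eps[p, q] = max(eps_kl[k, l], 1e-12)
        # site-count factor per slot and component: nu_{k,i} * n_{k,a}
        self.slot_mult = np.array(
            [[self.nu[i, k] * n for (k, a, n) in slots] for i in range(nc)]
        )

        # --- electrostatics -------------------------------------------------
        self.ion_map = electrolyte.map_ions(self.components, specs, self.nu,
                                            mapping)
        self.solvent_idx = [i for i, c in enumerate(self.components) if c.is_solvent]
        self.has_ions = bool(self.ion_map.entities) and np.any(self.z_comp != 0)
        if self.has_ions and not self.solvent_idx:
            raise DomainError("charged species require at least one solvent")

        self._dcache = {}

    # -- cached temperature-dependent geometry -----------------------------

    def _geometry(self, T):
        key = float(T)
        hit = self._dcache.get(key)
        if hit is not None:
            return hit
        d_kk = np.atleast_1d(mie.bh_diameter(
            T, self.sigma / ANGSTROM, self.eps_K, self.lam_r, self.lam_a
        )) * ANGSTROM
        d_kl = 0.5 * (d_kk[:, None] + d_kk[None, :])
        x0_kl = np.where(d_kl > 0, self.sigma_kl / np.where(d_kl > 0, d_kl, 1.0), 1.0)
        dbar3 = np.einsum("ik,il,kl->i", self.zfrac, self.zfrac, d_kl ** 3)
        dbar = np.where(dbar3 > 0, dbar3, 1.0) ** (1 / 3)
        xbar0 = np.where(dbar3 > 0, self.sigbar3 ** (1 / 3) / dbar, 1.0)
        out = (d_kk, d_kl, x0_kl, dbar, xbar0)
        if len(self._dcache) > 64:
            self._dcache.clear()
        self._dcache[key] = out
        return out

    def max_density(self, T, x):
        """Molar density at segment packing fraction 0.9 (solver bound)."""
        d_kk, d_kl, *_ = self._geometry(T)
        x = np.asarray(x, float)
        seg_vol = (PI / 6.0) * ((x @ self.nu) * self.seg_weight * d_kk ** 3).sum()
        if seg_vol <= 0:
            return 1e8  # interaction-free fixture: effectively unbounded
        return 0.9 / seg_vol / N_A

    # -- free-energy pieces -------------------------------------------------

    def a_ideal(self, T, V, n):
        """A_ideal/(N k_B T) with the unit de Broglie volume convention."""
        n = np.asarray(n)
        N = n.sum()
        x = n / N
        rho_i = n * N_A / V
        mask = np.abs(x) > 0
        return (x[mask] * np.log(rho_i[mask])).sum() - 1.0

    def _packing(self, T, V, n):
        d_kk, d_kl, x0_kl, dbar, xbar0 = self._geometry(T)
        N = n.sum()
        rho = N * N_A / V  # molecules / m^3
        x = n / N
        mbar = x @ self.mseg
        rho_s = rho * mbar
        xs = (x @ self.nu) * self.seg_weight / mbar if np.abs(mbar) > 0 else \
            np.zeros(len(self.seg_weight))
        pref = PI * rho_s / 6.0
        zeta = [pref * (xs * d_kk ** l).sum() for l in range(4)]
        zeta_x = pref * np.einsum("k,l,kl->", xs, xs, d_kl ** 3)
        zeta_x_bar = pref * np.einsum("k,l,kl->", xs, xs, self.sigma_kl ** 3)
        return dict(rho=rho, x=x, mbar=mbar, rho_s=rho_s, xs=xs, zeta=zeta,
                    zeta_x=zeta_x, zeta_x_bar=zeta_x_bar, d_kk=d_kk, d_kl=d_kl,
                    x0_kl=x0_kl, dbar=dbar, xbar0=xbar0)

    def a_mono(self, T, V, n, pk=None, parts=False):
        """Monomer contribution A_mono/(N k_B T)."""
        n = np.asarray(n)
        pk = pk or self._packing(T, V, n)
        z0, z1, z2, z3 = pk["zeta"]
        if np.abs(z3) < 1e-300:
            if parts:
                return 0.0, (0.0, 0.0, 0.0, 0.0)
            return 0.0
        if z3.real >= 1.0:
            raise DomainError(f"hard-sphere packing fraction {z3.real:.3f} >= 1")
        rho_s, xs, zx, zxb = pk["rho_s"], pk["xs"], pk["zeta_x"], pk["zeta_x_bar"]
        x0, d_kl = pk["x0_kl"], pk["d_kl"]

        one = 1.0 - z3
        a_hs = (6.0 / (PI * rho_s)) * (
            (z2 ** 3 / z3 ** 2 - z0) * np.log(one)
            + 3.0 * z1 * z2 / one + z2 ** 3 / (z3 * one ** 2)
        )

        s = {ch: mie.s_channel(self._pair_lam[ch], self._pair_c[ch], x0, zx)
             for ch in _CHANNELS}
        la, lr = self._pair_lam["a"], self._pair_lam["r"]
        xs2 = np.einsum("k,l->kl", xs, xs)

        a1_kl = (2.0 * PI * rho_s * self.eps_K * d_kl ** 3 * self.C_kl
                 * (x0 ** la * s["a"] - x0 ** lr * s["r"]))
        a1 = (xs2 * a1_kl).sum()

        khs = mie.k_hs(zx)
        chi = self.f_chi[0] * zxb + self.f_chi[1] * zxb ** 5 + self.f_chi[2] * zxb ** 8
        s2sum = (x0 ** (2 * la) * s["aa"] - 2.0 * x0 ** self._pair_lam["ar"] * s["ar"]
                 + x0 ** (2 * lr) * s["rr"])
        a2_kl = (PI * rho_s * khs * (1.0 + chi) * self.eps_K ** 2 * d_kl ** 3
                 * self.C_kl ** 2 * s2sum)
        a2 = (xs2 * a2_kl).sum()

        a3_kl = (-self.eps_K ** 3 * self.f_a3[0] * zxb
                 * np.exp(self.f_a3[1] * zxb + self.f_a3[2] * zxb ** 2))
        a3 = (xs2 * a3_kl).sum()

        mbar = pk["mbar"]
        total = mbar * (a_hs + a1 / T + a2 / T ** 2 + a3 / T ** 3)
        if parts:
            return total, (mbar * a_hs, mbar * a1 / T, mbar * a2 / T ** 2,
                           mbar * a3 / T ** 3)
        return total

    def _g_mie(self, T, pk):
        """Contact RDF of each component's averaged Mie fluid (array)."""
        zx, zxb, rho_s = pk["zeta_x"], pk["zeta_x_bar"], pk["rho_s"]
        xbar0 = pk["xbar0"]
        act = self._chain_active
        la, lr = self._chain_lam["a"], self._chain_lam["r"]
        s = {}
        ds = {}
        for ch in _CHANNELS:
            s[ch], ds[ch] = mie.s_channel(self._chain_lam[ch], self._chain_c[ch],
                                          xbar0, zx, want_derivative=True)
        g_hs = mie.g_hs_contact(xbar0, zx)

        C = self.Cbar
        g1 = C * (
            3.0 * (xbar0 ** la * (s["a"] + zx * ds["a"])
                   - xbar0 ** lr * (s["r"] + zx * ds["r"]))
            - la * xbar0 ** la * s["a"] + lr * xbar0 ** lr * s["r"]
        )

        khs, dkhs = mie.k_hs(zx, want_derivative=True)
        lar = self._chain_lam["ar"]
        s2 = (xbar0 ** (2 * la) * s["aa"] - 2.0 * xbar0 ** lar * s["ar"]
              + xbar0 ** (2 * lr) * s["rr"])
        ds2 = (xbar0 ** (2 * la) * ds["aa"] - 2.0 * xbar0 ** lar * ds["ar"]
               + xbar0 ** (2 * lr) * ds["rr"])
        g2_mca = C ** 2 * (
            1.5 * (khs * s2 + zx * (dkhs * s2 + khs * ds2))
            - khs * (lr * xbar0 ** (2 * lr) * s["rr"]
                     - lar * xbar0 ** lar * s["ar"]
                     + la * xbar0 ** (2 * la) * s["aa"])
        )
        theta = np.exp(self.epsbar / T) - 1.0
        gc = mie.GAMMA_C
        gamma_c = (gc[0] * (-np.tanh(gc[1] * (gc[2] - self.alphabar)) + 1.0)
                   * zxb * theta * np.exp(gc[3] * zxb + gc[4] * zxb ** 2))
        g2 = (1.0 + gamma_c) * g2_mca
        be = self.epsbar / T
        return g_hs * np.exp((be * g1 + be ** 2 * g2) / g_hs), act

    def a_chain(self, T, V, n, pk=None):
        """Chain-connectivity contribution A_chain/(N k_B T)."""
        n = np.asarray(n)
        pk = pk or self._packing(T, V, n)
        if np.abs(pk["zeta"][3]) < 1e-300 or not self._chain_active.any():
            return 0.0
        g, act = self._g_mie(T, pk)
        x = pk["x"]
        return -(x[act] * (self.mseg[act] - 1.0) * np.log(g[act])).sum()

    # -- association --------------------------------------------------------

    def _delta_matrix(self, T, pk):
        """Association strengths Delta_ab (m^3) between site slots."""
        if not self.assoc_mask.any():
            return None
        rho_s = pk["rho_s"]
        sigx3 = np.einsum("k,l,kl->", pk["xs"], pk["xs"], self.sigma_kl ** 3)
        rho_star = rho_s * sigx3
        t_star = T / self.tstar_eps
        I = mie.association_kernel(rho_star, t_star)
        F = np.exp(self.eps_hb / T) - 1.0
        return np.where(self.assoc_mask, F * self.k_hb * I, 0.0)

    def solve_association(self, T, V, n, pk=None, tol=1e-12, max_iter=800):
        """Unbonded site fractions X per (group, site-type) slot.

        Damped successive substitution (factor 0.5) with a Newton polish;
        X = 1 exactly for sites without partners.
        """
        n = np.asarray(n)
        pk = pk or self._packing(T, V, n)
        ns = len(self.site_slots)
        if ns == 0:
            return np.ones(0)
        delta = self._delta_matrix(T, pk)
        if delta is None or not np.any(np.abs(delta) > 0):
            return np.ones(ns, dtype=np.result_type(pk["rho"], 1.0))
        rho_slot = pk["rho"] * (pk["x"] @ self.slot_mult)  # sites / m^3
        coupling = delta * rho_slot[None, :]

        dtype = np.result_type(coupling, 1.0)
        X = np.ones(ns, dtype=dtype)
        # damped successive substitution to reach the Newton basin
        for it in range(100):
            X_new = 1.0 / (1.0 + coupling @ X)
            err = np.abs(X_new / X - 1.0).max()
            X = 0.5 * X + 0.5 * X_new
            if err < 1e-3:
                break
        # Newton in log variables u = ln X keeps the fractions positive:
        # H(u) = u + ln(1 + C exp(u)) = 0
        u = np.log(X)
        h_norm = np.inf
        for it in range(100):
            X = np.exp(u)
            cx = coupling @ X
            H = u + np.log(1.0 + cx)
            h_norm = np.abs(H).max()
            if h_norm < tol:
                return X
            J = np.eye(ns, dtype=dtype) + (coupling * X[None, :]) / (1.0 + cx)[:, None]
            step = np.linalg.solve(J, H)
            lam = 1.0
            for _ in range(40):
                u_try = u - lam * step
                # X <= 1 physically: clamp the real part of ln X at zero
                u_try = np.where(u_try.real > 0, 1j * u_try.imag
                                 if np.iscomplexobj(u_try) else 0.0, u_try)
                X_try = np.exp(u_try)
                H_try = u_try + np.log(1.0 + coupling @ X_try)
                if np.abs(H_try).max() < h_norm or lam < 1e-4:
                    u = u_try
                    break
                lam *= 0.5
        raise ConvergenceError(
            f"association solver: no convergence, residual {h_norm:.2e}")

    def a_assoc(self, T, V, n, X=None, pk=None):
        """Association contribution A_assoc/(N k_B T)."""
        n = np.asarray(n)
        pk = pk or self._packing(T, V, n)
        if X is None:
            X = self.solve_association(T, V, n, pk=pk)
        if len(X) == 0:
            return 0.0
        mult = pk["x"] @ self.slot_mult  # sites per molecule, mixture-averaged
        return (mult * (np.log(X) + (1.0 - X) / 2.0)).sum()

    # -- electrostatics ------------------------------------------------------

    def _a_electro(self, T, V, n, pk):
        if not self.has_ions:
            return 0.0, 0.0
        x = pk["x"]
        if np.abs((x * self.z_comp).sum()).real > 1e-12:
            raise DomainError("mixture is not electroneutral")
        D = self.relative_permittivity(T, V, n)
        rho_e = pk["rho"] * (self.ion_map.counts @ x)  # entities / m^3
        if not np.any(np.abs(rho_e) > 0):
            return 0.0, 0.0
        scr = electrolyte.solve_screening(
            rho_e, self.ion_map.charges, self.ion_map.sigma_msa, D, T)
        a_ion = electrolyte.a_ion(rho_e, self.ion_map.charges,
                                  self.ion_map.sigma_msa, D, T, scr) / pk["rho"]
        a_born = electrolyte.a_born(rho_e, self.ion_map.charges,
                                    self.ion_map.sigma_born, D, T) / pk["rho"]
        return a_ion, a_born

    def relative_permittivity(self, T, V, n):
        """Relative static permittivity from the solvent species."""
        n = np.asarray(n)
        if not self.solvent_idx:
            raise DomainError("no solvent present")
        return electrolyte.relative_permittivity(
            T, V, n, self.components, self.solvent_idx)

    # -- assembly ------------------------------------------------------------

    def a_residual(self, T, V, n, parts=False):
        """Residual A/(N k_B T) (everything except the ideal term)."""
        n = np.asarray(n)
        pk = self._packing(T, V, n)
        mono = self.a_mono(T, V, n, pk=pk)
        chain = self.a_chain(T, V, n, pk=pk)
        assoc = self.a_assoc(T, V, n, pk=pk)
        ion, born = self._a_electro(T, V, n, pk)
        if parts:
            return dict(mono=mono, chain=chain, assoc=assoc, ion=ion, born=born)
        return mono + chain + assoc + ion + born

    def free_energy_breakdown(self, T, V, n):
        """Dimensionless breakdown incl. the ideal term (per molecule)."""
        parts = self.a_residual(T, V, n, parts=True)
        parts["ideal"] = self.a_ideal(T, V, n)
        parts["total"] = sum(parts.values())
        return parts

    def a_residual_total(self, T, V, n):
        """Residual Helmholtz energy in joules (complex-step safe)."""
        n = np.asarray(n)
        N = n.sum() * N_A
        return self.a_residual(T, V, n) * N * K_B * T
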