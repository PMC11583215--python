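"""Acid-base speciation of diprotic amino acids in water.

A diprotic amino acid AA speciates between its cation AA+, zwitterion AA+-
and anion AA-:

    AA+  + H2O <-> AA+- + H3O+     K_A1 = a_zw a_H / (a_cat a_w)
    AA+- + H2O <-> AA-  + H3O+     K_A2 = a_an a_H / (a_zw a_w)
    2 H2O      <-> H3O+ + OH-      K_W  = a_H a_OH / a_w^2

Solute activities follow the asymmetric molality convention
(a_i = m_i gamma_m,i / m0); the water activity is symmetric. pH is
-log10 a_H3O+. Equilibrium constants are moved in temperature with the
van 't Hoff relation ln K(T) = ln K(T0) + (dh/R)(1/T0 - 1/T). Strong base
(NaOH) and acid (HCl) are fully dissociated; their counterions close the
charge balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import DH_W, KW_298, M0_REF, R_GAS, T_REF
from .eos import ConvergenceError, DomainError, GammaMieEoS
from .parameters import amino_acid, ion, load_ka, water
from .sle import MeltingProperties, sle_rhs
from . import thermo

# species slots in a speciation mixture
WATER, ZW, CAT, AN, H3O, OH, NA, CL = range(8)
_SPECIES_CHARGE = np.array([0, 0, +1, -1, +1, -1, +1, -1], float)


def k_at_temperature(k_ref: float, dh_J_mol: float, T: float,
                     T0: float = T_REF) -> float:
    """van 't Hoff temperature correction of an equilibrium constant."""
    return k_ref * math.exp(dh_J_mol / R_GAS * (1.0 / T0 - 1.0 / T))


def pK(K: float) -> float:
    return -math.log10(K)


def pI(pK_A1: float, pK_A2: float) -> float:
    """Isoelectric point: arithmetic mean of the two pK values."""
    return 0.5 * (pK_A1 + pK_A2)


@dataclass(frozen=True)
class ReactionSet:
    """Equilibrium constants (at 298.15 K) and protonation enthalpies."""

    K_A1: float
    dh_A1: float  # J/mol
    K_A2: float
    dh_A2: float  # J/mol
    K_W: float = KW_298
    dh_W: float = DH_W

    @classmethod
    def from_table(cls, compound: str, path=None) -> "ReactionSet":
        row = load_ka(path).loc[compound]
        return cls(float(row["K_A1_298"]), float(row["dh_A1_kJmol"]) * 1e3,
                   float(row["K_A2_298"]), float(row["dh_A2_kJmol"]) * 1e3)

    def at(self, T):
        """(K_A1, K_A2, K_W) at temperature T."""
        return (k_at_temperature(self.K_A1, self.dh_A1, T),
                k_at_temperature(self.K_A2, self.dh_A2, T),
                k_at_temperature(self.K_W, self.dh_W, T))


# ---------------------------------------------------------------------------
# activity models


class IdealActivities:
    """gamma = 1 for all solutes; water activity x_w (or exactly 1)."""

    def __init__(self, aw: str = "xw"):
        if aw not in ("xw", "unity"):
            raise ValueError("aw must be 'xw' or 'unity'")
        self.aw = aw

    def evaluate(self, T, P, molalities):
        gam = np.ones(8)
        if self.aw == "unity":
            return gam, 1.0
        x = _x_from_molality(molalities)
        return gam, x[WATER]


class SaftActivities:
    """Asymmetric molality activity coefficients and symmetric water
    activity from the full free-energy model."""

    def __init__(self, compound: str = "glycine", mapping: str = "G",
                 aw: str = "saft", groups=None, db=None):
        if aw not in ("saft", "unity"):
            raise ValueError("aw must be 'saft' or 'unity'")
        self.aw = aw
        comps = [
            water(),
            amino_acid(compound, "zwitterion", groups),
            amino_acid(compound, "cation", groups),
            amino_acid(compound, "anion", groups),
            ion("hydronium"), ion("hydroxide"), ion("sodium"), ion("chloride"),
        ]
        self.eos = GammaMieEoS(comps, groups=groups, db=db, mapping=mapping)
        self._ref_cache = {}

    def _references(self, T, P):
        key = (float(T), float(P))
        if key not in self._ref_cache:
            x_ref = thermo._reference_composition(self.eos, np.ones(8) / 8.0)
            x_ref = _neutralise(x_ref)
            ln_ref = thermo.ln_fugacity_coeff(self.eos, T, P, x_ref,
                                              phase="liquid")
            x_w = np.zeros(8)
            x_w[WATER] = 1.0
            ln_w = thermo.ln_fugacity_coeff(self.eos, T, P, x_w, phase="liquid")
            self._ref_cache[key] = (ln_ref, ln_w[WATER])
        return self._ref_cache[key]

    def evaluate(self, T, P, molalities):
        x = _x_from_molality(molalities)
        x = _neutralise(x)
        ln_ref, ln_w_pure = self._references(T, P)
        ln_phi = thermo.ln_fugacity_coeff(self.eos, T, P, x, phase="liquid")
        gam = x[WATER] * np.exp(ln_phi - ln_ref)
        gam[WATER] = 1.0
        if self.aw == "unity":
            a_w = 1.0
        else:
            a_w = x[WATER] * math.exp(ln_phi[WATER] - ln_w_pure)
        return gam, a_w


def _x_from_molality(m):
    """Mole fractions of the 8 species from molalities (mol/kg water)."""
    n = np.array(m, float)
    n[WATER] = 1.0 / 18.015e-3
    return n / n.sum()


def _neutralise(x, tol=1e-30):
    """Exact electroneutrality by adjusting the majority counterion."""
    x = np.array(x, float)
    q = float(x @ _SPECIES_CHARGE)
    if q > 0:
        x[CL] += q
    elif q < 0:
        x[NA] += -q
    return x / x.sum()


# ---------------------------------------------------------------------------
# problems and results


@dataclass
class SpeciationProblem:
    T: float
    P: float
    m_total: float          # total amino-acid molality, mol/kg water
    reactions: ReactionSet
    added_base: float = 0.0  # NaOH molality, fully dissociated
    added_acid: float = 0.0  # HCl molality, fully dissociated


@dataclass
class SpeciationResult:
    molalities: np.ndarray   # per species slot, mol/kg water
    pH: float
    xi: np.ndarray           # relative AA concentrations (zw, cat, an)
    oh_equivalents: float
    a_w: float
    converged: bool
    residual: float
    saturated: bool = False

    @property
    def m_AA(self) -> float:
        return float(self.molalities[[ZW, CAT, AN]].sum())


def _ideal_proton(reactions: ReactionSet, T, m_total, m_na, m_cl):
    """Proton molality of the ideal (gamma = 1, a_w = 1) diprotic system."""
    K1, K2, KW = reactions.at(T)

    def charge(log_h):
        h = 10.0 ** log_h
        D = h * h + K1 * h + K1 * K2
        f_cat, f_an = h * h / D, K1 * K2 / D
        return m_total * (f_cat - f_an) + h - KW / h + m_na - m_cl

    return 10.0 ** brentq(charge, -16.0, 2.0, xtol=1e-15)


def solve_speciation(problem: SpeciationProblem, activity_model=None,
                     tol=1e-10, max_iter=80) -> SpeciationResult:
    """Equilibrium speciation at fixed total amino acid and added acid/base.

    Newton iteration on the log-molalities of (AA+-, AA+, AA-, H3O+, OH-);
    Na+/Cl- are fixed by the added strong base/acid.
    """
    activity_model = activity_model or IdealActivities()
    rx = problem.reactions
    T, P = problem.T, problem.P
    K1, K2, KW = rx.at(T)
    m_na, m_cl = problem.added_base, problem.added_acid

    h0 = _ideal_proton(rx, T, problem.m_total, m_na, m_cl)
    D = h0 * h0 + K1 * h0 + K1 * K2
    m0 = problem.m_total * np.array([K1 * h0, h0 * h0, K1 * K2]) / D
    guess = np.array([m0[0], m0[1], m0[2], h0, KW / h0])
    u = np.log(np.maximum(guess, 1e-300))

    def residuals(u):
        m = np.zeros(8)
        m[[ZW, CAT, AN, H3O, OH]] = np.exp(u)
        m[NA], m[CL] = m_na, m_cl
        gam, a_w = activity_model.evaluate(T, P, m)
        ln_a = np.log(np.maximum(m * gam / M0_REF, 1e-300))
        r = np.empty(5)
        r[0] = ln_a[ZW] + ln_a[H3O] - ln_a[CAT] - math.log(a_w) - math.log(K1)
        r[1] = ln_a[AN] + ln_a[H3O] - ln_a[ZW] - math.log(a_w) - math.log(K2)
        r[2] = ln_a[H3O] + ln_a[OH] - 2.0 * math.log(a_w) - math.log(KW)
        r[3] = math.log(m[[ZW, CAT, AN]].sum() / problem.m_total)
        r[4] = (m[CAT] + m[H3O] + m[NA] - m[AN] - m[OH] - m[CL]) \
            / max(problem.m_total, 1e-7)
        return r, m, gam, a_w, ln_a

    r, m, gam, a_w, ln_a = residuals(u)
    for it in range(max_iter):
        norm = np.abs(r).max()
        if norm < tol:
            break
        J = np.empty((5, 5))
        for j in range(5):
            du = np.zeros(5)
            du[j] = 1e-7
            J[:, j] = (residuals(u + du)[0] - r) / 1e-7
        step = np.linalg.solve(J, r)
        lam, ok = 1.0, False
        for _ in range(30):
            try:
                r_try, m, gam, a_w, ln_a = residuals(u - lam * step)
            except (DomainError, ConvergenceError):
                lam *= 0.5
                continue
            if np.abs(r_try).max() < norm or lam < 1e-3:
                u = u - lam * step
                r = r_try
                ok = True
                break
            lam *= 0.5
        if not ok:
            break
    else:
        raise ConvergenceError(
            f"speciation solve: residual {np.abs(r).max():.2e} after "
            f"{max_iter} iterations")
    if np.abs(r).max() > 1e-6:
        raise ConvergenceError(
            f"speciation solve stalled, residual {np.abs(r).max():.2e}")

    pH = -math.log10(math.exp(ln_a[H3O]))
    m_aa = m[[ZW, CAT, AN]].sum()
    xi = m[[ZW, CAT, AN]] / m_aa
    z_aa = np.array([0.0, 1.0, -1.0])
    oh_eq = 1.0 - float(xi @ z_aa)
    return SpeciationResult(m, pH, xi, oh_eq, a_w, True, float(np.abs(r).max()))


def speciation_at_ph(T, P, m_total, pH, reactions: ReactionSet,
                     activity_model=None, tol=1e-10,
                     max_iter=80) -> SpeciationResult:
    """Speciation of an unsaturated solution at a target pH.

    The counterion (Na+ above the isoelectric point, Cl- below) is solved to
    reach the requested pH; the amino-acid total is held at ``m_total``.
    """
    activity_model = activity_model or IdealActivities()
    K1, K2, KW = reactions.at(T)
    pI_val = pI(pK(K1), pK(K2))
    a_h_target = 10.0 ** (-pH)

    h = a_h_target
    D = h * h + K1 * h + K1 * K2
    m0 = m_total * np.array([K1 * h, h * h, K1 * K2]) / D
    u = np.log(np.maximum(np.r_[m0, [h, KW / h]], 1e-300))

    def residuals(u):
        m = np.zeros(8)
        m[[ZW, CAT, AN, H3O, OH]] = np.exp(u)
        m = _close_counterion(m)
        gam, a_w = activity_model.evaluate(T, P, m)
        ln_a = np.log(np.maximum(m * gam / M0_REF, 1e-300))
        r = np.empty(5)
        r[0] = ln_a[ZW] + ln_a[H3O] - ln_a[CAT] - math.log(a_w) - math.log(K1)
        r[1] = ln_a[AN] + ln_a[H3O] - ln_a[ZW] - math.log(a_w) - math.log(K2)
        r[2] = ln_a[H3O] + ln_a[OH] - 2.0 * math.log(a_w) - math.log(KW)
        r[3] = math.log(m[[ZW, CAT, AN]].sum() / m_total)
        r[4] = ln_a[H3O] - math.log(a_h_target)
        return r, m, gam, a_w, ln_a

    return _newton_speciation(residuals, u, T, tol, max_iter)


def _close_counterion(m):
    """Close the charge balance with Na+ (excess negative charge) or Cl-."""
    q = float(m @ _SPECIES_CHARGE)
    if q > 0:
        m[CL] = q
    else:
        m[NA] = -q
    return m


def _newton_speciation(residuals, u, T, tol, max_iter):
    r, m, gam, a_w, ln_a = residuals(u)
    n = len(u)
    for it in range(max_iter):
        norm = np.abs(r).max()
        if norm < tol:
            break
        J = np.empty((n, n))
        for j in range(n):
            du = np.zeros(n)
            du[j] = 1e-7
            J[:, j] = (residuals(u + du)[0] - r) / 1e-7
        try:
            step = np.linalg.solve(J, r)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, r, rcond=None)[0]
        lam, improved = 1.0, False
        while lam > 1e-6:
            u_try = np.clip(u - lam * step, -690.0, 12.0)
            try:
                r_try, m, gam, a_w, ln_a = residuals(u_try)
            except (DomainError, ConvergenceError, ValueError):
                lam *= 0.5
                continue
            if np.all(np.isfinite(r_try)) and np.abs(r_try).max() < norm:
                u, r, improved = u_try, r_try, True
                break
            lam *= 0.5
        if not improved:
            break  # stalled; the residual check below decides
    if np.abs(r).max() > 1e-6:
        raise ConvergenceError(
            f"speciation solve stalled, residual {np.abs(r).max():.2e}")
    pH = -math.log10(math.exp(ln_a[H3O]))
    m_aa = m[[ZW, CAT, AN]].sum()
    xi = m[[ZW, CAT, AN]] / m_aa
    oh_eq = 1.0 - float(xi @ np.array([0.0, 1.0, -1.0]))
    return SpeciationResult(m, pH, xi, oh_eq, a_w, True, float(np.abs(r).max()))


def titration_curve(T, P, m_total, reactions: ReactionSet, ph_grid=None,
                    equivalents_grid=None, activity_model=None):
    """Series of speciation states along a titration.

    Either a pH grid or an OH-equivalents grid may be given; with an
    equivalents grid the matching pH is found by bisection (the relation is
    monotone)."""
    activity_model = activity_model or IdealActivities()
    if ph_grid is None and equivalents_grid is None:
        raise ValueError("provide ph_grid or equivalents_grid")
    out = []
    if ph_grid is not None:
        for ph in ph_grid:
            out.append(speciation_at_ph(T, P, m_total, ph, reactions,
                                        activity_model))
        return out
    for eq in equivalents_grid:
        def f(ph):
            return speciation_at_ph(T, P, m_total, ph, reactions,
                                    activity_model).oh_equivalents - eq
        ph = brentq(f, 0.5, 13.5, xtol=1e-9)
        out.append(speciation_at_ph(T, P, m_total, ph, reactions,
                                    activity_model))
    return out


def solubility_vs_ph(T, P, pH_values, reactions: ReactionSet,
                     melting: MeltingProperties, activity_model=None,
                     compound: str = "glycine", zw_gamma=None):
    """Total amino-acid solubility m_AA(pH) with the zwitterion pinned to
    solid-liquid equilibrium.

    Only the zwitterion's chemical potential is equated with the pure solid;
    the cation and anion add to the dissolved total through the acid-base
    equilibria. ``zw_gamma``: optional callable m_zw -> symmetric activity
    coefficient of the zwitterion at saturation composition (defaults to 1,
    the ideal-solution route); the mole-fraction solubility product
    x_zw * gamma_zw is fixed by the melting properties.
    """
    activity_model = activity_model or IdealActivities()
    x_zw_sat = math.exp(sle_rhs(T, melting))
    out = []
    for ph in pH_values:
        # solve m_zw such that x_zw(m) * gamma_zw(m) = x_zw_sat
        def sle_gap(log_mzw):
            m_zw = math.exp(log_mzw)
            res = _ph_state_with_fixed_zw(T, P, m_zw, ph, reactions,
                                          activity_model)
            x = _x_from_molality(res.molalities)
            gam = zw_gamma(res) if zw_gamma is not None else 1.0
            return math.log(x[ZW] * gam) - math.log(x_zw_sat), res
        lo = math.log(1e-8)
        flo = sle_gap(lo)[0]
        fhi = None
        for m_hi in (60.0, 30.0, 15.0):
            try:
                hi = math.log(m_hi)
                fhi = sle_gap(hi)[0]
                break
            except (ConvergenceError, np.linalg.LinAlgError):
                continue
        if fhi is None or flo * fhi > 0:
            raise DomainError(f"no saturation root at pH={ph}")
        log_mzw = brentq(lambda v: sle_gap(v)[0], lo, hi, xtol=1e-12)
        res = sle_gap(log_mzw)[1]
        out.append(res)
    return out


def _ph_state_with_fixed_zw(T, P, m_zw, pH, reactions, activity_model,
                            tol=1e-10, max_iter=60):
    """Speciation with the zwitterion molality held fixed and pH imposed."""
    K1, K2, KW = reactions.at(T)
    a_h = 10.0 ** (-pH)
    m_cat0 = m_zw * a_h / K1
    m_an0 = m_zw * K2 / a_h
    u = np.log(np.maximum(
        np.array([m_cat0, m_an0, a_h, KW / a_h]), 1e-300))

    def residuals(u):
        m = np.zeros(8)
        m[ZW] = m_zw
        m[[CAT, AN, H3O, OH]] = np.exp(u)
        m = _close_counterion(m)
        gam, a_w = activity_model.evaluate(T, P, m)
        ln_a = np.log(np.maximum(m * gam / M0_REF, 1e-300))
        r = np.empty(4)
        r[0] = ln_a[ZW] + ln_a[H3O] - ln_a[CAT] - math.log(a_w) - math.log(K1)
        r[1] = ln_a[AN] + ln_a[H3O] - ln_a[ZW] - math.log(a_w) - math.log(K2)
        r[2] = ln_a[H3O] + ln_a[OH] - 2.0 * math.log(a_w) - math.log(KW)
        r[3] = ln_a[H3O] - math.log(a_h)
        return r, m, gam, a_w, ln_a

    return _newton_speciation(residuals, u, T, tol, max_iter)
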