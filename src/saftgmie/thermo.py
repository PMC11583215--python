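"""Thermodynamic properties derived from the Helmholtz model.

Pressure and chemical potentials are obtained by complex-step
differentiation of the residual Helmholtz energy (exact to machine
precision), densities at given (T, P) from a scan-and-bracket root search on
the pressure isotherm, and activities in the two conventions used for
solution chemistry: symmetric (pure-liquid reference; used for water) and
asymmetric molality-based (infinite-dilution reference; used for solutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import K_B, M0_REF, N_A, R_GAS
from .eos import ConvergenceError, DomainError, GammaMieEoS

_CSTEP = 1e-100  # relative complex step


def pressure(eos: GammaMieEoS, T, V, n):
    """P (Pa) at fixed T, V, mole numbers: ideal part + residual -dA/dV."""
    n = np.asarray(n, float)
    h = V * _CSTEP
    dAdV = eos.a_residual_total(T, V + 1j * h, n.astype(complex)).imag / h
    return n.sum() * R_GAS * T / V - dAdV


def mu_residual(eos: GammaMieEoS, T, V, n):
    """Residual chemical potentials (J/mol) at fixed T, V."""
    n = np.asarray(n, float)
    out = np.empty(len(n))
    for i in range(len(n)):
        h = max(abs(n[i]), 1e-8 * n.sum()) * _CSTEP
        nc = n.astype(complex)
        nc[i] += 1j * h
        out[i] = eos.a_residual_total(T, V, nc).imag / h
    return out


def solve_density(eos: GammaMieEoS, T, P, x, phase=None, n_grid=200):
    """Molar density (mol/m^3) at (T, P, x).

    When the isotherm has several mechanically stable roots the one with the
    lowest Gibbs energy is returned unless ``phase`` forces ``"liquid"``
    (densest root) or ``"vapor"`` (least dense).
    """
    x = np.asarray(x, float)
    x = x / x.sum()
    rho_max = eos.max_density(T, x)
    rho_min = min(1e-8 * rho_max, P / (R_GAS * T) * 1e-6)
    grid = np.geomspace(rho_min, 0.999 * rho_max, n_grid)

    def p_of_rho(rho):
        with np.errstate(all="ignore"):
            try:
                p = pressure(eos, T, 1.0 / rho, x)
            except (DomainError, ConvergenceError, FloatingPointError):
                return np.inf
        return p if np.isfinite(p) else np.inf

    f = np.array([p_of_rho(r) - P for r in grid])
    roots = []
    for i in range(len(grid) - 1):
        if not (np.isfinite(f[i]) and np.isfinite(f[i + 1])):
            continue
        if np.sign(f[i]) * np.sign(f[i + 1]) < 0:
            rho = brentq(lambda r: p_of_rho(r) - P, grid[i], grid[i + 1],
                         xtol=1e-300, rtol=1e-15)
            roots.append(rho)
    if not roots:
        # monotone isotherm without crossing on grid: extend search downward
        raise DomainError(f"no density root at T={T}, P={P}")
    # mechanical stability: dP/drho > 0
    stable = []
    for rho in roots:
        drho = rho * 1e-6
        if p_of_rho(rho + drho) > p_of_rho(rho - drho):
            stable.append(rho)
    roots = stable or roots
    if phase == "liquid":
        return max(roots)
    if phase == "vapor":
        return min(roots)
    if len(roots) == 1:
        return roots[0]

    def gibbs(rho):
        V = 1.0 / rho
        a_res = eos.a_residual(T, V, x)
        z = P * V / (R_GAS * T)
        return np.log(rho) + a_res + z

    return min(roots, key=gibbs)


def ln_fugacity_coeff(eos: GammaMieEoS, T, P, x, phase=None, rho=None):
    """ln phi_i at (T, P, x)."""
    x = np.asarray(x, float)
    x = x / x.sum()
    if rho is None:
        rho = solve_density(eos, T, P, x, phase=phase)
    V = 1.0 / rho
    mu = mu_residual(eos, T, V, x)
    z = P * V / (R_GAS * T)
    return mu / (R_GAS * T) - np.log(z)


# ---------------------------------------------------------------------------
# molality / composition conversions


def molality_from_x(x, solvent_mask, molar_mass):
    """Molality (mol per kg of total solvent) of every component."""
    x = np.asarray(x, float)
    m_solv = (x * solvent_mask * molar_mass).sum()
    if m_solv <= 0:
        raise DomainError("zero solvent mass")
    return x / m_solv


def x_from_molality(m, solvent_mask, molar_mass, solvent_split=None):
    """Inverse of :func:`molality_from_x`.

    ``m`` holds the solute molalities (entries where ``solvent_mask`` is
    True are ignored); the solvent entries are filled so that one kilogram
    of solvent is distributed according to ``solvent_split`` (mole basis,
    default: single solvent)."""
    m = np.asarray(m, float)
    solvent_mask = np.asarray(solvent_mask, bool)
    n = m.copy()
    idx = np.where(solvent_mask)[0]
    if solvent_split is None:
        split = np.ones(len(idx)) / len(idx)
    else:
        split = np.asarray(solvent_split, float)
        split = split / split.sum()
    mw = (split * molar_mass[idx]).sum()
    n_solv_total = 1.0 / mw  # moles of solvent in 1 kg
    n[idx] = split * n_solv_total
    return n / n.sum()


# ---------------------------------------------------------------------------
# activities


@dataclass
class ActivityRecord:
    component: str
    convention: str
    gamma: float
    activity: float
    molality: float | None = None


def _reference_composition(eos, x, dilute=1e-15):
    """Infinite-dilution reference: every non-solvent at ``dilute``,
    solvents renormalised keeping their internal ratio."""
    x = np.asarray(x, float)
    solvent = np.array([c.is_solvent for c in eos.components])
    if not solvent.any():
        raise DomainError("asymmetric convention needs a solvent")
    x_ref = np.where(solvent, 0.0, dilute)
    x_solv = np.where(solvent, x, 0.0)
    if x_solv.sum() == 0:
        x_solv = solvent.astype(float)
    x_ref = x_ref + x_solv / x_solv.sum() * (1.0 - x_ref.sum())
    return x_ref


def activity_asymmetric(eos: GammaMieEoS, T, P, x, i, rho=None,
                        ln_phi_ref=None):
    """Asymmetric molality-based activity of solute ``i``.

    gamma_m,i = x_solv * phi_i(x) / phi_i(x_inf); a_i = m_i gamma / m0.
    """
    x = np.asarray(x, float)
    solvent = np.array([c.is_solvent for c in eos.components])
    if solvent[i]:
        raise DomainError("asymmetric convention is for solutes, not solvents")
    ln_phi = ln_fugacity_coeff(eos, T, P, x, phase="liquid", rho=rho)
    if ln_phi_ref is None:
        x_ref = _reference_composition(eos, x)
        ln_phi_ref = ln_fugacity_coeff(eos, T, P, x_ref, phase="liquid")
    gamma = x[solvent].sum() * np.exp(ln_phi[i] - ln_phi_ref[i])
    m = molality_from_x(x, solvent, eos.molar_mass)
    return ActivityRecord(eos.components[i].name, "asymmetric-molality",
                          float(gamma), float(m[i] * gamma / M0_REF),
                          float(m[i]))


def activity_water(eos: GammaMieEoS, T, P, x, water_index=None, rho=None,
                   ln_phi_pure=None):
    """Symmetric-convention water activity a_w = x_w gamma_w."""
    x = np.asarray(x, float)
    if water_index is None:
        names = [c.name for c in eos.components]
        water_index = names.index("water")
    ln_phi = ln_fugacity_coeff(eos, T, P, x, phase="liquid", rho=rho)
    if ln_phi_pure is None:
        x_pure = np.zeros(len(x))
        x_pure[water_index] = 1.0
        ln_phi_pure = ln_fugacity_coeff(eos, T, P, x_pure, phase="liquid")
    gamma = np.exp(ln_phi[water_index] - ln_phi_pure[water_index])
    return ActivityRecord("water", "symmetric", float(gamma),
                          float(x[water_index] * gamma))


def gibbs_duhem_residual(eos: GammaMieEoS, T, P, x, step=1e-5):
    """|sum_i x_i d mu_i| / RT along a random composition direction at
    constant T, P (finite difference); a consistency diagnostic."""
    x = np.asarray(x, float)
    nc = len(x)
    rng = np.random.default_rng(0)
    direction = rng.standard_normal(nc)
    direction -= direction.mean()  # keep sum x = 1
    direction /= np.linalg.norm(direction)

    def mu_total(xx):
        xx = np.clip(xx, 1e-14, None)
        xx = xx / xx.sum()
        rho = solve_density(eos, T, P, xx, phase="liquid")
        mu = mu_residual(eos, T, 1.0 / rho, xx) / (R_GAS * T)
        return mu + np.log(xx * rho)

    mu_p = mu_total(x + step * direction)
    mu_m = mu_total(x - step * direction)
    dmu = (mu_p - mu_m) / (2 * step)
    return abs(float(x @ dmu))
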