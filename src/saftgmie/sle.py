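"""Solid-liquid equilibrium (solubility) and a bubble-pressure utility.

The solubility of a solute crystallising as a pure solid follows from
equating its solid and subcooled-liquid chemical potentials:

    ln(x_sat gamma) = -(dh_fus/R)(1/T - 1/T_fus)
                      + (dcp/R)(T_fus/T - 1 - ln(T_fus/T))

with gamma the symmetric-convention activity coefficient at saturation.
The heat-capacity term is retained only when a dcp value is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import R_GAS
from .eos import DomainError, GammaMieEoS
from .parameters import load_melting
from . import thermo


@dataclass(frozen=True)
class MeltingProperties:
    """Fusion temperature (K), enthalpy (kJ/mol) and optional heat-capacity
    difference liquid-solid at T_fus (J/mol/K)."""

    T_fus: float
    dh_fus: float
    dcp: float | None = None

    def __post_init__(self):
        if self.T_fus <= 0 or self.dh_fus < 0:
            raise ValueError("invalid melting properties")

    @classmethod
    def from_table(cls, solute: str, path=None) -> "MeltingProperties":
        row = load_melting(path).loc[solute]
        dcp = row["dcp_JmolK"]
        return cls(float(row["T_fus_K"]), float(row["dh_fus_kJmol"]),
                   None if np.isnan(dcp) else float(dcp))


@dataclass
class SolubilityResult:
    x_sat: float
    gamma_at_sat: float
    converged: bool
    residual: float


def sle_rhs(T, mp: MeltingProperties) -> float:
    """Right-hand side ln(x gamma) of the solubility equation."""
    val = -(mp.dh_fus * 1e3 / R_GAS) * (1.0 / T - 1.0 / mp.T_fus)
    if mp.dcp is not None:
        u = mp.T_fus / T
        val += (mp.dcp / R_GAS) * (u - 1.0 - math.log(u))
    return val


def ideal_solubility(T, mp: MeltingProperties) -> float:
    """Saturation mole fraction with gamma = 1 (capped at 1 above T_fus)."""
    return min(1.0, math.exp(sle_rhs(T, mp)))


def solve_sle(eos: GammaMieEoS, T, P, solvent_x, solute_index,
              mp: MeltingProperties, x_lo=1e-10, x_hi=0.95,
              tol=1e-10) -> SolubilityResult:
    """Saturation composition of ``solute_index`` in the given solvents.

    ``solvent_x`` is the solute-free solvent composition over all components
    (its entry at ``solute_index`` is ignored). The solute activity
    coefficient is symmetric, referenced to its pure subcooled liquid.
    """
    solvent_x = np.asarray(solvent_x, float).copy()
    solvent_x[solute_index] = 0.0
    if solvent_x.sum() <= 0:
        raise DomainError("no solvent composition given")
    solvent_x /= solvent_x.sum()
    rhs = sle_rhs(T, mp)

    x_pure = np.zeros(len(solvent_x))
    x_pure[solute_index] = 1.0
    ln_phi_pure = thermo.ln_fugacity_coeff(eos, T, P, x_pure, phase="liquid")

    def mix(x_solute):
        x = solvent_x * (1.0 - x_solute)
        x[solute_index] = x_solute
        return x

    def residual(ln_x):
        x_solute = math.exp(ln_x)
        ln_phi = thermo.ln_fugacity_coeff(eos, T, P, mix(x_solute),
                                          phase="liquid")
        ln_gamma = ln_phi[solute_index] - ln_phi_pure[solute_index]
        return ln_x + ln_gamma - rhs

    grid = np.log(np.geomspace(x_lo, x_hi, 40))
    f_prev = residual(grid[0])
    bracket = None
    for lo, hi in zip(grid[:-1], grid[1:]):
        f_next = residual(hi)
        if np.sign(f_prev) * np.sign(f_next) <= 0:
            bracket = (lo, hi, f_prev, f_next)
            break
        f_prev = f_next
    if bracket is None:
        raise DomainError(
            "no solid-liquid equilibrium root in (0, 1): the mixture appears "
            "fully miscible or immiscible over the search range"
        )
    ln_x = brentq(residual, bracket[0], bracket[1], xtol=tol)
    x_sat = math.exp(ln_x)
    ln_phi = thermo.ln_fugacity_coeff(eos, T, P, mix(x_sat), phase="liquid")
    gamma = math.exp(ln_phi[solute_index] - ln_phi_pure[solute_index])
    res = ln_x + math.log(gamma) - rhs
    return SolubilityResult(x_sat, gamma, abs(res) < 1e-8, res)


def vapor_pressure(eos: GammaMieEoS, T, component=0, p_lo=1.0, p_hi=5e7,
                   n_scan=120):
    """Pure-component saturation pressure by isofugacity.

    Scans ln P for a sign change of ln phi_L - ln phi_V restricted to
    pressures where distinct vapor and liquid density roots exist, then
    refines with Brent's method.
    """
    x = np.zeros(len(eos.components))
    x[component] = 1.0

    def dlnphi(P):
        rho_l = thermo.solve_density(eos, T, P, x, phase="liquid")
        rho_v = thermo.solve_density(eos, T, P, x, phase="vapor")
        if abs(rho_l - rho_v) / rho_l < 1e-6:
            return None  # single phase at this pressure
        lp_l = thermo.ln_fugacity_coeff(eos, T, P, x, rho=rho_l)
        lp_v = thermo.ln_fugacity_coeff(eos, T, P, x, rho=rho_v)
        return lp_l[component] - lp_v[component]

    grid = np.geomspace(p_lo, p_hi, n_scan)
    prev = None
    for P in grid:
        try:
            val = dlnphi(P)
        except DomainError:
            val = None
        if val is None:
            continue
        if prev is not None and np.sign(prev[1]) * np.sign(val) < 0:
            return brentq(lambda p: dlnphi(p), prev[0], P, rtol=1e-12)
        prev = (P, val)
    raise DomainError(f"no vapor-liquid coexistence found at T={T}")


def bubble_pressure(eos: GammaMieEoS, T, x, p_init=None, tol=1e-10,
                    max_iter=200):
    """Bubble pressure and vapor composition at (T, x) by isofugacity.

    Successive substitution on K_i = phi_i^L / phi_i^V with a pressure
    update from the summation condition sum y = 1.
    """
    x = np.asarray(x, float)
    x = x / x.sum()
    P = p_init if p_init is not None else 1e5
    y = x.copy()
    for it in range(max_iter):
        ln_phi_l = thermo.ln_fugacity_coeff(eos, T, P, x, phase="liquid")
        ln_phi_v = thermo.ln_fugacity_coeff(eos, T, P, y, phase="vapor")
        K = np.exp(ln_phi_l - ln_phi_v)
        s = (K * x).sum()
        y_new = K * x / s
        P_new = P * s
        if abs(P_new - P) / P < tol and np.abs(y_new - y).max() < tol:
            y, P = y_new, P_new
            break
        y, P = y_new, 0.5 * (P + P_new) if it < 5 else P_new
    else:
        raise DomainError("bubble-pressure iteration did not converge")
    rho_l = thermo.solve_density(eos, T, P, x, phase="liquid")
    rho_v = thermo.solve_density(eos, T, P, y, phase="vapor")
    if abs(rho_l - rho_v) / rho_l < 1e-4:
        raise DomainError("bubble-pressure solve collapsed to a trivial root")
    return P, y


def aad_metrics(calc, exp):
    """(%AAD, AAD) between calculated and experimental series.

    %AAD = 100/N sum |X_exp - X_cal| / X_exp ; zero experimental values are
    excluded from the percentage metric with a warning.
    """
    calc = np.asarray(calc, float)
    exp = np.asarray(exp, float)
    if calc.shape != exp.shape:
        raise ValueError("series lengths differ")
    adev = np.abs(exp - calc)
    aad = adev.mean()
    nz = exp != 0
    if not nz.all():
        warnings.warn("zero experimental values excluded from %AAD")
    pct = 100.0 * (adev[nz] / np.abs(exp[nz])).mean() if nz.any() else math.nan
    return pct, aad
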