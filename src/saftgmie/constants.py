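"""Physical constants and group molar masses (SI units)."""

from scipy.constants import (
    Avogadro as N_A,
    Boltzmann as K_B,
    R as R_GAS,
    e as E_CHARGE,
    epsilon_0 as EPS_0,
    pi as PI,
)

ANGSTROM = 1e-10  # m
ANGSTROM3 = 1e-30  # m^3

#: reference molality for the asymmetric activity convention, mol/kg
M0_REF = 1.0

#: molar masses of the functional groups, kg/mol
GROUP_MASS = {
    "H2O": 18.015e-3,
    "COOH": 45.018e-3,
    "NH2": 16.023e-3,
    "CH3": 15.035e-3,
    "CH2": 14.027e-3,
    "CH": 13.019e-3,
    "CH2OH": 31.034e-3,
    "CHOH": 30.026e-3,
    "CONH": 43.025e-3,
    "COO-": 44.010e-3,
    "NH3+": 17.031e-3,
    "H3O+": 19.023e-3,
    "OH-": 17.007e-3,
    "Na+": 22.990e-3,
    "Cl-": 35.453e-3,
}

#: water autoionisation: 2 H2O <-> H3O+ + OH-  (reference 298.15 K)
KW_298 = 1.0077e-14
DH_W = 56.149e3  # J/mol, protonation enthalpy of the water reaction
T_REF = 298.15  # K

__all__ = [
    "N_A", "K_B", "R_GAS", "E_CHARGE", "EPS_0", "PI",
    "ANGSTROM", "ANGSTROM3", "M0_REF", "GROUP_MASS",
    "KW_298", "DH_W", "T_REF",
]
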