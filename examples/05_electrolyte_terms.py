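"""Electrostatic contributions for aqueous NaCl.

Shows the MSA screening parameter against its Debye-Hueckel limit, the ion
and Born free-energy terms, and the equivalence of the group (G) and
molecular (M) sphere mappings for monatomic ions.
"""

import numpy as np

from saftgmie import GammaMieEoS, ion, solve_density, water
from saftgmie import electrolyte as el

comps = [water(), ion("sodium"), ion("chloride")]
T, P = 298.15, 1.0e5

for x_salt in (1e-4, 0.01, 0.03):
    x = np.array([1 - 2 * x_salt, x_salt, x_salt])
    eos = GammaMieEoS(comps, mapping="G")
    rho = solve_density(eos, T, P, x, phase="liquid")
    V = 1.0 / rho
    D = eos.relative_permittivity(T, V, x)
    pk = eos._packing(T, V, x)
    rho_e = pk["rho"] * (eos.ion_map.counts @ x)
    scr = el.solve_screening(rho_e, eos.ion_map.charges,
                             eos.ion_map.sigma_msa, D, T)
    kd = el.debye_kappa(rho_e, eos.ion_map.charges, D, T)
    parts = eos.a_residual(T, V, x, parts=True)
    print(f"x_salt = {x_salt}: D = {D:.1f}  Gamma = {scr.gamma:.3e} 1/m "
          f"(kappa_D/2 = {kd / 2:.3e})")
    print(f"   a_ion = {parts['ion']: .5f}   a_born = {parts['born']: .5f}")
# Gamma approaches kappa_D/2 at high dilution; the Born term dominates the
# ionic free energy because solvation in a D ~ 78 medium is strong.
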