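"""Aqueous solubility of neutral amino-acid models.

Assembles glycine and valine from functional groups, then solves the
solid-liquid equilibrium ln(x gamma) = -(dh_fus/R)(1/T - 1/T_fus) at 298 K
using activity coefficients from the full free-energy model. The printed
gamma is the symmetric activity coefficient at saturation (pure subcooled
liquid reference); x_ideal is the gamma = 1 solution.
"""

from saftgmie import (GammaMieEoS, MeltingProperties, amino_acid,
                      ideal_solubility, solve_sle, water)

T, P = 298.15, 1.0e5
for name in ("glycine", "valine"):
    solute = amino_acid(name)
    groups = ", ".join(f"{c}x{g.name}" for g, c in solute.groups)
    eos = GammaMieEoS([water(), solute])
    melting = MeltingProperties.from_table(name)
    res = solve_sle(eos, T, P, [1.0, 0.0], 1, melting)
    print(f"{name} ({groups})")
    print(f"  T_fus = {melting.T_fus} K, dh_fus = {melting.dh_fus} kJ/mol")
    print(f"  x_ideal = {ideal_solubility(T, melting):.4g}   "
          f"x_sat = {res.x_sat:.4g}   gamma = {res.gamma_at_sat:.4g}")
# gamma > 1 means the melt is penalised in water relative to its own
# liquid; the hydrophobic side chain of valine pushes gamma far above
# glycine's value, hence its much lower solubility.
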