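"""Glycine solubility as a function of pH.

Couples the zwitterion's solid-liquid equilibrium to the acid-base
equilibria: at each pH only the zwitterion's chemical potential is equated
with the pure solid, while the cation and anion (balanced by Cl- or Na+
counterions) add to the dissolved total m_AA = m_zw + m_cat + m_an. The
curve has its minimum at the isoelectric point and rises on both sides.
Ideal activities keep this example fast; SaftActivities drops in for the
full model.
"""

import numpy as np

from saftgmie import (IdealActivities, MeltingProperties, ReactionSet, pI,
                      pK, solubility_vs_ph)

rx = ReactionSet.from_table("glycine")
melting = MeltingProperties.from_table("glycine")
pi_val = pI(pK(rx.K_A1), pK(rx.K_A2))
ideal = IdealActivities(aw="unity")

for T in (298.15, 348.15):
    K1, K2, _ = rx.at(T)
    pi_T = pI(pK(K1), pK(K2))
    print(f"T = {T} K (pI = {pi_T:.2f})")
    # stay below pH ~9.5: with ideal activities the anion branch grows so
    # fast that no finite saturation exists at the alkaline extreme
    for ph in np.arange(2.0, 9.01, 1.0):
        r = solubility_vs_ph(T, 1e5, [ph], rx, melting, ideal)[0]
        print(f"  pH {ph:4.1f}: m_AA = {r.m_AA:8.4f} mol/kg  "
              f"xi = ({r.xi[1]:.3f}, {r.xi[0]:.3f}, {r.xi[2]:.3f})")
# the higher temperature shifts the whole profile up (higher solubility)
# and to the left (lower pKs), as the melting term and the van 't Hoff
# corrections dictate.
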