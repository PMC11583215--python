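"""Acid-base titration of glycine and the diprotic speciation diagram.

Uses the tabulated equilibrium constants (pK_A1 = 2.34, pK_A2 = 9.60 at
298.15 K) with ideal activities: the relative concentrations of cation,
zwitterion and anion as a function of pH, and the OH-equivalents consumed,
computed from the population-averaged net charge.
"""

import numpy as np

from saftgmie import (IdealActivities, ReactionSet, pI, pK, speciation_at_ph,
                      titration_curve)

rx = ReactionSet.from_table("glycine")
print(f"pK_A1 = {pK(rx.K_A1):.3f}, pK_A2 = {pK(rx.K_A2):.3f}, "
      f"pI = {pI(pK(rx.K_A1), pK(rx.K_A2)):.3f}")
K1, K2, _ = rx.at(348.15)
print(f"at 348.15 K: pK_A1 = {pK(K1):.3f}, pK_A2 = {pK(K2):.3f}")

ideal = IdealActivities(aw="unity")
print("\n pH   xi_cation  xi_zwit  xi_anion  OH-equivalents")
for ph in np.arange(1.0, 13.0, 1.5):
    r = speciation_at_ph(298.15, 1e5, 0.147, ph, rx, ideal)
    print(f"{ph:4.1f}   {r.xi[1]:8.4f} {r.xi[0]:8.4f} {r.xi[2]:9.4f}"
          f"   {r.oh_equivalents:8.4f}")

# the half-equivalence points recover the pKs (buffer midpoints)
for eq in (0.5, 1.0, 1.5):
    r = titration_curve(298.15, 1e5, 0.147, rx, equivalents_grid=[eq],
                        activity_model=ideal)[0]
    print(f"OH-equivalents {eq}: pH = {r.pH:.3f}")
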