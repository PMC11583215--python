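"""Self-contained toy parameter sets with closed-form behavior.

These fixtures exist for validation: each kind isolates one physical
ingredient of the model against an analytic oracle (ideal gas, hard spheres
vs Carnahan-Starling, a bare Mie fluid, the restricted primitive model for
the MSA screening length, and an ideal diprotic ampholyte).
"""

from __future__ import annotations

from .parameters import Component, GroupSpec, InteractionDB, build_component

KINDS = ("ideal-gas", "hard-sphere", "lj-like-mie", "rpm-electrolyte",
         "diprotic-ideal")


def make_fixture(kind: str) -> dict:
    """Return a dict with ``groups``, ``db`` and ``components`` (and
    ``reactions`` for the diprotic kind)."""
    if kind == "ideal-gas":
        # sigma = 0 switches off every interaction: exact ideal gas
        g = GroupSpec("IG", 1, 1.0, 0.0, 12.0, 6.0, 0.0)
        groups = {"IG": g}
        comp = build_component("idealgas", {"IG": 1}, groups)
        return dict(groups=groups, db=InteractionDB(), components=[comp])
    if kind == "hard-sphere":
        # epsilon = 0 keeps the repulsive core with d = sigma and no attraction
        g = GroupSpec("HS", 1, 1.0, 3.0, 12.0, 6.0, 0.0)
        groups = {"HS": g}
        comp = build_component("hardsphere", {"HS": 1}, groups)
        return dict(groups=groups, db=InteractionDB(), components=[comp])
    if kind == "lj-like-mie":
        g = GroupSpec("LJ", 1, 1.0, 3.0, 12.0, 6.0, 150.0)
        groups = {"LJ": g}
        comp = build_component("mie126", {"LJ": 1}, groups)
        return dict(groups=groups, db=InteractionDB(), components=[comp])
    if kind == "rpm-electrolyte":
        # equal-diameter +-1 ions in a structureless dielectric solvent
        solv = GroupSpec("SOLV", 1, 1.0, 0.0, 12.0, 6.0, 0.0)
        cat = GroupSpec("CAT+", 1, 1.0, 4.0, 12.0, 6.0, 0.0, charge=1,
                        sigma_born=4.28)
        ani = GroupSpec("ANI-", 1, 1.0, 4.0, 12.0, 6.0, 0.0, charge=-1,
                        sigma_born=4.28)
        groups = {"SOLV": solv, "CAT+": cat, "ANI-": ani}
        comps = [
            build_component("solvent", {"SOLV": 1}, groups, solvent=True,
                            dielectric=(100.0, 1500.0)),
            build_component("cation", {"CAT+": 1}, groups),
            build_component("anion", {"ANI-": 1}, groups),
        ]
        return dict(groups=groups, db=InteractionDB(), components=comps)
    if kind == "diprotic-ideal":
        from .speciation import ReactionSet
        return dict(reactions=ReactionSet(K_A1=1.0e-3, dh_A1=50.0e3,
                                          K_A2=1.0e-9, dh_A2=40.0e3))
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
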