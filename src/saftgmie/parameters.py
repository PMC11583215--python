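"""Group-parameter database: like, unlike and association parameters of the
functional groups, combining rules, and molecule construction.

Groups are fused-sphere Mie segments: ``nu_star`` identical segments of
diameter ``sigma`` contribute to the molecular free energy with a fractional
shape factor ``S``. Charged groups additionally carry an integer charge and a
Born (solvated-cavity) diameter. Association sites of types H, e1 and e2
mediate hydrogen bonding.

The packaged CSV files transcribe the interaction tables this model ships
with; entries marked ``CR`` are generated from the standard combining rules

    sigma_kl = (sigma_kk + sigma_ll) / 2
    eps_kl   = sqrt(sigma_kk^3 sigma_ll^3) / sigma_kl^3 * sqrt(eps_kk eps_ll)
    lam_kl   = 3 + sqrt((lam_kk - 3)(lam_ll - 3))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .constants import GROUP_MASS

SITE_TYPES = ("H", "e1", "e2")

#: group aliases: a distinct name that inherits all parameters of the target
#: group unless an interaction is stored for the alias itself. ``CH2_adj``
#: marks a CH2 unit bonded to a carboxylate, whose interaction with COO- is
#: the stored adjacent-CH2 value.
GROUP_ALIASES = {"CH2_adj": "CH2"}


class ParameterError(ValueError):
    """Malformed or inconsistent parameter input."""


@dataclass(frozen=True)
class GroupSpec:
    """Like parameters of one functional group."""

    name: str
    nu_star: int
    shape_factor: float
    sigma: float            # segment diameter, Angstrom
    lambda_r: float
    lambda_a: float
    epsilon_over_kB: float  # dispersion energy / k_B, K
    charge: int = 0
    sigma_born: float | None = None  # Born cavity diameter, Angstrom
    sites: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma < 0:
            raise ParameterError(f"{self.name}: sigma must be non-negative")
        if self.sigma > 0 and not self.lambda_r > self.lambda_a >= 3:
            raise ParameterError(f"{self.name}: need lambda_r > lambda_a >= 3")
        if self.epsilon_over_kB < 0:
            raise ParameterError(f"{self.name}: epsilon/kB must be >= 0")
        if self.nu_star < 1:
            raise ParameterError(f"{self.name}: nu_star must be >= 1")
        if not 0 < self.shape_factor <= 1.5:
            raise ParameterError(f"{self.name}: shape factor outside (0, 1.5]")
        if self.charge != 0 and self.sigma_born is None:
            raise ParameterError(f"{self.name}: charged group needs a Born diameter")
        if any(v < 0 or int(v) != v for v in self.sites.values()):
            raise ParameterError(f"{self.name}: site counts must be non-negative ints")

    @property
    def n_sites(self) -> int:
        return sum(self.sites.values())

    def with_born_default(self) -> "GroupSpec":
        """Return self, filling sigma_born = 1.07 sigma for charged groups."""
        if self.charge != 0 and self.sigma_born is None:
            return GroupSpec(**{**self.__dict__, "sigma_born": 1.07 * self.sigma})
        return self


def _pair_key(k: str, l: str) -> tuple[str, str]:
    return (k, l) if k <= l else (l, k)


def _assoc_key(k: str, a: str, l: str, b: str):
    return ((k, a), (l, b)) if (k, a) <= (l, b) else ((l, b), (k, a))


@dataclass
class InteractionDB:
    """Unlike dispersion and association parameters with provenance.

    ``dispersion`` maps a sorted group-name pair to
    ``(epsilon_K | None, lambda_r | None, provenance)`` where ``None`` means
    "use the combining rule" for that entry. ``association`` maps a sorted
    (group, site) pair to ``(eps_HB_K, K_HB_A3, provenance)``; a value of
    ``None`` requests the association combining rule.
    """

    dispersion: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)

    def set_dispersion(self, k, l, epsilon_K, lambda_r, provenance="fitted"):
        key = _pair_key(k, l)
        existing = self.dispersion.get(key)
        new = (epsilon_K, lambda_r, provenance)
        if existing is not None and existing[:2] != new[:2]:
            raise ParameterError(f"conflicting duplicate dispersion entry for {key}")
        self.dispersion[key] = new

    def set_association(self, k, a, l, b, eps_HB, K_HB, provenance="fitted"):
        key = _assoc_key(k, a, l, b)
        existing = self.association.get(key)
        new = (eps_HB, K_HB, provenance)
        if existing is not None and existing[:2] != new[:2]:
            raise ParameterError(f"conflicting duplicate association entry for {key}")
        self.association[key] = new

    def _dealias(self, name: str) -> list[str]:
        """Lookup order for a group name: itself, then its alias target."""
        return [name, GROUP_ALIASES[name]] if name in GROUP_ALIASES else [name]

    def dispersion_entry(self, k: str, l: str):
        for kk in self._dealias(k):
            for ll in self._dealias(l):
                hit = self.dispersion.get(_pair_key(kk, ll))
                if hit is not None:
                    return hit
        return None

    def association_entry(self, k: str, a: str, l: str, b: str):
        for kk in self._dealias(k):
            for ll in self._dealias(l):
                hit = self.association.get(_assoc_key(kk, a, ll, b))
                if hit is not None:
                    return hit
        return None


def combining_sigma(sk: float, sl: float) -> float:
    return 0.5 * (sk + sl)


def combining_epsilon(gk: GroupSpec, gl: GroupSpec) -> float:
    s_kl = combining_sigma(gk.sigma, gl.sigma)
    if s_kl == 0:
        return math.sqrt(gk.epsilon_over_kB * gl.epsilon_over_kB)
    return (
        math.sqrt(gk.sigma ** 3 * gl.sigma ** 3) / s_kl ** 3
        * math.sqrt(gk.epsilon_over_kB * gl.epsilon_over_kB)
    )


def combining_lambda(lk: float, ll: float) -> float:
    return 3.0 + math.sqrt((lk - 3.0) * (ll - 3.0))


def resolve_unlike(gk: GroupSpec, gl: GroupSpec, db: InteractionDB):
    """Resolve the unlike Mie parameters of a group pair.

    Returns ``(epsilon_K, lambda_r, lambda_a, sigma_A, provenance)``; stored
    table values take precedence, combining rules fill the rest.
    """
    if gk.name == gl.name:
        return (gk.epsilon_over_kB, gk.lambda_r, gk.lambda_a, gk.sigma, "like")
    entry = db.dispersion_entry(gk.name, gl.name) or (None, None, "CR")
    eps, lam_r, prov = entry
    if eps is None:
        eps = combining_epsilon(gk, gl)
    if lam_r is None:
        lam_r = combining_lambda(gk.lambda_r, gl.lambda_r)
    lam_a = combining_lambda(gk.lambda_a, gl.lambda_a)
    return (eps, lam_r, lam_a, combining_sigma(gk.sigma, gl.sigma), prov)


def resolve_association(gk: GroupSpec, a: str, gl: GroupSpec, b: str,
                        db: InteractionDB):
    """Resolve (eps_HB_K, K_HB_A3) for a site pair, or ``None`` if the sites
    do not associate. Entries flagged CR use the association combining rules
    built from the like site-pair parameters of the two groups."""
    entry = db.association_entry(gk.name, a, gl.name, b)
    if entry is None:
        return None
    eps, k_hb, prov = entry
    if eps is not None:
        return (eps, k_hb, prov)
    like_k = db.association_entry(gk.name, a, gk.name, b)
    like_l = db.association_entry(gl.name, a, gl.name, b)
    if like_k is None or like_l is None or like_k[0] is None or like_l[0] is None:
        raise ParameterError(
            f"association CR for ({gk.name}:{a}, {gl.name}:{b}) needs both "
            "like site-pair entries"
        )
    s_kl = combining_sigma(gk.sigma, gl.sigma)
    eps_cr = (
        math.sqrt(like_k[0] * like_l[0])
        * math.sqrt(gk.sigma ** 3 * gl.sigma ** 3) / s_kl ** 3
    )
    k_cr = ((like_k[1] ** (1 / 3) + like_l[1] ** (1 / 3)) / 2.0) ** 3
    return (eps_cr, k_cr, "CR")


@dataclass(frozen=True)
class Component:
    """A molecule as a multiset of groups with charge bookkeeping."""

    name: str
    groups: tuple  # tuple of (GroupSpec, count)
    net_charge: int = 0
    is_zwitterion: bool = False
    is_solvent: bool = False
    dielectric_dV: float | None = None  # A^3
    dielectric_dT: float | None = None  # K

    @property
    def molar_mass(self) -> float:
        """kg/mol from the group masses; NaN for synthetic test groups."""
        total = 0.0
        for g, count in self.groups:
            base = GROUP_ALIASES.get(g.name, g.name)
            mass = GROUP_MASS.get(base)
            if mass is None:
                return float("nan")
            total += count * mass
        return total

    @property
    def group_charge_sum(self) -> int:
        return sum(count * g.charge for g, count in self.groups)


def build_component(name: str, group_counts: Mapping[str, int],
                    groups: Mapping[str, GroupSpec], *,
                    zwitterion: bool = False, solvent: bool = False,
                    dielectric: tuple[float, float] | None = None) -> Component:
    """Assemble a Component from group names and counts.

    The net charge is the sum of group charges; a zwitterion must have a zero
    group-charge sum and is assigned net charge zero; a solvent may not
    contain charged groups.
    """
    pairs = []
    for gname, count in group_counts.items():
        if gname not in groups:
            raise ParameterError(f"unknown group {gname!r} in {name}")
        if count < 1 or int(count) != count:
            raise ParameterError(f"{name}: group count for {gname} must be >= 1")
        pairs.append((groups[gname], int(count)))
    z = sum(c * g.charge for g, c in pairs)
    if zwitterion:
        if z != 0:
            raise ParameterError(
                f"{name}: zwitterion flag requires zero group-charge sum, got {z}"
            )
        if solvent:
            raise ParameterError(f"{name}: a zwitterion cannot be a solvent")
    if solvent and any(g.charge != 0 for g, _ in pairs):
        raise ParameterError(f"{name}: a solvent cannot contain charged groups")
    dV, dT = dielectric if dielectric is not None else (None, None)
    return Component(
        name=name, groups=tuple(pairs), net_charge=0 if zwitterion else z,
        is_zwitterion=zwitterion, is_solvent=solvent,
        dielectric_dV=dV, dielectric_dT=dT,
    )


# ---------------------------------------------------------------------------
# loading


def _parse_value(raw):
    """Numeric cell, or None for a CR marker / blank."""
    if raw is None:
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("cr", "nan"):
        return None
    return float(text)


def load_parameter_db(groups_file, unlike_file, association_file):
    """Read the three parameter tables.

    Returns ``(groups, db)`` with ``groups`` a name -> GroupSpec mapping
    (aliases included) and ``db`` the InteractionDB.
    """
    gdf = pd.read_csv(groups_file, comment="#", skipinitialspace=True)
    groups: dict[str, GroupSpec] = {}
    for idx, row in gdf.iterrows():
        try:
            sites = {a: int(row[f"n_{a}"]) if pd.notna(row[f"n_{a}"]) else 0
                     for a in SITE_TYPES}
            born = _parse_value(row.get("sigma_born_A"))
            spec = GroupSpec(
                name=str(row["name"]).strip(),
                nu_star=int(row["nu_star"]),
                shape_factor=float(row["shape_factor"]),
                sigma=float(row["sigma_A"]),
                sigma_born=born,
                lambda_r=float(row["lambda_r"]),
                lambda_a=float(row["lambda_a"]),
                epsilon_over_kB=float(row["epsilon_K"]),
                charge=int(row["charge"]),
                sites={a: n for a, n in sites.items() if n > 0},
            ).with_born_default()
        except (ValueError, KeyError) as exc:
            raise ParameterError(f"{groups_file}: bad group row {idx + 2}: {exc}") from exc
        groups[spec.name] = spec

    for alias, target in GROUP_ALIASES.items():
        if target in groups:
            base = groups[target]
            groups[alias] = GroupSpec(**{**base.__dict__, "name": alias})

    db = InteractionDB()
    udf = pd.read_csv(unlike_file, comment="#", skipinitialspace=True)
    for idx, row in udf.iterrows():
        k, l = str(row["group_k"]).strip(), str(row["group_l"]).strip()
        if k not in groups or l not in groups:
            raise ParameterError(f"{unlike_file}: row {idx + 2}: unknown group")
        try:
            db.set_dispersion(k, l, _parse_value(row["epsilon_K"]),
                              _parse_value(row["lambda_r"]),
                              str(row.get("provenance", "fitted")))
        except ValueError as exc:
            raise ParameterError(f"{unlike_file}: bad row {idx + 2}: {exc}") from exc

    adf = pd.read_csv(association_file, comment="#", skipinitialspace=True)
    for idx, row in adf.iterrows():
        k, l = str(row["group_k"]).strip(), str(row["group_l"]).strip()
        a, b = str(row["site_a"]).strip(), str(row["site_b"]).strip()
        if k not in groups or l not in groups:
            raise ParameterError(f"{association_file}: row {idx + 2}: unknown group")
        if a not in SITE_TYPES or b not in SITE_TYPES:
            raise ParameterError(f"{association_file}: row {idx + 2}: unknown site type")
        db.set_association(k, a, l, b, _parse_value(row["eps_HB_K"]),
                           _parse_value(row["K_HB_A3"]),
                           str(row.get("provenance", "fitted")))
    return groups, db


def save_parameter_db(groups, db: InteractionDB, groups_file, unlike_file,
                      association_file):
    """Write the three parameter tables in the packaged CSV schema."""
    rows = []
    for g in groups.values():
        if g.name in GROUP_ALIASES:
            continue
        rows.append(dict(name=g.name, nu_star=g.nu_star,
                         shape_factor=g.shape_factor, sigma_A=g.sigma,
                         sigma_born_A="" if g.sigma_born is None else g.sigma_born,
                         lambda_r=g.lambda_r, lambda_a=g.lambda_a,
                         epsilon_K=g.epsilon_over_kB, charge=g.charge,
                         n_H=g.sites.get("H", 0), n_e1=g.sites.get("e1", 0),
                         n_e2=g.sites.get("e2", 0)))
    pd.DataFrame(rows).to_csv(groups_file, index=False)

    rows = []
    for (k, l), (eps, lam, prov) in sorted(db.dispersion.items()):
        rows.append(dict(group_k=k, group_l=l,
                         epsilon_K="CR" if eps is None else repr(eps),
                         lambda_r="CR" if lam is None else repr(lam),
                         provenance=prov))
    pd.DataFrame(rows).to_csv(unlike_file, index=False)

    rows = []
    for ((k, a), (l, b)), (eps, khb, prov) in sorted(db.association.items()):
        rows.append(dict(group_k=k, site_a=a, group_l=l, site_b=b,
                         eps_HB_K="CR" if eps is None else repr(eps),
                         K_HB_A3="CR" if khb is None else repr(khb),
                         provenance=prov))
    pd.DataFrame(rows).to_csv(association_file, index=False)


_DEFAULT_CACHE = None


def default_db():
    """The packaged parameter tables (cached)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        pkg = resources.files("saftgmie") / "data"
        _DEFAULT_CACHE = load_parameter_db(
            pkg / "groups.csv", pkg / "unlike.csv", pkg / "association.csv"
        )
    return _DEFAULT_CACHE


def load_melting(path=None) -> pd.DataFrame:
    path = path or resources.files("saftgmie") / "data" / "melting.csv"
    return pd.read_csv(path, comment="#", skipinitialspace=True).set_index("solute")


def load_dielectric(path=None) -> pd.DataFrame:
    path = path or resources.files("saftgmie") / "data" / "dielectric.csv"
    return pd.read_csv(path, comment="#", skipinitialspace=True).set_index("solvent")


def load_ka(path=None) -> pd.DataFrame:
    path = path or resources.files("saftgmie") / "data" / "ka.csv"
    return pd.read_csv(path, comment="#", skipinitialspace=True).set_index("compound")


# ---------------------------------------------------------------------------
# molecule library

_RESIDUE_SIDE = {
    # side-chain groups attached to the backbone carbon; glycine's backbone
    # carbon is a CH2, every other residue contributes a backbone CH
    "gly": {},
    "ala": {"CH3": 1},
    "val": {"CH": 1, "CH3": 2},
    "leu": {"CH2": 1, "CH": 1, "CH3": 2},
    "ser": {"CH2OH": 1},
}

_AMINO_NEUTRAL = {
    "glycine": {"NH2": 1, "CH2": 1, "COOH": 1},
    "alanine": {"NH2": 1, "CH": 1, "CH3": 1, "COOH": 1},
    "valine": {"NH2": 1, "CH": 2, "CH3": 2, "COOH": 1},
    "leucine": {"NH2": 1, "CH": 2, "CH2": 1, "CH3": 2, "COOH": 1},
    "serine": {"NH2": 1, "CH": 1, "CH2OH": 1, "COOH": 1},
}

# charged glycine/alanine species: the CH2 adjacent to the carboxylate uses
# the adjacent-CH2 interaction alias
_AMINO_SPECIES = {
    "glycine": {
        "zwitterion": {"NH3+": 1, "CH2_adj": 1, "COO-": 1},
        "cation": {"NH3+": 1, "CH2": 1, "COOH": 1},
        "anion": {"NH2": 1, "CH2_adj": 1, "COO-": 1},
    },
    "alanine": {
        "zwitterion": {"NH3+": 1, "CH": 1, "CH3": 1, "COO-": 1},
        "cation": {"NH3+": 1, "CH": 1, "CH3": 1, "COOH": 1},
        "anion": {"NH2": 1, "CH": 1, "CH3": 1, "COO-": 1},
    },
}

_IONS = {
    "hydronium": {"H3O+": 1},
    "hydroxide": {"OH-": 1},
    "sodium": {"Na+": 1},
    "chloride": {"Cl-": 1},
}


def water(groups=None, dielectric=True) -> Component:
    groups = groups or default_db()[0]
    diel = None
    if dielectric:
        row = load_dielectric().loc["water"]
        diel = (float(row["d_V_A3"]), float(row["d_T_K"]))
    return build_component("water", {"H2O": 1}, groups, solvent=True,
                           dielectric=diel)


def amino_acid(name: str, species: str = "neutral", groups=None) -> Component:
    """Amino acid as a neutral molecule or as one of its charged species
    (``neutral``, ``zwitterion``, ``cation``, ``anion``)."""
    groups = groups or default_db()[0]
    if species == "neutral":
        counts = _AMINO_NEUTRAL[name]
        return build_component(name, counts, groups)
    counts = _AMINO_SPECIES[name][species]
    return build_component(f"{name}_{species}", counts, groups,
                           zwitterion=(species == "zwitterion"))


def ion(name: str, groups=None) -> Component:
    groups = groups or default_db()[0]
    return build_component(name, _IONS[name], groups)


def peptide(*residues: str, groups=None) -> Component:
    """Linear peptide from residue codes (gly, ala, val, leu, ser)."""
    groups = groups or default_db()[0]
    counts: dict[str, int] = {"NH2": 1, "COOH": 1}
    if len(residues) < 2:
        raise ParameterError("a peptide needs at least two residues")
    counts["CONH"] = len(residues) - 1
    for res in residues:
        if res not in _RESIDUE_SIDE:
            raise ParameterError(f"unknown residue {res!r}")
        backbone = "CH2" if res == "gly" else "CH"
        counts[backbone] = counts.get(backbone, 0) + 1
        for g, c in _RESIDUE_SIDE[res].items():
            counts[g] = counts.get(g, 0) + c
    return build_component("-".join(residues), counts, groups)
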