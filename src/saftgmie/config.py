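"""Run configuration: schema-validated YAML/JSON in, CSV + manifest out."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import thermo
from .eos import GammaMieEoS
from .parameters import (amino_acid, build_component, default_db, ion,
                         load_parameter_db, peptide, water)
from .sle import MeltingProperties, bubble_pressure, solve_sle
from .speciation import (IdealActivities, ReactionSet, SaftActivities,
                         solubility_vs_ph, titration_curve)

log = logging.getLogger("saftgmie")

TASKS = ("density", "activity", "sle", "bubble", "titrate", "solubility-vs-ph")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    task: str
    components: list = field(default_factory=list)
    state: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    output: str = "result"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        task = raw.get("task")
        if task not in TASKS:
            raise ConfigError(f"task: must be one of {TASKS}, got {task!r}")
        cfg = cls(task=task,
                  components=raw.get("components", []),
                  state=raw.get("state", {}),
                  model=raw.get("model", {}),
                  solver=raw.get("solver", {}),
                  seed=int(raw.get("seed", 0)),
                  output=str(raw.get("output", "result")))
        cfg.validate()
        return cfg

    def validate(self):
        required = {
            "density": ["T", "P", "x"],
            "activity": ["T", "P", "x"],
            "sle": ["T_grid", "P", "solute"],
            "bubble": ["T", "x"],
            "titrate": ["T", "P", "m_total", "ph_grid"],
            "solubility-vs-ph": ["T_grid", "P", "ph_grid"],
        }[self.task]
        for key in required:
            if key not in self.state:
                raise ConfigError(f"state.{key}: required for task {self.task}")

    def to_dict(self):
        return dict(task=self.task, components=self.components,
                    state=self.state, model=self.model, solver=self.solver,
                    seed=self.seed, output=self.output)


def _build_components(cfg: RunConfig, groups):
    comps = []
    for item in cfg.components:
        if isinstance(item, str):
            comps.append(_named_component(item, groups))
        elif isinstance(item, dict):
            comps.append(build_component(
                item["name"], item["groups"], groups,
                zwitterion=item.get("zwitterion", False),
                solvent=item.get("solvent", False),
                dielectric=tuple(item["dielectric"]) if "dielectric" in item
                else None))
        else:
            raise ConfigError(f"components: bad entry {item!r}")
    return comps


def _named_component(name, groups):
    if name == "water":
        return water(groups)
    if name in ("hydronium", "hydroxide", "sodium", "chloride"):
        return ion(name, groups)
    if name.count("-") >= 1 and all(
            part in ("gly", "ala", "val", "leu", "ser")
            for part in name.split("-")):
        return peptide(*name.split("-"), groups=groups)
    for species in ("zwitterion", "cation", "anion"):
        suffix = f"_{species}"
        if name.endswith(suffix):
            return amino_acid(name[: -len(suffix)], species, groups)
    return amino_acid(name, "neutral", groups)


def run(config_path, params_dir=None, out_dir=".", seed=None) -> dict:
    """Execute one task; write a CSV table and a JSON manifest."""
    cfg = RunConfig.from_file(config_path)
    if seed is not None:
        cfg.seed = seed
    np.random.seed(cfg.seed % 2 ** 31)
    if params_dir is not None:
        p = Path(params_dir)
        groups, db = load_parameter_db(p / "groups.csv", p / "unlike.csv",
                                       p / "association.csv")
    else:
        groups, db = default_db()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mapping = cfg.model.get("mapping", "G")

    st = cfg.state
    if cfg.task in ("density", "activity", "sle", "bubble"):
        comps = _build_components(cfg, groups)
        eos = GammaMieEoS(comps, groups=groups, db=db, mapping=mapping)

    if cfg.task == "density":
        x = np.asarray(st["x"], float)
        rho = thermo.solve_density(eos, st["T"], st["P"], x,
                                   phase=st.get("phase"))
        df = pd.DataFrame([dict(T=st["T"], P=st["P"], rho_mol_m3=rho,
                                Z=st["P"] / (rho * 8.314462618 * st["T"]))])
    elif cfg.task == "activity":
        x = np.asarray(st["x"], float)
        rows = []
        aw = thermo.activity_water(eos, st["T"], st["P"], x)
        rows.append(dict(component="water", convention=aw.convention,
                         gamma=aw.gamma, activity=aw.activity))
        for i, comp in enumerate(eos.components):
            if comp.is_solvent:
                continue
            rec = thermo.activity_asymmetric(eos, st["T"], st["P"], x, i)
            rows.append(dict(component=rec.component,
                             convention=rec.convention, gamma=rec.gamma,
                             activity=rec.activity))
        df = pd.DataFrame(rows)
    elif cfg.task == "sle":
        names = [c.name for c in eos.components]
        i_solute = names.index(st["solute"])
        solvent_x = np.asarray(st.get("solvent_x",
                                      [1.0 if i != i_solute else 0.0
                                       for i in range(len(names))]), float)
        mp = (MeltingProperties(**st["melting"]) if "melting" in st
              else MeltingProperties.from_table(st["solute"]))
        rows = []
        for T in st["T_grid"]:
            log.info("SLE solve at T=%.2f K", T)
            res = solve_sle(eos, T, st["P"], solvent_x, i_solute, mp)
            rows.append(dict(T=T, x_sat=res.x_sat, gamma=res.gamma_at_sat,
                             residual=res.residual))
        df = pd.DataFrame(rows)
    elif cfg.task == "bubble":
        x = np.asarray(st["x"], float)
        P, y = bubble_pressure(eos, st["T"], x,
                               p_init=st.get("p_init", 1e5))
        df = pd.DataFrame([dict(T=st["T"], P_bubble=P,
                                **{f"y_{c.name}": yi
                                   for c, yi in zip(eos.components, y)})])
    elif cfg.task in ("titrate", "solubility-vs-ph"):
        compound = cfg.model.get("compound", "glycine")
        rx = ReactionSet.from_table(compound)
        if cfg.model.get("ideal_activities", True):
            act = IdealActivities(
                aw="xw" if cfg.model.get("include_aw", True) else "unity")
        else:
            act = SaftActivities(
                compound, mapping=mapping,
                aw="saft" if cfg.model.get("include_aw", True) else "unity",
                groups=groups, db=db)
        if cfg.task == "titrate":
            series = titration_curve(st["T"], st["P"], st["m_total"], rx,
                                     ph_grid=st["ph_grid"],
                                     activity_model=act)
            df = pd.DataFrame([dict(T=st["T"], pH=r.pH,
                                    oh_equivalents=r.oh_equivalents,
                                    xi_zwitterion=r.xi[0], xi_cation=r.xi[1],
                                    xi_anion=r.xi[2], a_w=r.a_w)
                               for r in series])
        else:
            mp = MeltingProperties.from_table(compound)
            rows = []
            for T in st["T_grid"]:
                series = solubility_vs_ph(T, st["P"], st["ph_grid"], rx, mp,
                                          act, compound=compound)
                for ph, r in zip(st["ph_grid"], series):
                    rows.append(dict(T=T, pH=ph, m_AA=r.m_AA,
                                     xi_zwitterion=r.xi[0],
                                     xi_cation=r.xi[1], xi_anion=r.xi[2],
                                     a_w=r.a_w))
            df = pd.DataFrame(rows)
    else:  # pragma: no cover
        raise ConfigError(cfg.task)

    csv_path = out_dir / f"{cfg.output}.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    manifest = dict(config=cfg.to_dict(), rows=len(df),
                    outputs=[str(csv_path)])
    with open(out_dir / f"{cfg.output}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("wrote %s (%d rows)", csv_path, len(df))
    return dict(table=df, manifest=manifest)
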