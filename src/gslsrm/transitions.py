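"""Enumerate the wide-targeted species grid and emit the SRM transition list.

The default method configuration (10 acidic glycans x 24 fatty-acyl
chains on a d18:1 base = 240 transitions) ships as a YAML file and is
fully user-overridable.
"""

from __future__ import annotations

import csv
import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .chem import (
    D18_1,
    FattyAcyl,
    GlycanHeadgroup,
    GSLSpecies,
    Ceramide,
    SphingoidBase,
    mz_deprotonated,
    neutral_mass,
    round_mz,
)

__all__ = [
    "TransitionConfig",
    "SRMTransition",
    "ConfigError",
    "load_config",
    "default_config",
    "enumerate_species",
    "assign_charge",
    "build_transitions",
    "export_transition_list",
    "read_transition_list",
]

#: Known sphingoid bases resolvable from shorthand in config files.
_BASES = {"d18:1": D18_1}


class ConfigError(ValueError):
    """Raised for invalid or incomplete method configuration."""


@dataclass(frozen=True)
class TransitionConfig:
    """Method configuration: catalogs plus charge-independent acquisition defaults."""

    glycans: tuple[GlycanHeadgroup, ...]
    acyls: tuple[FattyAcyl, ...]
    base: SphingoidBase = D18_1
    ce_by_neuac: dict[int, float] = field(default_factory=dict)
    q3_mz: float = 290.09
    declustering_potential: float = -100.0
    cell_exit_potential: float = -15.0
    rt_window: tuple[float, float] = (0.0, 45.0)

    def __post_init__(self) -> None:
        if not self.glycans:
            raise ConfigError("glycan catalog is empty")
        if not self.acyls:
            raise ConfigError("acyl list is empty")
        names = Counter(g.name for g in self.glycans)
        dupes = [n for n, k in names.items() if k > 1]
        if dupes:
            raise ConfigError(f"duplicate glycan names in catalog: {dupes}")
        shorthands = Counter(a.shorthand for a in self.acyls)
        dupes = [s for s, k in shorthands.items() if k > 1]
        if dupes:
            raise ConfigError(f"duplicate acyl shorthands: {dupes}")
        missing = sorted({g.n_neuac for g in self.glycans} - set(self.ce_by_neuac))
        if missing:
            raise ConfigError(f"ce_by_neuac missing entries for NeuAc counts: {missing}")


@dataclass(frozen=True)
class SRMTransition:
    """One Q1/Q3 pair with its acquisition parameters."""

    analyte_id: str
    q1: float
    q3: float
    charge: int
    ce: float
    dp: float = -100.0
    cxp: float = -15.0
    rt_start: float = 0.0
    rt_stop: float = 45.0
    isomer_group: str = ""


def _parse_config_dict(doc: dict) -> TransitionConfig:
    try:
        glycans = tuple(
            GlycanHeadgroup(
                name=str(g["name"]),
                n_hex=int(g.get("hex", 0)),
                n_hexnac=int(g.get("hexnac", 0)),
                n_neuac=int(g.get("neuac", 0)),
                n_dhex=int(g.get("dhex", 0)),
                series=str(g.get("series", "")),
            )
            for g in doc["glycans"]
        )
        acyls = tuple(FattyAcyl.from_shorthand(str(a)) for a in doc["acyls"])
    except KeyError as exc:
        raise ConfigError(f"config missing required key: {exc}") from None
    base_name = str(doc.get("base", "d18:1"))
    if base_name not in _BASES:
        raise ConfigError(f"unknown sphingoid base {base_name!r}; known: {sorted(_BASES)}")
    ce = {int(k): float(v) for k, v in doc.get("ce_by_neuac", {}).items()}
    rt = doc.get("rt_window", [0.0, 45.0])
    return TransitionConfig(
        glycans=glycans,
        acyls=acyls,
        base=_BASES[base_name],
        ce_by_neuac=ce,
        q3_mz=float(doc.get("q3_mz", 290.09)),
        declustering_potential=float(doc.get("declustering_potential", -100.0)),
        cell_exit_potential=float(doc.get("cell_exit_potential", -15.0)),
        rt_window=(float(rt[0]), float(rt[1])),
    )


def load_config(path: str | Path) -> TransitionConfig:
    """Load a method configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return _parse_config_dict(doc)


def default_config() -> TransitionConfig:
    """The packaged default method: 10 glycans x 24 acyls on d18:1."""
    ref = importlib.resources.files("gslsrm.data") / "default_method.yaml"
    doc = yaml.safe_load(ref.read_text())
    return _parse_config_dict(doc)


def enumerate_species(cfg: TransitionConfig) -> list[GSLSpecies]:
    """Cartesian product of glycans x acyls in deterministic catalog order."""
    return [
        GSLSpecies(glycan=g, ceramide=Ceramide(base=cfg.base, acyl=a))
        for g in cfg.glycans
        for a in cfg.acyls
    ]


def assign_charge(species: GSLSpecies) -> int:
    """Precursor charge rule: z = 2 for >= 2 NeuAc, else z = 1."""
    n = species.glycan.n_neuac
    if n < 1:
        raise ValueError(
            f"glycan {species.glycan.name!r} has no NeuAc; charge rule applies to acidic GSLs only"
        )
    return 2 if n >= 2 else 1


def _isomer_groups(glycans: Sequence[GlycanHeadgroup]) -> dict[str, str]:
    """Map glycan name -> shared label when >= 2 glycans have identical residue counts."""
    by_key: dict[tuple[int, int, int, int], list[str]] = {}
    for g in glycans:
        by_key.setdefault(g.residue_key, []).append(g.name)
    out: dict[str, str] = {}
    for (h, n, s, d), names in by_key.items():
        if len(names) > 1:
            label = f"Hex{h}HexNAc{n}NeuAc{s}" + (f"dHex{d}" if d else "")
            for name in names:
                out[name] = label
    return out


def build_transitions(cfg: TransitionConfig) -> list[SRMTransition]:
    """One transition per enumerated species; Q1 rounded to one decimal."""
    isomers = _isomer_groups(cfg.glycans)
    transitions = []
    for species in enumerate_species(cfg):
        z = assign_charge(species)
        q1 = round_mz(mz_deprotonated(neutral_mass(species), z))
        transitions.append(
            SRMTransition(
                analyte_id=species.name,
                q1=q1,
                q3=cfg.q3_mz,
                charge=z,
                ce=cfg.ce_by_neuac[species.glycan.n_neuac],
                dp=cfg.declustering_potential,
                cxp=cfg.cell_exit_potential,
                rt_start=cfg.rt_window[0],
                rt_stop=cfg.rt_window[1],
                isomer_group=isomers.get(species.glycan.name, ""),
            )
        )
    return transitions


_COLUMNS = [
    "id",
    "Q1",
    "Q3",
    "charge",
    "RT_window_start",
    "RT_window_stop",
    "DP",
    "CE",
    "CXP",
    "isomer_group",
]


def export_transition_list(
    transitions: Iterable[SRMTransition], path: str | Path, dialect: str = "generic"
) -> None:
    """Write a vendor-neutral delimited transition list (CSV with header)."""
    transitions = list(transitions)
    if not transitions:
        raise ValueError("refusing to export an empty transition list")
    if dialect != "generic":
        raise ValueError(f"unknown dialect {dialect!r}; supported: 'generic'")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for t in transitions:
            writer.writerow(
                [t.analyte_id, t.q1, t.q3, t.charge, t.rt_start, t.rt_stop,
                 t.dp, t.ce, t.cxp, t.isomer_group]
            )


def read_transition_list(path: str | Path) -> list[SRMTransition]:
    """Read a transition list written by :func:`export_transition_list`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SRMTransition(
                    analyte_id=row["id"],
                    q1=float(row["Q1"]),
                    q3=float(row["Q3"]),
                    charge=int(row["charge"]),
                    ce=float(row["CE"]),
                    dp=float(row["DP"]),
                    cxp=float(row["CXP"]),
                    rt_start=float(row["RT_window_start"]),
                    rt_stop=float(row["RT_window_stop"]),
                    isomer_group=row["isomer_group"],
                )
            )
    return out
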