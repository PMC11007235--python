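"""Internal-coordinate topology template for the 20 standard amino acids.

The template (shipped as ``data/topology.yaml``) stores, per residue type,
a z-matrix for every side-chain atom and polar hydrogen: reference atoms,
bond length, bond angle and a torsion that is either fixed or tied to a
named degree of freedom (chi1..chi5, with an optional offset for atoms
that co-rotate with a chi axis).  Backbone placement constants and the
standard chi-angle quadruples live here as well.  The same template drives
the synthetic-peptide builder and torsion-space forward kinematics, which
makes torsion round-trips exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

__all__ = [
    "SidechainAtom",
    "ResidueTopology",
    "Topology",
    "load_topology",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "STANDARD_AA",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = tuple(THREE_TO_ONE)


@dataclass(frozen=True)
class SidechainAtom:
    """One z-matrix row: place ``name`` relative to three reference atoms."""

    name: str
    element: str
    refs: tuple[str, str, str]
    r: float            # bond length to refs[0], Angstrom
    theta: float        # bond angle name-refs[0]-refs[1], radians
    tau_dof: str | None  # 'chi1'..'chi5' or None for a fixed torsion
    tau_value: float    # fixed torsion, or offset added to the dof, radians


@dataclass(frozen=True)
class ResidueTopology:
    name: str
    backbone: dict
    sidechain: tuple[SidechainAtom, ...]
    chi: tuple[tuple[str, str, str, str], ...]
    default_chi: tuple[float, ...]  # radians
    has_amide_h: bool

    @property
    def n_chi(self) -> int:
        return len(self.chi)

    def heavy_sidechain_names(self) -> list[str]:
        return [a.name for a in self.sidechain if a.element != "H"]


@dataclass(frozen=True)
class Topology:
    peptide: dict
    residues: dict = field(default_factory=dict)

    def __contains__(self, resname: str) -> bool:
        return resname in self.residues

    def __getitem__(self, resname: str) -> ResidueTopology:
        try:
            return self.residues[resname]
        except KeyError:
            raise KeyError(f"no topology for residue type {resname!r}") from None


def _parse_residue(name: str, raw: dict) -> ResidueTopology:
    atoms = []
    for e in raw["sidechain"]:
        tau = e["tau"]
        if "dof" in tau:
            dof, val = tau["dof"], math.radians(tau.get("offset", 0.0))
        else:
            dof, val = None, math.radians(tau["fixed"])
        atoms.append(SidechainAtom(
            name=e["name"], element=e["element"], refs=tuple(e["refs"]),
            r=float(e["r"]), theta=math.radians(e["theta"]),
            tau_dof=dof, tau_value=val,
        ))
    bb = {k: (math.radians(v) if k.startswith("ang_") else float(v))
          for k, v in raw["backbone"].items()}
    return ResidueTopology(
        name=name,
        backbone=bb,
        sidechain=tuple(atoms),
        chi=tuple(tuple(q) for q in raw["chi"]),
        default_chi=tuple(math.radians(v) for v in raw["default_chi"]),
        has_amide_h=bool(raw["has_amide_h"]),
    )


@lru_cache(maxsize=1)
def load_topology() -> Topology:
    """Load the shipped topology template (cached)."""
    with resources.files("gradff.data").joinpath("topology.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    pep = {k: (math.radians(v) if k.startswith("ang_") else float(v))
           for k, v in raw["peptide"].items()}
    residues = {name: _parse_residue(name, r) for name, r in raw["residues"].items()}
    return Topology(peptide=pep, residues=residues)
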