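"""Physical constants, per-term weights and annotation tables.

:class:`ParameterSet` gathers every tunable number in the force field:
solvent conditions (temperature, ionic strength, dielectric), the Coulomb
constant, per-term weights, the smooth solvent-exposure parameters,
interaction cutoffs, and the per-residue/per-atom lookup tables (charges,
radii, donor/acceptor flags, solvation/vdW/entropy coefficients).  The
tables default to the ones shipped in ``data/atom_params.yaml`` and can be
overridden from a user YAML config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ParameterSet", "TERM_NAMES", "load_default_tables"]

# order of the energy classes in every breakdown / report
TERM_NAMES = (
    "hbond",
    "electrostatics",
    "disulfide",
    "solvation_polar",
    "solvation_hydrophobic",
    "vdw",
    "clash",
    "entropy_backbone",
    "entropy_sidechain",
    "peptide_violation",
    "sidechain_violation",
)

CLASH_GROUPS = (
    "same_residue",
    "hbond",
    "disulfide",
    "consecutive_backbone",
    "donor_acceptor",
    "other",
)


@lru_cache(maxsize=1)
def load_default_tables() -> dict:
    with resources.files("gradff.data").joinpath("atom_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def _default_weights() -> dict:
    w = {name: 1.0 for name in TERM_NAMES}
    # backbone entropy has two factors: one for the omega density (w1) and
    # one for the phi/psi density (w2)
    w["entropy_omega"] = 1.0
    return w


@dataclass
class ParameterSet:
    """All tunable physical parameters of the force field.

    Defaults describe a generic aqueous condition (298 K, 50 mM ionic
    strength, dielectric 80) with all term weights at 1.
    """

    # solvent conditions
    temperature: float = 298.0          # K
    ionic_strength: float = 0.05        # M
    dielectric: float = 80.0
    coulomb_constant: float = 332.0     # kcal Angstrom / (mol e^2)
    screening_uses_dielectric: bool = True  # include dielectric in the Debye kappa

    # per-term weights (kcal/mol scale factors)
    weights: dict = field(default_factory=_default_weights)

    # smooth solvent-exposure proxy
    exposure_kappa: float = 0.08        # occlusion decay per weighted neighbor
    exposure_shell: float = 5.0         # Angstrom
    exposure_sharpness: float = 0.4     # Angstrom, sigmoid width

    # interaction cutoffs, Angstrom
    elec_cutoff: float = 12.0
    clash_cutoff: float = 5.0
    hbond_cutoff: float = 3.5           # H...acceptor
    disulfide_cutoff: float = 2.5       # SG...SG

    # hydrogen-bond well
    hbond_optimal_distance: float = 1.9
    hbond_distance_sigma: float = 0.3
    hbond_geom_power: int = 3
    hbond_acceptor_angle: float = math.radians(115.0)
    hbond_acceptor_sigma: float = 0.35  # width in cosine space
    hbond_softmin_tau: float = 0.05     # kcal/mol, acceptor soft-selection

    # disulfide well
    ss_optimal_distance: float = 2.05
    ss_distance_sigma: float = 0.1

    # side-chain entropy gating
    strong_elec_threshold: float = -1.0  # kcal/mol, residue-pair energy
    gate_sharpness: float = 16.0

    # clash term
    clash_exponent_scale: float = 10.0
    clash_continuous: bool = False      # subtract w on the active branch

    # electrostatics guards
    min_distance: float = 1e-3

    # calibration controls
    clash_percentile: float = 10.0
    min_group_count: int = 50
    min_density_samples: int = 100
    max_kde_centers: int = 2000
    kde_bandwidth: float | None = None  # radians; None = circular Silverman
    density_floor: float = 1e-12
    peptide_sigma_floor: float = 1e-3
    chain_break_distance: float = 2.5

    # annotation tables (charges, radii, flags, coefficients)
    tables: dict = field(default_factory=lambda: dict(load_default_tables()))
    unknown_residue_policy: str = "warn"  # or "error"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("term weights must be non-negative")

    # -- convenience table access -------------------------------------
    def radius_of(self, element: str) -> float:
        return float(self.tables["radii"].get(element.capitalize(), 1.7))

    def charge_of(self, res_name: str, atom_name: str) -> float:
        return float(self.tables["charges"].get(res_name, {}).get(atom_name, 0.0))

    def coefficient(self, res_name: str, kind: str) -> float:
        return float(self.tables["coefficients"].get(res_name, {}).get(kind, 0.0))

    def weight(self, term: str) -> float:
        return float(self.weights.get(term, 1.0))

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        base = cls()
        known = set(base.to_dict())
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        merged = base.to_dict()
        for key, val in data.items():
            if isinstance(merged.get(key), dict) and isinstance(val, dict):
                deep = dict(merged[key])
                for k2, v2 in val.items():
                    if isinstance(deep.get(k2), dict) and isinstance(v2, dict):
                        deep[k2] = {**deep[k2], **v2}
                    else:
                        deep[k2] = v2
                merged[key] = deep
            else:
                merged[key] = val
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
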