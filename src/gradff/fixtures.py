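"""Deterministic synthetic-structure generator.

Ideal-geometry peptides built by forward kinematics from the topology
template: helix/strand backbones, arbitrary sequences, optional Gaussian
coordinate noise, jittered "reference sets" used to calibrate clash
corrections and torsion densities (a desk-scale stand-in for a set of
high-resolution crystal structures), plus small engineered constructs
(disulfide bridges, controlled clash pairs) for unit-level checks.

Everything is pure: the same spec and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from . import geometry
from .structure_io import StructureModel
from .topology import ONE_TO_THREE, Topology, load_topology

__all__ = [
    "FixtureSpec",
    "PRESETS",
    "build_peptide",
    "build_reference_set",
    "build_disulfide_bridge",
    "build_clash_pair",
]

# backbone presets: (phi, psi, omega) in radians
PRESETS = {
    "helix": (np.radians(-57.0), np.radians(-47.0), np.pi),
    "strand": (np.radians(-120.0), np.radians(120.0), np.pi),
}

# default side-chain rotamers per preset, degrees: the clash-minimal
# combination from a discrete (chi1, chi2) scan of each residue type as a
# guest in a poly-Ala host with the same backbone preset.  Proline keeps
# its ring-pucker values from the topology template.
PRESET_CHI = {
    "ARG": {"helix": [180, 180, 180, 180, 180], "strand": [60, 180, 180, 180, 180]},
    "ASN": {"helix": [180, 60], "strand": [-60, -60]},
    "ASP": {"helix": [180, 60], "strand": [-60, -60]},
    "CYS": {"helix": [180], "strand": [-60]},
    "GLN": {"helix": [180, 180, 180], "strand": [-60, 180, 180]},
    "GLU": {"helix": [180, 180, 180], "strand": [-60, 180, 180]},
    "HIS": {"helix": [180, 90], "strand": [-60, 90]},
    "ILE": {"helix": [-60, 180], "strand": [-60, 180]},
    "LEU": {"helix": [180, 60], "strand": [-60, 180]},
    "LYS": {"helix": [180, 180, 180, 180], "strand": [-60, 180, 180, 180]},
    "MET": {"helix": [180, 180, 180], "strand": [-60, 180, 180]},
    "PHE": {"helix": [180, 90], "strand": [-60, 90]},
    "SER": {"helix": [180], "strand": [-60]},
    "THR": {"helix": [-60], "strand": [-60]},
    "TRP": {"helix": [180, -90], "strand": [-60, 90]},
    "TYR": {"helix": [180, 90], "strand": [-60, 90]},
    "VAL": {"helix": [180], "strand": [180]},
}


def preset_chi(res_name: str, preset: str, topo: Topology | None = None) -> list[float]:
    """Default side-chain torsions (radians) for a backbone preset."""
    topo = topo or load_topology()
    if res_name not in PRESET_CHI:
        return list(topo[res_name].default_chi)
    key = preset if preset in ("helix", "strand") else "strand"
    return [np.radians(v) for v in PRESET_CHI[res_name][key]]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic peptide."""

    sequence: str
    preset: str = "helix"                    # 'helix' | 'strand' | 'custom'
    custom_angles: list | None = None        # per-residue (phi, psi, omega) rad
    chi: dict = field(default_factory=dict)  # residue index -> list of rad
    noise_sigma: float = 0.0                 # Angstrom
    seed: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letter(s): {bad}")
        if self.preset not in PRESETS and self.preset != "custom":
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset == "custom" and (
                self.custom_angles is None
                or len(self.custom_angles) != len(self.sequence)):
            raise ValueError("custom preset needs one (phi, psi, omega) per residue")


def _assemble(res_names: list[str], keys, positions, chain_id: str,
              start_res_id: int = 1) -> StructureModel:
    coords = np.stack([np.asarray(p, dtype=np.float64) for p in positions])
    n = len(keys)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.full(n, chain_id)
    arr.res_id = np.array([start_res_id + i for i, _ in keys])
    arr.res_name = np.array([res_names[i] for i, _ in keys])
    arr.atom_name = np.array([name for _, name in keys])
    arr.element = np.array([name[0] for _, name in keys])
    arr.hetero = np.zeros(n, bool)
    return StructureModel(arr, provenance="fixture", coords64=coords)


def build_peptide(spec: FixtureSpec, include_hydrogens: bool = True,
                  chain_id: str = "A", topo: Topology | None = None) -> StructureModel:
    """Build one ideal-geometry peptide from a :class:`FixtureSpec`."""
    topo = topo or load_topology()
    res_names = [ONE_TO_THREE[c] for c in spec.sequence]
    n = len(res_names)
    if spec.preset == "custom":
        angles = np.asarray(spec.custom_angles, dtype=float)
    else:
        angles = np.tile(PRESETS[spec.preset], (n, 1))
    chi = []
    for i, rn in enumerate(res_names):
        default = preset_chi(rn, spec.preset, topo)
        given = spec.chi.get(i)
        if given is not None:
            default[:len(given)] = list(given)
        chi.append(default)
    dofs = {"phi": angles[:, 0], "psi": angles[:, 1], "omega": angles[:, 2],
            "chi": chi}
    keys, positions = geometry.build_chain_coords(
        res_names, dofs, topo, include_hydrogens=include_hydrogens)
    s = _assemble(res_names, keys, positions, chain_id)
    if spec.noise_sigma > 0:
        # noise_sigma is the RMS displacement per atom; split over axes
        rng = np.random.default_rng(spec.seed)
        noisy = s.coords + rng.normal(0.0, spec.noise_sigma / np.sqrt(3.0),
                                      size=s.coords.shape)
        s = s.with_coords(noisy)
    return s


def build_reference_set(n: int, length_range: tuple[int, int] = (8, 14),
                        mix: tuple[str, ...] = ("helix", "strand"),
                        seed: int = 0,
                        backbone_jitter: float = np.radians(8.0),
                        omega_jitter: float = np.radians(3.0),
                        chi_jitter: float = np.radians(12.0),
                        coordinate_noise: float = 0.02,
                        topo: Topology | None = None) -> list[StructureModel]:
    """A calibration-grade set of jittered ideal peptides.

    Backbone angles are wrapped-normal around the preset values (so fitted
    torsion densities have known ground-truth modes); chi angles jitter
    around the topology defaults; a small Gaussian coordinate noise
    (default 0.02 Angstrom) gives bond lengths and angles the finite
    spread real structures show, which keeps the fitted peptide-geometry
    Gaussians well conditioned.  Residue letters are drawn by cycling
    shuffled decks of all 20 types, which guarantees near-uniform type
    coverage.  ``mix`` may include ``"cys_bridge"`` to interleave
    disulfide-bridged two-chain constructs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    topo = topo or load_topology()
    rng = np.random.default_rng(seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    deck: list[str] = []

    def draw_letter() -> str:
        if not deck:
            sh = letters.copy()
            rng.shuffle(sh)
            deck.extend(sh)
        return deck.pop()

    out = []
    for k in range(n):
        preset = mix[k % len(mix)]
        if preset == "cys_bridge":
            out.append(build_disulfide_bridge(seed=int(rng.integers(2 ** 31))))
            continue
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(draw_letter() for _ in range(length))
        phi0, psi0, omega0 = PRESETS[preset]
        angles = np.column_stack([
            phi0 + rng.normal(0, backbone_jitter, length),
            psi0 + rng.normal(0, backbone_jitter, length),
            omega0 + rng.normal(0, omega_jitter, length),
        ])
        angles = (angles + np.pi) % (2 * np.pi) - np.pi
        angles[angles <= -np.pi] += 2 * np.pi
        chi = {}
        res_names = [ONE_TO_THREE[c] for c in seq]
        for i, rn in enumerate(res_names):
            defaults = preset_chi(rn, preset, topo)
            if defaults:
                chi[i] = [geometry.wrap_angle(v + rng.normal(0, chi_jitter))
                          for v in defaults]
        spec = FixtureSpec(sequence=seq, preset="custom",
                           custom_angles=angles.tolist(), chi=chi,
                           noise_sigma=coordinate_noise,
                           seed=int(rng.integers(2 ** 31)))
        out.append(build_peptide(spec, topo=topo))
    return out


def build_disulfide_bridge(seed: int = 0, sequence: str = "ACA") -> StructureModel:
    """Two short chains joined by an ideal disulfide bridge.

    The second chain is rigidly placed so the two cysteine SG atoms sit at
    2.05 Angstrom with a CB-S-S angle of ~104 deg and an S-S torsion of
    ~90 deg.  Thiol hydrogens are omitted on the bridged cysteines.
    """
    if "C" not in sequence:
        raise ValueError("bridge sequence needs a cysteine")
    a = build_peptide(FixtureSpec(sequence=sequence, seed=seed), chain_id="A")
    b = build_peptide(FixtureSpec(sequence=sequence, seed=seed + 1), chain_id="B")

    def sg_cb_ca(s):
        for r in s.residues:
            if r.name == "CYS" and {"SG", "CB", "CA"} <= set(r.atom_ids):
                c = s.coords
                return (c[r.atom_ids["SG"]], c[r.atom_ids["CB"]],
                        c[r.atom_ids["CA"]], r)
        raise ValueError("no complete cysteine")

    sg_a, cb_a, ca_a, _ = sg_cb_ca(a)
    sg_b, cb_b, ca_b, _ = sg_cb_ca(b)

    # target frame: CB-S-S angle 104 deg, S-S torsion 90 deg, S-S 2.05 A;
    # built from chain B's own internal geometry so the rigid fit is exact
    sg_t = np.asarray(geometry.place_atom(sg_a, cb_a, ca_a, 2.05,
                                          np.radians(104.0), np.radians(-60.0)))
    cb_t = np.asarray(geometry.place_atom(
        sg_t, sg_a, cb_a, float(np.linalg.norm(sg_b - cb_b)),
        np.radians(104.0), np.radians(90.0)))
    ca_t = np.asarray(geometry.place_atom(
        cb_t, sg_t, sg_a, float(np.linalg.norm(ca_b - cb_b)),
        float(geometry.bond_angle(ca_b, cb_b, sg_b)), np.pi))

    from scipy.spatial.transform import Rotation
    P = np.stack([sg_b, cb_b, ca_b])
    Q = np.stack([sg_t, cb_t, ca_t])
    Pc, Qc = P.mean(0), Q.mean(0)
    rot, _ = Rotation.align_vectors(Q - Qc, P - Pc)
    b = b.with_coords(rot.apply(b.coords - Pc) + Qc)

    # drop thiol hydrogens on the bridged cysteines
    mask_a = np.ones(a.n_atoms, bool)
    mask_b = np.ones(b.n_atoms, bool)
    for r in a.residues:
        if r.name == "CYS" and "HG" in r.atom_ids:
            mask_a[r.atom_ids["HG"]] = False
    for r in b.residues:
        if r.name == "CYS" and "HG" in r.atom_ids:
            mask_b[r.atom_ids["HG"]] = False
    merged = a.array[mask_a] + b.array[mask_b]
    coords = np.concatenate([a.coords[mask_a], b.coords[mask_b]])
    return StructureModel(merged, provenance="cys_bridge", coords64=coords)


def build_clash_pair(gap: float, radius_sum: float = 3.4,
                     t_g: float = 0.0) -> StructureModel:
    """Two alanine residues with one controlled CB...CB contact.

    The CB-CB distance is set to ``radius_sum + t_g + gap``, i.e. ``gap``
    Angstrom outside the calibrated clash threshold for the pair's group
    (``t_g`` is the fitted 10th-percentile correction, typically
    negative).  All other inter-chain atom pairs sit farther apart than
    the contact pair.
    """
    a = build_peptide(FixtureSpec(sequence="A"), chain_id="A",
                      include_hydrogens=False)
    b = build_peptide(FixtureSpec(sequence="A"), chain_id="B",
                      include_hydrogens=False)
    ra, rb = a.residues[0], b.residues[0]
    cb_a = a.coords[ra.atom_ids["CB"]]
    ca_a = a.coords[ra.atom_ids["CA"]]
    u = (cb_a - ca_a) / np.linalg.norm(cb_a - ca_a)
    d = radius_sum + t_g + gap
    cb_t = cb_a + d * u
    ca_t = cb_t + np.linalg.norm(b.coords[rb.atom_ids["CA"]]
                                 - b.coords[rb.atom_ids["CB"]]) * u
    # off-axis reference so the placement frame is non-degenerate
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    n_t = np.asarray(geometry.place_atom(
        ca_t, cb_t, cb_a + v,
        float(np.linalg.norm(b.coords[rb.atom_ids["N"]] - b.coords[rb.atom_ids["CA"]])),
        geometry.bond_angle(b.coords[rb.atom_ids["N"]],
                            b.coords[rb.atom_ids["CA"]],
                            b.coords[rb.atom_ids["CB"]]),
        np.radians(60.0)))
    from scipy.spatial.transform import Rotation
    P = np.stack([b.coords[rb.atom_ids["CB"]], b.coords[rb.atom_ids["CA"]],
                  b.coords[rb.atom_ids["N"]]])
    Q = np.stack([cb_t, ca_t, n_t])
    Pc, Qc = P.mean(0), Q.mean(0)
    rot, _ = Rotation.align_vectors(Q - Qc, P - Pc)
    b = b.with_coords(rot.apply(b.coords - Pc) + Qc)
    merged = a.array + b.array
    coords = np.concatenate([a.coords, b.coords])
    return StructureModel(merged, provenance="clash_pair", coords64=coords)
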