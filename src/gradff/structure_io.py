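"""PDB parsing, the hierarchical structure model, polar-hydrogen placement
and per-atom physical annotation.

:class:`StructureModel` wraps a biotite ``AtomArray`` (which handles the
fixed-column PDB format, altloc filtering and model selection) and adds
residue-level bookkeeping.  :func:`assign_atom_annotations` flattens a
structure into the tensorizable :class:`AtomTable` carrying charges,
van der Waals radii and donor/acceptor/backbone flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io

from . import geometry
from .params import ParameterSet
from .topology import Topology, load_topology

__all__ = [
    "PDBFormatError",
    "ResidueView",
    "StructureModel",
    "AtomTable",
    "read_pdb",
    "write_pdb",
    "add_polar_hydrogens",
    "assign_atom_annotations",
]

log = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# covalent radii used for bond detection, Angstrom
_COV_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}
_BOND_TOL = 0.45


class PDBFormatError(ValueError):
    """Raised for files without usable ATOM records or with bad coordinates."""


@dataclass
class ResidueView:
    """Lightweight view of one residue of a :class:`StructureModel`."""

    index: int
    name: str
    chain_id: str
    chain_index: int
    res_id: int
    ins_code: str
    atom_indices: np.ndarray
    atom_ids: dict  # atom name -> global atom index


class StructureModel:
    """Hierarchical chain/residue/atom model backed by a biotite AtomArray."""

    def __init__(self, array: struc.AtomArray, provenance: str = "",
                 coords64: np.ndarray | None = None):
        self.array = array
        self.provenance = provenance
        self._residues: list[ResidueView] | None = None
        # keep a float64 master copy (AtomArray stores float32 internally)
        self._coords64 = (np.asarray(array.coord, dtype=np.float64)
                          if coords64 is None else np.asarray(coords64, np.float64))
        if array.array_length() and not np.all(np.isfinite(self._coords64)):
            raise PDBFormatError("non-finite atom coordinates")

    # -- basic views ---------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self._coords64

    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.array.chain_id:
            if c not in seen:
                seen.append(str(c))
        return seen

    @property
    def residues(self) -> list[ResidueView]:
        if self._residues is None:
            self._residues = self._build_residues()
        return self._residues

    @property
    def residue_index(self) -> np.ndarray:
        out = np.empty(self.n_atoms, dtype=int)
        for r in self.residues:
            out[r.atom_indices] = r.index
        return out

    def _build_residues(self) -> list[ResidueView]:
        arr = self.array
        if arr.array_length() == 0:
            return []
        starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
        chain_order: list[str] = []
        out = []
        for ri, (a, b) in enumerate(zip(starts[:-1], starts[1:])):
            cid = str(arr.chain_id[a])
            if cid not in chain_order:
                chain_order.append(cid)
            idx = np.arange(a, b)
            ins = arr.ins_code[a] if "ins_code" in arr.get_annotation_categories() else ""
            out.append(ResidueView(
                index=ri,
                name=str(arr.res_name[a]),
                chain_id=cid,
                chain_index=chain_order.index(cid),
                res_id=int(arr.res_id[a]),
                ins_code=str(ins),
                atom_indices=idx,
                atom_ids={str(arr.atom_name[k]): int(k) for k in idx},
            ))
        return out

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        arr = self.array.copy()
        arr.coord = np.asarray(coords, dtype=np.float32)
        return StructureModel(arr, provenance=self.provenance, coords64=coords)

    def copy(self) -> "StructureModel":
        return StructureModel(self.array.copy(), provenance=self.provenance,
                              coords64=self._coords64.copy())

    def __repr__(self):
        return (f"StructureModel({self.n_atoms} atoms, "
                f"{len(self.residues)} residues, chains={self.chains})")


def read_pdb(path: str | Path, keep_hetero: bool = False) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations are resolved to the highest-occupancy copy, waters
    are dropped, and non-water HETATM records are dropped unless
    ``keep_hetero``.  Raises ``FileNotFoundError`` for a missing file and
    :class:`PDBFormatError` for files without ATOM records or with
    non-finite coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdbf = pdb_io.PDBFile.read(str(path))
        arr = pdbf.get_structure(model=1, altloc="occupancy",
                                 extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various parse errors
        raise PDBFormatError(f"cannot parse {path.name}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path.name}: no ATOM records")
    mask = ~np.isin(arr.res_name, list(WATER_NAMES))
    if not keep_hetero:
        mask &= ~arr.hetero
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path.name}: no ATOM records after filtering")
    if not np.all(np.isfinite(arr.coord)):
        raise PDBFormatError(f"{path.name}: non-finite coordinates")
    return StructureModel(arr, provenance=path.name)


def write_pdb(s: StructureModel, path: str | Path) -> None:
    """Write the structure as a fixed-column PDB file."""
    pdbf = pdb_io.PDBFile()
    pdbf.set_structure(s.array)
    pdbf.write(str(path))


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------

def _make_atom(res: ResidueView, name: str, coord: np.ndarray) -> struc.Atom:
    return struc.Atom(
        coord=np.asarray(coord, dtype=np.float32),
        chain_id=res.chain_id,
        res_id=res.res_id,
        res_name=res.name,
        atom_name=name,
        element="H",
        hetero=False,
    )


def add_polar_hydrogens(s: StructureModel, topo: Topology | None = None) -> StructureModel:
    """Place backbone amide and side-chain polar hydrogens by ideal geometry.

    The amide H sits 1.01 Angstrom from N, in the C(prev)-N-CA plane,
    opposite the bisector of that angle; proline and chain-initial
    residues receive none.  Side-chain polar hydrogens (hydroxyl, thiol,
    amino, guanidinium, amide, ring NH) are placed from the topology
    z-matrix; the thiol H is skipped for disulfide-bonded cysteines.
    Existing hydrogens are preserved (the operation is idempotent).
    Missing parent heavy atoms log a warning and skip that hydrogen.
    """
    topo = topo or load_topology()
    res = s.residues
    coords = s.coords

    # disulfide-bonded cysteine SG atoms get no thiol H
    sg_idx = [r.atom_ids["SG"] for r in res if r.name == "CYS" and "SG" in r.atom_ids]
    bridged: set[int] = set()
    for a in range(len(sg_idx)):
        for b in range(a + 1, len(sg_idx)):
            if np.linalg.norm(coords[sg_idx[a]] - coords[sg_idx[b]]) < 2.5:
                bridged.update((sg_idx[a], sg_idx[b]))

    new_atoms: dict[int, list] = {}  # residue index -> list of Atom

    for i, r in enumerate(res):
        if r.name not in topo:
            continue
        rt = topo[r.name]
        added = []
        # backbone amide H
        prev = res[i - 1] if i > 0 and res[i - 1].chain_index == r.chain_index else None
        if (rt.has_amide_h and "H" not in r.atom_ids and prev is not None
                and "C" in prev.atom_ids and {"N", "CA"} <= set(r.atom_ids)):
            n = coords[r.atom_ids["N"]]
            u = _unit(coords[prev.atom_ids["C"]] - n) + _unit(coords[r.atom_ids["CA"]] - n)
            added.append(("H", n - 1.01 * _unit(u)))
        # side-chain polar hydrogens from the z-matrix
        for atom in rt.sidechain:
            if atom.element != "H" or atom.name in r.atom_ids:
                continue
            if r.name == "CYS" and atom.name == "HG" and r.atom_ids.get("SG") in bridged:
                continue
            try:
                refs = [coords[r.atom_ids[nm]] for nm in atom.refs]
            except KeyError as missing:
                log.warning("%s %s%d: missing %s, skipping %s",
                            r.name, r.chain_id, r.res_id, missing, atom.name)
                continue
            if atom.tau_dof is None:
                tau = atom.tau_value
            else:
                k = int(atom.tau_dof[3:]) - 1
                quad = rt.chi[k]
                try:
                    pts = [coords[r.atom_ids[nm]] for nm in quad]
                except KeyError as missing:
                    log.warning("%s %s%d: missing %s for %s, skipping %s",
                                r.name, r.chain_id, r.res_id, missing,
                                atom.tau_dof, atom.name)
                    continue
                tau = float(geometry.dihedral(*pts)) + atom.tau_value
            pos = geometry.place_atom(refs[0], refs[1], refs[2],
                                      atom.r, atom.theta, tau)
            added.append((atom.name, np.asarray(pos, dtype=np.float64)))
        if added:
            new_atoms[i] = added

    if not new_atoms:
        return s.copy()

    pieces = []
    coord_pieces = []
    for i, r in enumerate(res):
        pieces.append(s.array[r.atom_indices])
        coord_pieces.append(coords[r.atom_indices])
        for name, pos in new_atoms.get(i, []):
            pieces.append(struc.array([_make_atom(r, name, pos)]))
            coord_pieces.append(pos[None, :])
    merged = pieces[0]
    for p in pieces[1:]:
        merged += p
    return StructureModel(merged, provenance=s.provenance,
                          coords64=np.concatenate(coord_pieces, axis=0))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AtomTable:
    """Flat tensorized view of a structure: one row per atom.

    Charges are elementary-charge units, radii Angstrom.  ``donor_heavy``
    maps each donor hydrogen to its parent heavy atom (-1 elsewhere);
    ``acceptor_base`` maps each acceptor to its covalently bonded heavy
    antecedent (-1 elsewhere), used for hydrogen-bond lone-pair geometry.
    """

    coords: np.ndarray
    q: np.ndarray
    radius: np.ndarray
    is_donor_h: np.ndarray
    is_acceptor: np.ndarray
    is_sulfur: np.ndarray
    is_backbone: np.ndarray
    residue_index: np.ndarray
    chain_index: np.ndarray
    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    residue_names: list = field(default_factory=list)
    donor_heavy: np.ndarray | None = None
    acceptor_base: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.q)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def __post_init__(self):
        if np.any(self.radius <= 0):
            raise ValueError("radii must be strictly positive")
        if np.any(np.abs(self.q) > 1.0 + 1e-9):
            raise ValueError("per-atom |charge| must not exceed 1")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing")
        if np.any(self.is_donor_h & (self.element != "H")):
            raise ValueError("donor hydrogens must have element H")


def covalent_bonds(coords: np.ndarray, elements: np.ndarray) -> set[tuple[int, int]]:
    """Distance-based covalent bond detection (sorted index pairs)."""
    n = len(coords)
    if n < 2:
        return set()
    rad = np.array([_COV_RADII.get(str(e).capitalize(), 0.77) for e in elements])
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    thresh = rad[:, None] + rad[None, :] + _BOND_TOL
    ii, jj = np.where(np.triu(d <= thresh, k=1))
    # hydrogens bond to exactly one (nearest) heavy atom
    out = set()
    h_best: dict[int, tuple[float, int]] = {}
    for a, b in zip(ii, jj):
        ea, eb = str(elements[a]), str(elements[b])
        if ea == "H" and eb == "H":
            continue
        if ea == "H" or eb == "H":
            h, x = (a, b) if ea == "H" else (b, a)
            dd = d[a, b]
            if h not in h_best or dd < h_best[h][0]:
                h_best[h] = (dd, x)
        else:
            out.add((int(a), int(b)))
    for h, (_, x) in h_best.items():
        out.add(tuple(sorted((int(h), int(x)))))
    return out


def assign_atom_annotations(s: StructureModel, params: ParameterSet | None = None) -> AtomTable:
    """Assign charge, radius and interaction flags to every atom.

    Lookup tables come from ``params.tables`` (config-overridable).
    Unknown residue types follow ``params.unknown_residue_policy``:
    ``"warn"`` gives neutral default annotations with a logged warning,
    ``"error"`` raises ``KeyError``.
    """
    params = params or ParameterSet()
    tables = params.tables
    arr = s.array
    n = s.n_atoms
    res = s.residues
    residue_index = s.residue_index

    element = np.array([str(e).capitalize() for e in arr.element])
    atom_name = np.array([str(a) for a in arr.atom_name])
    res_name = np.array([res[residue_index[k]].name for k in range(n)])

    known = set(tables["coefficients"])
    for r in res:
        if r.name not in known:
            if params.unknown_residue_policy == "error":
                raise KeyError(f"unknown residue type {r.name!r}")
            log.warning("unknown residue type %s: default annotations", r.name)

    q = np.array([params.charge_of(rn, an) for rn, an in zip(res_name, atom_name)])
    radius = np.array([params.radius_of(e) for e in element])
    backbone_names = set(tables["backbone_atoms"])
    is_backbone = np.isin(atom_name, list(backbone_names))
    is_sulfur = element == "S"

    acceptors = tables["acceptors"]
    donors = tables["donors"]
    acc_bb = set(acceptors.get("_backbone", []))
    don_bb = set(donors.get("_backbone", []))
    is_acceptor = np.zeros(n, bool)
    donor_heavy_names = np.zeros(n, bool)
    for k in range(n):
        rn, an = res_name[k], atom_name[k]
        if an in acc_bb or an in acceptors.get(rn, []):
            is_acceptor[k] = True
        if (an in don_bb and rn != "PRO") or an in donors.get(rn, []):
            donor_heavy_names[k] = True

    bonds = covalent_bonds(s.coords, element)
    neighbors: dict[int, list[int]] = {}
    for a, b in bonds:
        neighbors.setdefault(a, []).append(b)
        neighbors.setdefault(b, []).append(a)

    is_donor_h = np.zeros(n, bool)
    donor_heavy = -np.ones(n, int)
    acceptor_base = -np.ones(n, int)
    for k in range(n):
        if element[k] == "H":
            heavies = [j for j in neighbors.get(k, []) if element[j] != "H"]
            if heavies and donor_heavy_names[heavies[0]]:
                is_donor_h[k] = True
                donor_heavy[k] = heavies[0]
        elif is_acceptor[k]:
            heavies = [j for j in neighbors.get(k, []) if element[j] != "H"]
            if heavies:
                dists = [np.linalg.norm(s.coords[k] - s.coords[j]) for j in heavies]
                acceptor_base[k] = heavies[int(np.argmin(dists))]

    chain_index = np.array([res[residue_index[k]].chain_index for k in range(n)])
    return AtomTable(
        coords=np.asarray(s.coords, dtype=np.float64),
        q=q, radius=radius,
        is_donor_h=is_donor_h, is_acceptor=is_acceptor,
        is_sulfur=is_sulfur, is_backbone=is_backbone,
        residue_index=residue_index, chain_index=chain_index,
        element=element, atom_name=atom_name, res_name=res_name,
        residue_names=[r.name for r in res],
        donor_heavy=donor_heavy, acceptor_base=acceptor_base,
    )
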