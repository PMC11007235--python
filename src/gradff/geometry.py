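"""Differentiable tensor geometry.

Pairwise distances, bond angles, signed dihedrals, backbone and side-chain
torsion extraction, a smooth solvent-exposure proxy, peptide-bond geometry
observations, and torsion-space forward kinematics (natural-extension
reference frames).  Every function accepts either plain numpy coordinates
(fast, no tape) or autodiff tensors (differentiable); see
:mod:`gradff.autodiff`.

Angle convention: radians, wrapped to (-pi, pi]; the same wrap is used by
the torsion density estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, value_of, is_tensor
from .topology import Topology, load_topology

__all__ = [
    "wrap_angle",
    "dihedral",
    "bond_angle",
    "place_atom",
    "pairwise_distances",
    "TorsionSet",
    "torsion_set",
    "backbone_torsions",
    "chi_torsions",
    "solvent_exposure",
    "PeptideGeometryObservation",
    "peptide_geometry",
    "build_chain_coords",
    "rebuild_from_torsions",
    "random_rigid_transform",
    "superimpose_rmsd",
]

_DEG = np.pi / 180.0


def wrap_angle(a):
    """Wrap angles into (-pi, pi]."""
    v = value_of(a)
    shift = 2.0 * np.pi * np.ceil((v - np.pi) / (2.0 * np.pi))
    return a - shift if is_tensor(a) else v - shift


def dihedral(p0, p1, p2, p3, eps: float = 1e-8):
    """Signed torsion angle of the chain p0-p1-p2-p3 in (-pi, pi].

    IUPAC sign convention: looking down the p1->p2 bond, positive when the
    far bond rotates clockwise from the near bond.  Near-collinear inputs
    (cross products below ``eps``) return 0 with zero gradient instead of
    propagating NaNs.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    c12 = ad.cross(b1, b2)
    c23 = ad.cross(b2, b3)
    n2 = ad.norm(b2, eps=1e-24)
    y = ad.dot(ad.cross(c12, c23), ad.div(b2, ad.expand_dims(n2, -1) if np.ndim(value_of(b2)) > 1 else n2))
    x = ad.dot(c12, c23)
    ang = ad.arctan2(y, x)
    # mask degenerate quadruples (collinear segments)
    bad = (np.linalg.norm(value_of(c12), axis=-1) < eps) | (
        np.linalg.norm(value_of(c23), axis=-1) < eps)
    if np.any(bad):
        ang = ad.where(bad, np.zeros_like(value_of(ang)), ang)
    return ang


def bond_angle(p0, p1, p2):
    """Angle at p1 in radians, computed with atan2 for stability."""
    u = p0 - p1
    v = p2 - p1
    return ad.arctan2(ad.norm(ad.cross(u, v), eps=1e-24), ad.dot(u, v))


def place_atom(a, b, c, r, theta, tau):
    """Place atom D with |D-a| = r, angle(D,a,b) = theta, dihedral(D,a,b,c) = tau.

    The natural-extension reference frame: deterministic, differentiable in
    all inputs.  ``r`` and ``theta`` may be floats; ``tau`` may be a scalar
    tensor so torsion gradients flow through the placement.
    """
    u = ad.normalize(a - b)                     # from b toward a
    n = ad.normalize(ad.cross(b - c, u))        # normal of the (c,b,a) plane
    m = ad.cross(n, u)
    ct, st = ad.cos(theta), ad.sin(theta)
    rst = ad.mul(st, r)
    return a + ad.mul(u, ad.mul(ct, -r)) + ad.mul(m, ad.mul(ad.cos(tau), rst)) \
        + ad.mul(n, ad.mul(ad.sin(tau), rst))


def pairwise_distances(coords, cutoff: float | None = None):
    """All-vs-all Euclidean distances.

    With ``cutoff=None`` returns the dense symmetric (n, n) matrix with a
    zero diagonal (differentiable).  With a cutoff returns ``(i, j, d)``
    for the pairs i < j with d <= cutoff; ``d`` is differentiable, the
    index selection is not.
    """
    vals = value_of(coords)
    n = len(vals)
    if n == 0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0)) if cutoff else np.empty((0, 0))
    if cutoff is None:
        a = ad.expand_dims(coords, 1)
        b = ad.expand_dims(coords, 0)
        diff = a - b
        return ad.norm(diff, axis=-1, eps=1e-24)
    diff = vals[:, None, :] - vals[None, :, :]
    dmat = np.sqrt((diff * diff).sum(-1))
    ii, jj = np.where(np.triu(dmat <= cutoff, k=1))
    d = ad.norm(coords[ii] - coords[jj], eps=1e-24) if is_tensor(coords) else dmat[ii, jj]
    return ii, jj, d


# ---------------------------------------------------------------------------
# torsion extraction
# ---------------------------------------------------------------------------

@dataclass
class TorsionSet:
    """Per-residue backbone (phi/psi/omega) and side-chain (chi1..chi5) angles.

    Angles are radians in (-pi, pi].  Masks are False where a defining atom
    quadruple is missing (chain termini, absent side-chain atoms); the
    stored value is 0 there, except ``psi`` of a chain-terminal residue
    which holds the pseudo-psi inferred from the carbonyl O so that
    forward kinematics can still place O (the mask stays False).
    Index arrays hold the coordinate rows of each defining quadruple
    (-1 where invalid) so energies can re-derive the angles
    differentiably from a coordinate tensor.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    phi_mask: np.ndarray
    psi_mask: np.ndarray
    omega_mask: np.ndarray
    chi: np.ndarray          # (n, 5)
    chi_mask: np.ndarray     # (n, 5)
    residue_type: list = field(default_factory=list)
    chain_index: np.ndarray | None = None
    phi_idx: np.ndarray | None = None
    psi_idx: np.ndarray | None = None
    omega_idx: np.ndarray | None = None
    chi_idx: np.ndarray | None = None

    @property
    def n_residues(self) -> int:
        return len(self.phi)

    def n_valid_chi(self, i: int) -> int:
        return int(self.chi_mask[i].sum())


def _quad_dihedrals(coords, idx: np.ndarray):
    """Dihedrals for an (m, 4) index array of coordinate rows."""
    if len(idx) == 0:
        return np.empty(0)
    return dihedral(coords[idx[:, 0]], coords[idx[:, 1]],
                    coords[idx[:, 2]], coords[idx[:, 3]])


def torsion_set(s, topo: Topology | None = None) -> TorsionSet:
    """Extract all backbone and chi torsions from a structure."""
    topo = topo or load_topology()
    res = s.residues
    n = len(res)
    coords = s.coords
    phi = np.zeros(n)
    psi = np.zeros(n)
    omega = np.zeros(n)
    masks = {k: np.zeros(n, bool) for k in ("phi", "psi", "omega")}
    idx = {k: -np.ones((n, 4), int) for k in ("phi", "psi", "omega")}
    chi = np.zeros((n, 5))
    chi_mask = np.zeros((n, 5), bool)
    chi_idx = -np.ones((n, 5, 4), int)
    chain_index = np.array([r.chain_index for r in res], int)

    def atom(i, name):
        return res[i].atom_ids.get(name, -1)

    for i, r in enumerate(res):
        prev = i - 1 if i > 0 and res[i - 1].chain_index == r.chain_index else None
        nxt = i + 1 if i + 1 < n and res[i + 1].chain_index == r.chain_index else None
        N, CA, C = atom(i, "N"), atom(i, "CA"), atom(i, "C")
        if prev is not None:
            Cp, CAp = atom(prev, "C"), atom(prev, "CA")
            if min(Cp, N, CA, C) >= 0:
                idx["phi"][i] = (Cp, N, CA, C)
                masks["phi"][i] = True
            if min(CAp, Cp, N, CA) >= 0:
                idx["omega"][i] = (CAp, Cp, N, CA)
                masks["omega"][i] = True
        if nxt is not None:
            Nn = atom(nxt, "N")
            if min(N, CA, C, Nn) >= 0:
                idx["psi"][i] = (N, CA, C, Nn)
                masks["psi"][i] = True
        if not masks["psi"][i]:
            O = atom(i, "O")
            if min(N, CA, C, O) >= 0:
                # pseudo-psi from the carbonyl oxygen (mask stays False)
                idx["psi"][i] = (N, CA, C, O)
        if r.name in topo:
            for k, quad in enumerate(topo[r.name].chi):
                ids = [atom(i, nm) for nm in quad]
                if min(ids) >= 0:
                    chi_idx[i, k] = ids
                    chi_mask[i, k] = True

    cvals = value_of(coords)
    for key, arr in ((("phi"), phi), (("psi"), psi), (("omega"), omega)):
        rows = np.where(idx[key][:, 0] >= 0)[0]
        if len(rows):
            vals = value_of(_quad_dihedrals(cvals, idx[key][rows]))
            arr[rows] = vals
    # pseudo-psi rows measured through O are off by pi from the N-based psi
    pseudo = (~masks["psi"]) & (idx["psi"][:, 0] >= 0)
    psi[pseudo] = wrap_angle(psi[pseudo] - np.pi)
    rows, slots = np.where(chi_mask)
    if len(rows):
        chi[rows, slots] = value_of(_quad_dihedrals(cvals, chi_idx[rows, slots]))

    return TorsionSet(
        phi=phi, psi=psi, omega=omega,
        phi_mask=masks["phi"], psi_mask=masks["psi"], omega_mask=masks["omega"],
        chi=chi, chi_mask=chi_mask,
        residue_type=[r.name for r in res],
        chain_index=chain_index,
        phi_idx=idx["phi"], psi_idx=idx["psi"], omega_idx=idx["omega"],
        chi_idx=chi_idx,
    )


def backbone_torsions(s, topo: Topology | None = None) -> TorsionSet:
    """Phi/psi/omega per residue (chain termini masked)."""
    return torsion_set(s, topo)


def chi_torsions(s, topo: Topology | None = None) -> TorsionSet:
    """Side-chain chi angles per residue (missing atoms masked)."""
    return torsion_set(s, topo)


# ---------------------------------------------------------------------------
# solvent exposure
# ---------------------------------------------------------------------------

def solvent_exposure(table, params, coords=None):
    """Smooth, differentiable solvent-exposure proxy in (0, 1].

    exposure_i = exp(-kappa * sum_j sigmoid((shell - d_ij) / sharpness))
    where j runs over atoms of *other* residues (a residue does not bury
    itself).  Returns ``(atom_exposure, residue_exposure,
    sidechain_exposure)``; the residue aggregates are means over heavy
    atoms (side-chain aggregate falls back to all heavy atoms for
    glycine).
    """
    x = table.coords if coords is None else coords
    n = len(value_of(x))
    if n == 0:
        z = np.empty(0)
        return z, z, z
    dmat = pairwise_distances(x)                       # (n, n) dense
    same_res = table.residue_index[:, None] == table.residue_index[None, :]
    w = ad.sigmoid((params.exposure_shell - dmat) * (1.0 / params.exposure_sharpness))
    w = ad.where(same_res | np.eye(n, dtype=bool), np.zeros((n, n)), w)
    occ = ad.tsum(w, axis=1)
    atom_exp = ad.exp(ad.mul(occ, -params.exposure_kappa))

    heavy = table.element != "H"
    nres = table.n_residues
    heavy_cnt = np.bincount(table.residue_index[heavy], minlength=nres).astype(float)
    heavy_cnt[heavy_cnt == 0] = 1.0
    res_exp = ad.scatter_add(atom_exp[np.where(heavy)[0]],
                             table.residue_index[heavy], nres) / heavy_cnt
    sc = heavy & ~table.is_backbone
    sc_cnt = np.bincount(table.residue_index[sc], minlength=nres).astype(float)
    has_sc = sc_cnt > 0
    sc_cnt[~has_sc] = 1.0
    sc_exp = ad.scatter_add(atom_exp[np.where(sc)[0]], table.residue_index[sc], nres) / sc_cnt
    if not np.all(has_sc):
        sc_exp = ad.where(has_sc, sc_exp, res_exp)
    return atom_exp, res_exp, sc_exp


# ---------------------------------------------------------------------------
# peptide-bond geometry
# ---------------------------------------------------------------------------

@dataclass
class PeptideGeometryObservation:
    """Geometry of one peptide bond between residue ``prev`` and ``res``."""

    res_index: int
    prev_index: int
    angle_ca_n_cp: float    # CA(i)-N(i)-C(i-1), radians
    angle_cap_cp_n: float   # CA(i-1)-C(i-1)-N(i), radians
    dist_n_cp: float        # N(i)-C(i-1), Angstrom
    excluded: bool          # chain break (distance above threshold)


def peptide_geometry(s, max_bond_distance: float = 2.5) -> list[PeptideGeometryObservation]:
    """One observation per peptide bond; broken bonds flagged ``excluded``."""
    res = s.residues
    coords = value_of(s.coords)
    out = []
    for i in range(1, len(res)):
        if res[i].chain_index != res[i - 1].chain_index:
            continue
        ids = (res[i].atom_ids.get("CA", -1), res[i].atom_ids.get("N", -1),
               res[i - 1].atom_ids.get("C", -1), res[i - 1].atom_ids.get("CA", -1))
        if min(ids) < 0:
            continue
        ca, n_, cp, cap = (coords[k] for k in ids)
        d = float(np.linalg.norm(n_ - cp))
        out.append(PeptideGeometryObservation(
            res_index=i, prev_index=i - 1,
            angle_ca_n_cp=float(value_of(bond_angle(ca, n_, cp))),
            angle_cap_cp_n=float(value_of(bond_angle(cap, cp, n_))),
            dist_n_cp=d,
            excluded=d > max_bond_distance,
        ))
    return out


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def build_chain_coords(res_names: list, dofs: dict, topo: Topology | None = None,
                       include_hydrogens: bool = True):
    """Build one chain of ideal-geometry residues from torsion angles.

    ``dofs`` maps 'phi', 'psi', 'omega' to per-residue scalars and 'chi'
    to a per-residue sequence of up to five scalars; scalars may be plain
    floats or autodiff tensors.  The first three backbone atoms define the
    global frame (N at origin, CA on +x, C in the xy-plane).  Returns
    ``(atom_keys, positions)`` with ``atom_keys[k] = (residue_index,
    atom_name)`` and positions differentiable w.r.t. the torsion inputs.

    Raises ``KeyError`` for residue types absent from the topology.
    """
    topo = topo or load_topology()
    pep = topo.peptide
    pos: dict[tuple, object] = {}
    keys: list[tuple] = []

    def put(i, name, p):
        pos[(i, name)] = p
        keys.append((i, name))

    for i, rn in enumerate(res_names):
        rt = topo[rn]
        bb = rt.backbone
        phi = dofs["phi"][i]
        psi = dofs["psi"][i]
        omega = dofs["omega"][i]
        if i == 0:
            put(i, "N", np.zeros(3))
            put(i, "CA", np.array([bb["r_N_CA"], 0.0, 0.0]))
            ang = bb["ang_N_CA_C"]
            put(i, "C", pos[(i, "CA")] + bb["r_CA_C"] *
                np.array([-np.cos(ang), np.sin(ang), 0.0]))
        else:
            Cp, CAp, Np = pos[(i - 1, "C")], pos[(i - 1, "CA")], pos[(i - 1, "N")]
            psip = dofs["psi"][i - 1]
            put(i, "N", place_atom(Cp, CAp, Np, pep["r_C_N"], pep["ang_CA_C_N"], psip))
            put(i, "CA", place_atom(pos[(i, "N")], Cp, CAp,
                                    bb["r_N_CA"], pep["ang_C_N_CA"], omega))
            put(i, "C", place_atom(pos[(i, "CA")], pos[(i, "N")], Cp,
                                   bb["r_CA_C"], bb["ang_N_CA_C"], phi))
            if include_hydrogens and rt.has_amide_h:
                put(i, "H", place_atom(pos[(i, "N")], Cp, CAp,
                                       pep["r_N_H"], pep["ang_H_N_C"], omega - np.pi))
        put(i, "O", place_atom(pos[(i, "C")], pos[(i, "CA")], pos[(i, "N")],
                               bb["r_C_O"], bb["ang_CA_C_O"], psi + np.pi))
        chi_vals = dofs.get("chi")
        chis = chi_vals[i] if chi_vals is not None else rt.default_chi
        for atom in rt.sidechain:
            if atom.element == "H" and not include_hydrogens:
                continue
            refs = [pos[(i, nm)] for nm in atom.refs]
            if atom.tau_dof is None:
                tau = atom.tau_value
            else:
                k = int(atom.tau_dof[3:]) - 1
                base = chis[k] if k < len(chis) else rt.default_chi[k]
                tau = base + atom.tau_value
            put(i, atom.name, place_atom(refs[0], refs[1], refs[2],
                                         atom.r, atom.theta, tau))
    return keys, [pos[k] for k in keys]


def rebuild_from_torsions(tset: TorsionSet, topo: Topology | None = None,
                          include_hydrogens: bool = True,
                          chi_override=None):
    """Rebuild ideal-geometry coordinates of a single chain from torsions.

    Bond lengths and angles come from the topology template; the returned
    positions are differentiable with respect to any tensor-valued angles.
    Returns ``(atom_keys, coords)`` where coords is (n_atoms, 3).
    """
    topo = topo or load_topology()
    if tset.chain_index is not None and len(set(tset.chain_index.tolist())) > 1:
        raise ValueError("rebuild_from_torsions expects a single chain")
    n = tset.n_residues
    chi = chi_override
    if chi is None:
        chi = [[tset.chi[i, k] if tset.chi_mask[i, k] else
                (topo[tset.residue_type[i]].default_chi[k]
                 if k < topo[tset.residue_type[i]].n_chi else 0.0)
                for k in range(5)] for i in range(n)]
    dofs = {"phi": tset.phi, "psi": tset.psi, "omega": tset.omega, "chi": chi}
    keys, positions = build_chain_coords(tset.residue_type, dofs, topo,
                                         include_hydrogens=include_hydrogens)
    coords = ad.stack(positions, axis=0)
    return keys, coords


# ---------------------------------------------------------------------------
# rigid-motion utilities
# ---------------------------------------------------------------------------

def random_rigid_transform(rng: np.random.Generator, max_shift: float = 20.0):
    """A uniformly random rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def superimpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between coordinate sets after optimal rigid superposition."""
    from scipy.spatial.transform import Rotation

    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a0, b0)
    return float(np.sqrt(np.mean(np.sum((a0 - rot.apply(b0)) ** 2, axis=1))))
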