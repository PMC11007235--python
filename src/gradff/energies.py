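"""The eleven energy classes and their aggregation.

Stabilizing interactions (hydrogen bonds, screened electrostatics,
disulfides, solvation, van der Waals burial) and knowledge-based
penalties (steric clashes, backbone/side-chain entropy, peptide-bond and
side-chain conformation violations) are all expressed through the
autodiff ops, so the total energy of a structure is one differentiable
graph from the coordinate tensor to a scalar in kcal/mol.

Each term is a standalone function over an :class:`~gradff.structure_io.AtomTable`
(plus whatever calibration data it needs); :class:`EnergyModel` caches
the static bookkeeping (bond graph, torsion indices, pair exclusions)
and evaluates all terms on a shared coordinate tensor.

Pair lists are selected from the current numpy coordinate values (the
selection itself carries no gradient); every distance-dependent term goes
smoothly to zero before its selection cutoff, so the selection boundary
does not create gradient artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import Tensor, value_of, is_tensor
from .calibration import (Calibration, ClashGroupTable, DensityModel,
                          collect_clash_pairs, debye_huckel_kappa,
                          detect_hbond_pairs)
from .params import ParameterSet, TERM_NAMES
from .structure_io import (AtomTable, StructureModel, assign_atom_annotations,
                           covalent_bonds)
from .topology import Topology, load_topology

__all__ = [
    "SetupError",
    "EnergyBreakdown",
    "EnergyModel",
    "total_energy",
    "electrostatics",
    "hydrogen_bonds",
    "disulfide",
    "solvation",
    "vdw",
    "clash",
    "backbone_entropy",
    "sidechain_entropy",
    "peptide_violation",
    "sidechain_violation",
]

log = logging.getLogger(__name__)


class SetupError(RuntimeError):
    """Raised when calibration lacks a density needed by the structure."""


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _switch(d, r_on: float, r_off: float):
    """C1 switching function: 1 below r_on, 0 above r_off."""
    dv = value_of(d)
    d2 = ad.mul(d, d)
    on2, off2 = r_on * r_on, r_off * r_off
    num = ad.mul(ad.mul(off2 - d2, off2 - d2), ad.mul(d2, 2.0) + (off2 - 3.0 * on2))
    s = ad.mul(num, 1.0 / (off2 - on2) ** 3)
    return ad.where(dv <= r_on, np.ones_like(dv),
                    ad.where(dv >= r_off, np.zeros_like(dv), s))


def _half_scatter(e_pair, idx_a, idx_b, nres):
    """Split pair energies half/half onto the two residues."""
    half = ad.mul(e_pair, 0.5)
    return ad.scatter_add(half, idx_a, nres) + ad.scatter_add(half, idx_b, nres)


def _pair_distances(coords, i, j):
    return ad.norm(coords[i] - coords[j], eps=1e-24)


def bond_adjacency(bonds: set, n: int) -> dict:
    adj: dict[int, set] = {k: set() for k in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _excluded_12_13(adj: dict, i: int, j: int) -> bool:
    if j in adj[i]:
        return True
    return any(j in adj[k] for k in adj[i])


def _default_adj(table: AtomTable, coords_val):
    bonds = covalent_bonds(coords_val, table.element)
    return bond_adjacency(bonds, table.n_atoms), bonds


# ---------------------------------------------------------------------------
# pair interaction terms
# ---------------------------------------------------------------------------

def electrostatics(table: AtomTable, params: ParameterSet, coords=None,
                   adj: dict | None = None, kappa: float | None = None):
    """Screened Coulomb energy of charged-atom pairs.

    E_ij = C q_i q_j / (eps d_ij) * exp(-d_ij K), switched smoothly to
    zero at the cutoff.  Pairs within the same residue and 1-2/1-3
    bonded pairs are excluded; distances below ``params.min_distance``
    are clamped.  Returns ``(per_residue, (i, j, e_pair))``.
    """
    x = table.coords if coords is None else coords
    cv = value_of(x)
    nres = table.n_residues
    if adj is None:
        adj, _ = _default_adj(table, cv)
    if kappa is None:
        kappa = float(value_of(debye_huckel_kappa(
            params.ionic_strength, params.temperature,
            params.dielectric if params.screening_uses_dielectric else 1.0))) \
            if params.ionic_strength > 0 else 0.0
    charged = np.where(np.abs(table.q) > 1e-12)[0]
    pairs = []
    for a_ in range(len(charged)):
        for b_ in range(a_ + 1, len(charged)):
            a, b = int(charged[a_]), int(charged[b_])
            if table.residue_index[a] == table.residue_index[b]:
                continue
            if _excluded_12_13(adj, a, b):
                continue
            if np.linalg.norm(cv[a] - cv[b]) <= params.elec_cutoff:
                pairs.append((a, b))
    if not pairs:
        return np.zeros(nres), (np.empty(0, int), np.empty(0, int), np.zeros(0))
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    d = _pair_distances(x, i, j)
    if np.any(value_of(d) < params.min_distance):
        log.warning("electrostatic pair below %.0e A clamped", params.min_distance)
    d = ad.clamp_min(d, params.min_distance)
    qq = table.q[i] * table.q[j]
    e = ad.mul(ad.div(ad.exp(ad.mul(d, -kappa)), d),
               qq * params.coulomb_constant / params.dielectric)
    e = ad.mul(e, _switch(d, params.elec_cutoff - 1.0, params.elec_cutoff))
    e = ad.mul(e, params.weight("electrostatics"))
    per_res = _half_scatter(e, table.residue_index[i], table.residue_index[j], nres)
    return per_res, (i, j, e)


def hydrogen_bonds(table: AtomTable, params: ParameterSet, coords=None,
                   adj: dict | None = None):
    """Donor-H / acceptor energies with smooth geometry factors.

    E = -w * f_dist(d) * f_align(theta_DHA) * f_lp(theta_HAB), where
    f_dist is a Gaussian well at the optimal H...A distance (switched off
    at the cutoff), f_align a cosine power favoring linear D-H...A, and
    f_lp a squared-cosine Gaussian around the acceptor lone-pair
    direction (the H-acceptor-antecedent angle).  Each hydrogen is
    assigned to (approximately) its best acceptor through differentiable
    soft-min weights.  Returns ``(per_residue, per_residue_strength)``
    with strength = the positive magnitude credited to both partners,
    used by the side-chain entropy gate.
    """
    x = table.coords if coords is None else coords
    cv = value_of(x)
    nres = table.n_residues
    hs_all = np.where(table.is_donor_h & (table.donor_heavy >= 0))[0]
    acc_all = np.where(table.is_acceptor)[0]
    if len(hs_all) == 0 or len(acc_all) == 0:
        return np.zeros(nres), np.zeros(nres)
    if adj is None:
        adj, _ = _default_adj(table, cv)
    dmat = np.linalg.norm(cv[hs_all][:, None, :] - cv[acc_all][None, :, :], axis=-1)
    hi, ai = np.where(dmat <= params.hbond_cutoff)
    keep = []
    for k, (h, a) in enumerate(zip(hs_all[hi], acc_all[ai])):
        if table.residue_index[h] == table.residue_index[a]:
            continue
        if _excluded_12_13(adj, int(h), int(a)):
            continue
        keep.append(k)
    if not keep:
        return np.zeros(nres), np.zeros(nres)
    keep = np.array(keep, int)
    hs, accs = hs_all[hi[keep]], acc_all[ai[keep]]
    dons = table.donor_heavy[hs]
    bases = table.acceptor_base[accs] if table.acceptor_base is not None \
        else -np.ones(len(accs), int)

    d = _pair_distances(x, hs, accs)
    dd = d - params.hbond_optimal_distance
    f_dist = ad.exp(ad.mul(ad.mul(dd, dd), -0.5 / params.hbond_distance_sigma ** 2))
    f_dist = ad.mul(f_dist, _switch(d, 3.0, params.hbond_cutoff))

    u = x[dons] - x[hs]
    v = x[accs] - x[hs]
    cos_dha = ad.div(ad.dot(u, v),
                     ad.mul(ad.norm(u, eps=1e-24), ad.norm(v, eps=1e-24)))
    f_a = ((1.0 - cos_dha) * 0.5) ** params.hbond_geom_power

    has_base = bases >= 0
    safe_base = np.where(has_base, bases, accs)
    w_ = x[hs] - x[accs]
    z_ = x[safe_base] - x[accs]
    cos_hab = ad.div(ad.dot(w_, z_),
                     ad.mul(ad.norm(w_, eps=1e-24), ad.norm(z_, eps=1e-12)))
    dev = cos_hab - math.cos(params.hbond_acceptor_angle)
    f_b = ad.exp(ad.mul(ad.mul(dev, dev), -0.5 / params.hbond_acceptor_sigma ** 2))
    f_b = ad.where(has_base, f_b, np.ones(len(hs)))

    e_cand = ad.mul(ad.mul(ad.mul(f_dist, f_a), f_b), -params.weight("hbond"))

    # soft-min acceptor selection per hydrogen (max-shifted for stability)
    uniq, seg = np.unique(hs, return_inverse=True)
    ev = value_of(e_cand)
    zmax = np.array([(-ev[seg == k] / params.hbond_softmin_tau).max()
                     for k in range(len(uniq))])
    expw = ad.exp(ad.mul(e_cand, -1.0 / params.hbond_softmin_tau) - zmax[seg])
    denom = ad.scatter_add(expw, seg, len(uniq))
    wts = ad.div(expw, denom[seg])
    e_sel = ad.mul(wts, e_cand)

    per_res = _half_scatter(e_sel, table.residue_index[hs],
                            table.residue_index[accs], nres)
    strength = ad.scatter_add(ad.mul(e_sel, -1.0), table.residue_index[hs], nres) \
        + ad.scatter_add(ad.mul(e_sel, -1.0), table.residue_index[accs], nres)
    return per_res, strength


def disulfide(table: AtomTable, params: ParameterSet, coords=None,
              adj: dict | None = None):
    """Disulfide-bridge energy from S-S distance and S-S torsion.

    E = w * [g_dist(d; optimum 2.05 A) + g_tors(chi_SS; optimum +-90 deg)]
    with each factor in [-1/2, 0], so an ideal bridge scores -w.
    Returns ``(per_residue, per_residue_strength)``.
    """
    x = table.coords if coords is None else coords
    cv = value_of(x)
    nres = table.n_residues
    sgs = np.where(table.is_sulfur & (table.res_name == "CYS")
                   & (table.atom_name == "SG"))[0]
    if len(sgs) < 2:
        return np.zeros(nres), np.zeros(nres)
    if adj is None:
        adj, _ = _default_adj(table, cv)
    cb_of = {}
    for sg in sgs:
        heavies = [k for k in adj[int(sg)]
                   if table.element[k] not in ("H", "S")]
        if heavies:
            cb_of[int(sg)] = heavies[0]
    pairs = [(int(a), int(b)) for k, a in enumerate(sgs) for b in sgs[k + 1:]
             if np.linalg.norm(cv[a] - cv[b]) <= params.disulfide_cutoff
             and int(a) in cb_of and int(b) in cb_of]
    if not pairs:
        return np.zeros(nres), np.zeros(nres)
    i = np.array([a for a, _ in pairs])
    j = np.array([b for _, b in pairs])
    d = _pair_distances(x, i, j)
    dd = d - params.ss_optimal_distance
    g_d = ad.mul(ad.exp(ad.mul(ad.mul(dd, dd), -0.5 / params.ss_distance_sigma ** 2)),
                 -0.5)
    cb_i = np.array([cb_of[a] for a, _ in pairs])
    cb_j = np.array([cb_of[b] for _, b in pairs])
    chi = geometry.dihedral(x[cb_i], x[i], x[j], x[cb_j])
    s = ad.sin(chi)
    g_t = ad.mul(ad.mul(s, s), -0.5)
    e = ad.mul(g_d + g_t, params.weight("disulfide"))
    e = ad.mul(e, _switch(d, 2.3, params.disulfide_cutoff))
    per_res = _half_scatter(e, table.residue_index[i], table.residue_index[j], nres)
    strength = ad.scatter_add(ad.mul(e, -1.0), table.residue_index[i], nres) \
        + ad.scatter_add(ad.mul(e, -1.0), table.residue_index[j], nres)
    return per_res, strength


# ---------------------------------------------------------------------------
# exposure-scaled coefficient terms
# ---------------------------------------------------------------------------

def solvation(table: AtomTable, res_exposure, params: ParameterSet):
    """Polar and hydrophobic solvation: coefficient times residue exposure.

    Exposed polar groups stabilize (negative coefficients), exposed
    hydrophobic surface destabilizes (positive coefficients).
    Returns ``(polar_per_residue, hydrophobic_per_residue)``.
    """
    c_pol = np.array([params.coefficient(rn, "polar")
                      for rn in table.residue_names])
    c_hyd = np.array([params.coefficient(rn, "hydrophobic")
                      for rn in table.residue_names])
    return (ad.mul(res_exposure, c_pol * params.weight("solvation_polar")),
            ad.mul(res_exposure, c_hyd * params.weight("solvation_hydrophobic")))


def vdw(table: AtomTable, atom_exposure, params: ParameterSet):
    """Van der Waals stabilization realized in proportion to atomic burial.

    E(res) = c_vdw(type) * mean over heavy atoms of (1 - exposure);
    coefficients are negative, so a fully exposed residue scores 0 and a
    fully buried one the full coefficient.
    """
    nres = table.n_residues
    heavy = table.element != "H"
    cnt = np.bincount(table.residue_index[heavy], minlength=nres).astype(float)
    cnt[cnt == 0] = 1.0
    burial = ad.scatter_add(1.0 - atom_exposure[np.where(heavy)[0]],
                            table.residue_index[heavy], nres) / cnt
    c = np.array([params.coefficient(rn, "vdw") for rn in table.residue_names])
    return ad.mul(burial, c * params.weight("vdw"))


# ---------------------------------------------------------------------------
# clash
# ---------------------------------------------------------------------------

def clash(table: AtomTable, groups: ClashGroupTable, params: ParameterSet,
          coords=None, bonds: set | None = None,
          hbond_pairs: set | None = None):
    """Exponential penalty for pairs closer than their group's threshold.

    A pair of group g clashes when d < R_i + R_j + t_g (t_g the fitted
    10th-percentile gap correction); the penalty is
    w * exp(s * (R_i + R_j + t_g - d)) on the active branch and 0
    otherwise, hence >= 0 everywhere.  Returns
    ``(per_residue, (i, j, e_pair))``.
    """
    x = table.coords if coords is None else coords
    cv = value_of(x)
    nres = table.n_residues
    i, j, g = collect_clash_pairs(table, params, coords=cv, bonds=bonds,
                                  hbond_pairs=hbond_pairs)
    if len(i) == 0:
        return np.zeros(nres), (i, j, np.zeros(0))
    tg = groups.as_array(g)
    d = _pair_distances(x, i, j)
    gap = (table.radius[i] + table.radius[j] + tg) - d
    w = params.weight("clash")
    e = ad.mul(ad.exp(ad.mul(gap, params.clash_exponent_scale)), w)
    if params.clash_continuous:
        e = e - w
    e = ad.where(value_of(gap) >= 0.0, e, np.zeros(len(i)))
    return _half_scatter(e, table.residue_index[i],
                         table.residue_index[j], nres), (i, j, e)


# ---------------------------------------------------------------------------
# entropy and violation terms
# ---------------------------------------------------------------------------

def backbone_entropy(tset: geometry.TorsionSet, densities: DensityModel,
                     params: ParameterSet, coords):
    """Negative log-probability of the backbone torsions.

    Per residue: w1 * (-ln KDE_omega(omega)) + w2 * (-ln KDE_type(phi, psi));
    masked angles contribute nothing.  Angles are re-derived from the
    coordinate tensor so the term stays differentiable.
    """
    x = coords
    nres = tset.n_residues
    out = None
    rows = np.where(tset.omega_mask)[0]
    if len(rows) and densities.omega is not None:
        idx = tset.omega_idx[rows]
        om = geometry.dihedral(x[idx[:, 0]], x[idx[:, 1]], x[idx[:, 2]], x[idx[:, 3]])
        nll = ad.mul(densities.omega.log_density(om), -params.weight("entropy_omega"))
        out = ad.scatter_add(nll, rows, nres)
    both = tset.phi_mask & tset.psi_mask
    by_type: dict[str, list[int]] = {}
    for r, rt in enumerate(tset.residue_type):
        if both[r]:
            by_type.setdefault(rt, []).append(r)
    for rt, members in by_type.items():
        if rt not in densities.backbone:
            raise SetupError(f"no backbone density for residue type {rt}")
        rows = np.array(members, int)
        pidx, sidx = tset.phi_idx[rows], tset.psi_idx[rows]
        phi = geometry.dihedral(x[pidx[:, 0]], x[pidx[:, 1]],
                                x[pidx[:, 2]], x[pidx[:, 3]])
        psi = geometry.dihedral(x[sidx[:, 0]], x[sidx[:, 1]],
                                x[sidx[:, 2]], x[sidx[:, 3]])
        q = ad.stack([phi, psi], axis=1)
        nll = ad.mul(densities.backbone[rt].log_density(q),
                     -params.weight("entropy_backbone"))
        add = ad.scatter_add(nll, rows, nres)
        out = add if out is None else out + add
    return np.zeros(nres) if out is None else out


def sidechain_entropy(table: AtomTable, sc_exposure, params: ParameterSet,
                      hbond_strength=None, elec_pairs=None, ss_strength=None):
    """Side-chain immobilization entropy cost.

    The per-type entropy constant is scaled by burial (1 - side-chain
    exposure), but a residue whose side chain is held by a hydrogen bond,
    a strong electrostatic residue pair (below
    ``params.strong_elec_threshold``) or a disulfide pays the full cost;
    the gate and the max are smooth so the term stays differentiable.
    """
    nres = table.n_residues
    S = np.array([params.coefficient(rn, "entropy") for rn in table.residue_names])
    zeros = np.zeros(nres)
    hb = zeros if hbond_strength is None else hbond_strength
    ss = zeros if ss_strength is None else ss_strength
    g_hb = ad.sigmoid(ad.mul(hb - 0.3, 1.0 / 0.05))
    g_ss = ad.sigmoid(ad.mul(ss - 0.5, 1.0 / 0.05))
    g_el = zeros
    if elec_pairs is not None and len(elec_pairs[0]):
        i, j, e = elec_pairs
        ri = table.residue_index[i].astype(np.int64)
        rj = table.residue_index[j].astype(np.int64)
        key = ri * nres + rj
        uniq, seg = np.unique(key, return_inverse=True)
        e_rp = ad.scatter_add(e, seg, len(uniq))
        fire = ad.sigmoid(ad.mul(e_rp - params.strong_elec_threshold, -1.0 / 0.1))
        ra = (uniq // nres).astype(int)
        rb = (uniq % nres).astype(int)
        g_el = ad.scatter_add(fire, ra, nres) + ad.scatter_add(fire, rb, nres)
        g_el = 1.0 - ad.exp(ad.mul(g_el, -3.0))
    gate = 1.0 - ad.mul(ad.mul(1.0 - g_hb, 1.0 - g_el), 1.0 - g_ss)
    buried = 1.0 - sc_exposure
    k = params.gate_sharpness
    scale = ad.mul(ad.log(ad.exp(ad.mul(gate, k)) + ad.exp(ad.mul(buried, k))),
                   1.0 / k)
    return ad.mul(scale, S * params.weight("entropy_sidechain"))


def peptide_violation(pep_idx: np.ndarray, densities: DensityModel,
                      params: ParameterSet, coords):
    """Deviation of peptide-bond geometry from the fitted Gaussians.

    V = w * sum over the two bond angles and the N-C distance of
    (x - mu)^2 / (2 sigma^2) -- the negative log-likelihood with its
    constant offset removed, so the minimum is exactly 0 at the means.
    Chain breaks (N-C beyond the break distance) contribute 0.
    ``pep_idx`` rows are (residue, N, C_prev, CA, CA_prev).
    """
    x = coords
    nres_guess = int(pep_idx[:, 0].max()) + 1 if len(pep_idx) else 0
    if len(pep_idx) == 0:
        return np.zeros(0)
    cv = value_of(x)
    g = densities.peptide
    res_i = pep_idx[:, 0]
    iN, iCp, iCA, iCAp = (pep_idx[:, k] for k in range(1, 5))
    ok = np.linalg.norm(cv[iN] - cv[iCp], axis=-1) <= params.chain_break_distance
    out_n = nres_guess
    if not np.any(ok):
        return np.zeros(out_n)
    res_i, iN, iCp, iCA, iCAp = (a[ok] for a in (res_i, iN, iCp, iCA, iCAp))
    d = _pair_distances(x, iN, iCp)
    a1 = geometry.bond_angle(x[iCA], x[iN], x[iCp])
    a2 = geometry.bond_angle(x[iCAp], x[iCp], x[iN])
    v = g["angle_ca_n_cp"].neg_log_excess(a1) \
        + g["angle_cap_cp_n"].neg_log_excess(a2) \
        + g["dist_n_cp"].neg_log_excess(d)
    v = ad.mul(v, params.weight("peptide_violation"))
    return ad.scatter_add(v, res_i, out_n)


def sidechain_violation(tset: geometry.TorsionSet, densities: DensityModel,
                        params: ParameterSet, coords,
                        topo: Topology | None = None):
    """Negative log-probability of the side-chain chi vector.

    Reported relative to a strict upper bound of the fitted density, so
    the value is >= 0 everywhere (a constant shift; gradients are those
    of -w ln KDE(chi)).  Residues without chi angles contribute 0;
    residues missing atoms for some chi slot are skipped.
    """
    topo = topo or load_topology()
    x = coords
    nres = tset.n_residues
    out = None
    by_type: dict[str, list[int]] = {}
    for r, rt in enumerate(tset.residue_type):
        by_type.setdefault(rt, []).append(r)
    for rt, members in by_type.items():
        if rt not in topo:
            continue
        nchi = topo[rt].n_chi
        if nchi == 0:
            continue
        rows = np.array([m for m in members if np.all(tset.chi_mask[m, :nchi])], int)
        if len(rows) == 0:
            continue
        if rt not in densities.chi:
            raise SetupError(f"no chi density for residue type {rt}")
        kde = densities.chi[rt]
        cols = []
        for k in range(nchi):
            qk = tset.chi_idx[rows, k]
            cols.append(geometry.dihedral(x[qk[:, 0]], x[qk[:, 1]],
                                          x[qk[:, 2]], x[qk[:, 3]]))
        q = ad.stack(cols, axis=1)
        offset = math.log(kde.max_density_bound() + kde.floor)
        nll = ad.mul(kde.log_density(q) - offset,
                     -params.weight("sidechain_violation"))
        add = ad.scatter_add(nll, rows, nres)
        out = add if out is None else out + add
    return np.zeros(nres) if out is None else out


# ---------------------------------------------------------------------------
# breakdown + aggregation
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    """Per-term, per-residue energies (kcal/mol) plus the total.

    ``terms`` maps each of the eleven energy classes to an array of length
    n_residues; ``total`` is their grand sum.  When evaluated through a
    gradient-tracked coordinate tensor, ``total_tensor`` retains the graph
    and ``gradient()`` returns dE/dX.
    """

    terms: dict
    residue_labels: list
    total: float
    total_tensor: object | None = None
    coords_tensor: object | None = None
    pair_detail: dict = field(default_factory=dict)

    def term_totals(self) -> dict:
        return {k: float(np.sum(v)) for k, v in self.terms.items()}

    def gradient(self) -> np.ndarray:
        if self.total_tensor is None or self.coords_tensor is None:
            raise ValueError("breakdown was not evaluated with gradient tracking")
        if self.coords_tensor.grad is None:
            self.total_tensor.backward()
        return self.coords_tensor.grad

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(TERM_NAMES) + "\ttotal\n")
            for r, label in enumerate(self.residue_labels):
                row = [self.terms[t][r] for t in TERM_NAMES]
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row)
                         + f"\t{sum(row):.6f}\n")
            fh.write("TOTAL\t" + "\t".join(
                f"{float(np.sum(self.terms[t])):.6f}" for t in TERM_NAMES)
                + f"\t{self.total:.6f}\n")

    def summary(self) -> dict:
        out = {f"total_{k}": v for k, v in self.term_totals().items()}
        out["total"] = self.total
        return out


class EnergyModel:
    """Precomputed evaluation context for one structure.

    Builds the atom table, covalent bond graph, hydrogen-bond pair set
    (for clash grouping), torsion index quadruples and peptide-bond
    indices once; :meth:`evaluate` computes the differentiable breakdown
    for the stored or a supplied coordinate set.
    """

    def __init__(self, s: StructureModel, calib: Calibration,
                 topo: Topology | None = None):
        self.structure = s
        self.calib = calib
        self.params = calib.params
        self.topo = topo or load_topology()
        self.table = assign_atom_annotations(s, self.params)
        t = self.table
        self.nres = t.n_residues
        self.bonds = covalent_bonds(t.coords, t.element)
        self.adj = bond_adjacency(self.bonds, t.n_atoms)
        self.tset = geometry.torsion_set(s, self.topo) if t.n_atoms else None
        self._check_densities()
        p = self.params
        self.kappa = float(value_of(debye_huckel_kappa(
            p.ionic_strength, p.temperature,
            p.dielectric if p.screening_uses_dielectric else 1.0))) \
            if p.ionic_strength > 0 else 0.0
        # peptide bonds: (res_i, N_i, C_prev, CA_i, CA_prev)
        res = s.residues
        pep = []
        for i in range(1, len(res)):
            if res[i].chain_index != res[i - 1].chain_index:
                continue
            ids = (res[i].atom_ids.get("N", -1), res[i - 1].atom_ids.get("C", -1),
                   res[i].atom_ids.get("CA", -1), res[i - 1].atom_ids.get("CA", -1))
            if min(ids) >= 0:
                pep.append((i,) + ids)
        self.pep_idx = np.array(pep, int).reshape(-1, 5)

    def _check_densities(self):
        d = self.calib.densities
        missing = []
        for rn in set(self.table.residue_names):
            if rn not in self.topo:
                continue
            if rn not in d.backbone:
                missing.append(f"backbone:{rn}")
            if self.topo[rn].n_chi and rn not in d.chi:
                missing.append(f"chi:{rn}")
        if d.omega is None:
            missing.append("omega")
        if missing:
            raise SetupError("missing fitted densities: " + ", ".join(sorted(missing)))

    def evaluate(self, coords=None, track_gradient: bool = True) -> EnergyBreakdown:
        t, p = self.table, self.params
        nres = self.nres
        labels = [f"{r.chain_id}:{r.name}{r.res_id}" for r in self.structure.residues]
        if t.n_atoms == 0:
            return EnergyBreakdown(terms={k: np.zeros(nres) for k in TERM_NAMES},
                                   residue_labels=labels, total=0.0)
        if coords is None:
            coords = t.coords
        x = coords if is_tensor(coords) else (
            Tensor(np.asarray(coords, float)) if track_gradient
            else np.asarray(coords, float))

        atom_exp, res_exp, sc_exp = geometry.solvent_exposure(t, p, coords=x)

        terms: dict[str, object] = {}
        terms["electrostatics"], elec_pairs = electrostatics(
            t, p, coords=x, adj=self.adj, kappa=self.kappa)
        terms["hbond"], hb_strength = hydrogen_bonds(t, p, coords=x, adj=self.adj)
        terms["disulfide"], ss_strength = disulfide(t, p, coords=x, adj=self.adj)
        terms["solvation_polar"], terms["solvation_hydrophobic"] = \
            solvation(t, res_exp, p)
        terms["vdw"] = vdw(t, atom_exp, p)
        # hydrogen-bond detection (for clash grouping) follows the current
        # geometry so re-evaluating a relaxed structure is self-consistent
        hb_pairs = detect_hbond_pairs(t, p, coords=value_of(x))
        terms["clash"], clash_pairs = clash(
            t, self.calib.clash, p, coords=x, bonds=self.bonds,
            hbond_pairs=hb_pairs)
        terms["entropy_backbone"] = backbone_entropy(
            self.tset, self.calib.densities, p, x)
        terms["entropy_sidechain"] = sidechain_entropy(
            t, sc_exp, p, hbond_strength=hb_strength,
            elec_pairs=elec_pairs, ss_strength=ss_strength)
        pv = peptide_violation(self.pep_idx, self.calib.densities, p, x) \
            if len(self.pep_idx) else np.zeros(nres)
        if len(value_of(pv)) < nres:
            pad = np.zeros(nres)
            pad[:len(value_of(pv))] = value_of(pv)
            pv = pad if not is_tensor(pv) else ad.scatter_add(
                pv, np.arange(len(value_of(pv))), nres)
        terms["peptide_violation"] = pv
        terms["sidechain_violation"] = sidechain_violation(
            self.tset, self.calib.densities, p, x, self.topo)

        total_t = None
        for k in TERM_NAMES:
            total_t = terms[k] if total_t is None else total_t + terms[k]
        total_scalar = ad.tsum(total_t)
        total = float(value_of(total_scalar))
        np_terms = {k: np.asarray(value_of(v), float).copy()
                    for k, v in terms.items()}
        return EnergyBreakdown(
            terms=np_terms, residue_labels=labels, total=total,
            total_tensor=total_scalar if is_tensor(total_scalar) else None,
            coords_tensor=x if is_tensor(x) else None,
            pair_detail={"electrostatics": elec_pairs, "clash": clash_pairs},
        )


def total_energy(s: StructureModel, calib: Calibration,
                 coords=None, topo: Topology | None = None,
                 track_gradient: bool = True) -> EnergyBreakdown:
    """Evaluate the full energy breakdown of a structure.

    Expects polar hydrogens already placed (see
    :func:`gradff.structure_io.add_polar_hydrogens`); without them the
    hydrogen-bond term is simply zero.
    """
    return EnergyModel(s, calib, topo).evaluate(coords, track_gradient=track_gradient)
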