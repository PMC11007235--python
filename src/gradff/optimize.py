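"""Gradient-based relaxation and the chi-rotation mutation operator.

Cartesian mode moves every atom along -dE/dX; torsion mode optimizes
(phi, psi, omega, chi) and rebuilds coordinates by forward kinematics
each step, so covalent bond lengths and angles stay exactly at their
template values.  Both modes use the analytic gradients of the energy
graph; the optimizers are plain gradient descent (default) and an
adaptive-moment scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import Tensor, value_of
from .calibration import Calibration
from .energies import EnergyBreakdown, EnergyModel
from .structure_io import StructureModel
from .topology import Topology, load_topology

__all__ = ["RelaxResult", "relax_cartesian", "relax_torsion", "rotate_chi"]

log = logging.getLogger(__name__)


@dataclass
class RelaxResult:
    """Outcome of a relaxation run."""

    energy_trajectory: list
    structure: StructureModel
    initial_breakdown: EnergyBreakdown
    final_breakdown: EnergyBreakdown
    steps_taken: int
    converged: bool
    seed: int
    mode: str = "cartesian"
    per_term_trajectory: list = field(default_factory=list)

    @property
    def initial_energy(self) -> float:
        return self.energy_trajectory[0]

    @property
    def final_energy(self) -> float:
        return self.energy_trajectory[-1]

    def write_trajectory(self, path) -> None:
        names = list(self.initial_breakdown.terms)
        with open(path, "w") as fh:
            fh.write("step\ttotal\t" + "\t".join(names) + "\n")
            for k, (e, terms) in enumerate(zip(self.energy_trajectory,
                                               self.per_term_trajectory)):
                fh.write(f"{k}\t{e:.6f}\t"
                         + "\t".join(f"{terms[n]:.6f}" for n in names) + "\n")


class _Adam:
    """Standard adaptive-moment estimation update."""

    def __init__(self, shape, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, x, g):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip(g: np.ndarray, max_norm: float | None) -> np.ndarray:
    if max_norm is None:
        return g
    n = float(np.linalg.norm(g))
    return g if n <= max_norm else g * (max_norm / n)


def _check_start(bd: EnergyBreakdown) -> None:
    if not np.isfinite(bd.total):
        bad = [k for k, v in bd.term_totals().items() if not np.isfinite(v)]
        raise ValueError(f"non-finite starting energy in term(s): {bad}")


def relax_cartesian(s: StructureModel, calib: Calibration, steps: int = 200,
                    step_size: float = 1e-4, optimizer: str = "gd",
                    seed: int = 0, tol: float = 1e-4,
                    patience: int = 10,
                    grad_clip: float | None = 1e3) -> RelaxResult:
    """Minimize the total energy over Cartesian coordinates.

    Deterministic given the inputs; convergence is declared when the
    energy change stays below ``tol`` (kcal/mol) for ``patience``
    consecutive steps.  ``grad_clip`` caps the gradient norm (useful on
    the steep exponential clash wall).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    model = EnergyModel(s, calib)
    x = s.coords.copy()
    bd = model.evaluate(x)
    _check_start(bd)
    first = bd
    traj = [bd.total]
    term_traj = [bd.term_totals()]
    adam = _Adam(x.shape, step_size) if optimizer == "adaptive-moment" else None
    if optimizer not in ("gd", "adaptive-moment"):
        raise ValueError("optimizer must be 'gd' or 'adaptive-moment'")
    still = 0
    k = 0
    converged = False
    for k in range(1, steps + 1):
        g = _clip(bd.gradient(), grad_clip)
        x = adam.step(x, g) if adam is not None else x - step_size * g
        bd = model.evaluate(x)
        traj.append(bd.total)
        term_traj.append(bd.term_totals())
        still = still + 1 if abs(traj[-1] - traj[-2]) < tol else 0
        if still >= patience:
            converged = True
            break
    return RelaxResult(energy_trajectory=traj,
                       structure=s.with_coords(x),
                       initial_breakdown=first, final_breakdown=bd,
                       steps_taken=len(traj) - 1, converged=converged,
                       seed=seed, mode="cartesian",
                       per_term_trajectory=term_traj)


def _dof_layout(tset: geometry.TorsionSet):
    """Flatten (phi, psi, omega, chi) into one vector; returns slot maps."""
    n = tset.n_residues
    entries = []  # (kind, residue, chi slot)
    for i in range(n):
        entries.append(("phi", i, -1))
        entries.append(("psi", i, -1))
        entries.append(("omega", i, -1))
        for k in range(5):
            if tset.chi_mask[i, k]:
                entries.append(("chi", i, k))
    vec = np.empty(len(entries))
    for e, (kind, i, k) in enumerate(entries):
        vec[e] = tset.chi[i, k] if kind == "chi" else getattr(tset, kind)[i]
    return entries, vec


def _rebuild(model: EnergyModel, tset, entries, theta, topo,
             atom_map: np.ndarray, optimize_mask: np.ndarray):
    """Coordinates (structure order) from a dof vector tensor."""
    n = tset.n_residues
    phi = [None] * n
    psi = [None] * n
    omega = [None] * n
    chi = [[topo[tset.residue_type[i]].default_chi[k]
            if k < topo[tset.residue_type[i]].n_chi else 0.0
            for k in range(5)] for i in range(n)]
    for e, (kind, i, k) in enumerate(entries):
        val = theta[e]
        if kind == "chi":
            chi[i][k] = val
        elif kind == "phi":
            phi[i] = val
        elif kind == "psi":
            psi[i] = val
        else:
            omega[i] = val
    dofs = {"phi": phi, "psi": psi, "omega": omega, "chi": chi}
    keys, positions = geometry.build_chain_coords(
        tset.residue_type, dofs, topo, include_hydrogens=True)
    coords = ad.stack(positions, axis=0)
    return coords[atom_map]


def relax_torsion(s: StructureModel, calib: Calibration, steps: int = 100,
                  step_size: float = 1e-3, optimizer: str = "gd",
                  seed: int = 0, tol: float = 1e-4, patience: int = 10,
                  only_chi: bool = False,
                  grad_clip: float | None = 50.0) -> RelaxResult:
    """Minimize the energy over torsion angles with ideal covalent geometry.

    The input is first idealized: torsions are extracted and coordinates
    rebuilt from the topology template (single chain only), then the
    torsion vector is optimized with coordinates re-derived by forward
    kinematics at every step.  With ``only_chi`` the backbone torsions
    are frozen and only side-chain angles move.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    topo = load_topology()
    tset = geometry.torsion_set(s, topo)
    if tset.chain_index is not None and len(set(tset.chain_index.tolist())) > 1:
        raise ValueError("torsion relaxation supports a single chain")
    entries, theta0 = _dof_layout(tset)
    keys, _ = geometry.rebuild_from_torsions(tset, topo)
    key_to_row = {kk: r for r, kk in enumerate(keys)}
    res = s.residues
    atom_map = []
    for i, r in enumerate(res):
        for name, gi in sorted(r.atom_ids.items(), key=lambda kv: kv[1]):
            if (i, name) not in key_to_row:
                raise ValueError(f"atom {r.name}:{name} not in topology template")
            atom_map.append(key_to_row[(i, name)])
    atom_map = np.array(atom_map, int)

    model = EnergyModel(s, calib)
    opt_mask = np.ones(len(entries), bool)
    if only_chi:
        opt_mask = np.array([kind == "chi" for kind, _, _ in entries])

    theta = theta0.copy()

    def energy_at(th):
        th_t = Tensor(th)
        coords = _rebuild(model, tset, entries, th_t, topo, atom_map, opt_mask)
        bd = model.evaluate(coords)
        return bd, th_t

    bd, th_t = energy_at(theta)
    _check_start(bd)
    first = bd
    traj = [bd.total]
    term_traj = [bd.term_totals()]
    adam = _Adam(theta.shape, step_size) if optimizer == "adaptive-moment" else None
    still = 0
    converged = False
    for k in range(1, steps + 1):
        bd.total_tensor.backward()
        g = np.where(opt_mask, th_t.grad, 0.0)
        g = _clip(g, grad_clip)
        theta = adam.step(theta, g) if adam is not None else theta - step_size * g
        bd, th_t = energy_at(theta)
        traj.append(bd.total)
        term_traj.append(bd.term_totals())
        still = still + 1 if abs(traj[-1] - traj[-2]) < tol else 0
        if still >= patience:
            converged = True
            break
    final_coords = value_of(bd.coords_tensor) if bd.coords_tensor is not None \
        else value_of(_rebuild(model, tset, entries, Tensor(theta), topo,
                               atom_map, opt_mask))
    return RelaxResult(energy_trajectory=traj,
                       structure=s.with_coords(final_coords),
                       initial_breakdown=first, final_breakdown=bd,
                       steps_taken=len(traj) - 1, converged=converged,
                       seed=seed, mode="torsion",
                       per_term_trajectory=term_traj)


def rotate_chi(s: StructureModel, residue, delta,
               topo: Topology | None = None) -> StructureModel:
    """Rotate a residue's side chain about its chi axes by ``delta``.

    ``residue`` is a residue index or a ``(chain_id, res_id)`` pair;
    ``delta`` holds up to five angles in radians (slot k rotates all
    atoms distal to the chi-k axis).  The backbone and every other
    residue are untouched.
    """
    topo = topo or load_topology()
    res = s.residues
    if isinstance(residue, (tuple, list)):
        matches = [r for r in res if (r.chain_id, r.res_id) == tuple(residue)]
        if not matches:
            raise ValueError(f"no residue matches {residue}")
        r = matches[0]
    else:
        if not 0 <= int(residue) < len(res):
            raise ValueError(f"residue index {residue} out of range")
        r = res[int(residue)]
    if r.name not in topo or topo[r.name].n_chi == 0:
        raise ValueError(f"residue {r.name} has no rotatable chi angles")
    rt = topo[r.name]
    delta = np.atleast_1d(np.asarray(delta, float))
    coords = s.coords.copy()

    # distal atoms per chi slot: topology order after the chi tip, plus the
    # tip itself for slots below
    order = [a.name for a in rt.sidechain]
    for k, quad in enumerate(rt.chi[:len(delta)]):
        d = float(delta[k])
        if d == 0.0:
            continue
        b_name, c_name = quad[1], quad[2]
        axis_from = r.atom_ids.get(quad[1])
        axis_to = r.atom_ids.get(quad[2])
        if axis_from is None or axis_to is None:
            continue
        # atoms that move: everything placed after the axis atom in the
        # side-chain build order whose ancestry passes through the axis
        moving = _distal_atoms(rt, quad[2])
        idx = [r.atom_ids[nm] for nm in moving if nm in r.atom_ids]
        if not idx:
            continue
        p0 = coords[axis_from]
        axis = coords[axis_to] - p0
        axis = axis / np.linalg.norm(axis)
        rel = coords[idx] - p0
        coords[idx] = p0 + _rodrigues(rel, axis, d)
    return s.with_coords(coords)


def _distal_atoms(rt, axis_atom: str) -> list[str]:
    """Side-chain atoms whose placement chain passes through ``axis_atom``."""
    parent = {a.name: a.refs[0] for a in rt.sidechain}
    out = []
    for a in rt.sidechain:
        nm = a.name
        seen = set()
        cur = nm
        while cur in parent and cur not in seen:
            seen.add(cur)
            cur = parent[cur]
            if cur == axis_atom:
                out.append(nm)
                break
    return out


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s_ = np.cos(angle), np.sin(angle)
    return (v * c + np.cross(axis, v) * s_
            + np.outer(v @ axis, axis) * (1 - c))
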