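"""Calibration: physical constants, clash-group corrections, torsion
densities and peptide-geometry Gaussians.

The knowledge-based terms of the force field are parameterized from a
reference set of structures: per-group 10th-percentile clash corrections,
periodic kernel-density estimates of backbone (phi, psi), omega and
side-chain chi angles, and Gaussians for peptide-bond geometry.  The
density estimator is a mixture of wrapped-Gaussian kernels placed at the
(optionally subsampled) observations -- exactly normalizable over the
periodic domain and differentiable in the query angles, so the entropy
and violation terms remain part of the gradient graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from . import geometry
from .autodiff import value_of, is_tensor
from .params import CLASH_GROUPS, ParameterSet
from .structure_io import (AtomTable, StructureModel, add_polar_hydrogens,
                           assign_atom_annotations, covalent_bonds)
from .topology import Topology, load_topology

__all__ = [
    "CalibrationError",
    "debye_huckel_kappa",
    "ClashGroupTable",
    "PeriodicKDE",
    "PeptideGaussian",
    "DensityModel",
    "Calibration",
    "detect_hbond_pairs",
    "collect_clash_pairs",
    "fit_clash_corrections",
    "fit_torsion_density",
    "fit_peptide_gaussians",
    "fit_density_model",
    "fit_calibration",
    "default_calibration",
]

log = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when a fit has too few samples or a group is empty."""


# ---------------------------------------------------------------------------
# Debye-Hueckel screening
# ---------------------------------------------------------------------------

# Gaussian-units physical constants (CODATA): elementary charge in esu,
# Boltzmann constant in erg/K, Avogadro's number
_E_ESU = 4.80320425e-10
_K_ERG = 1.380649e-16
_N_AVOGADRO = 6.02214076e23


def debye_huckel_kappa(ionic_strength, temperature, epsilon: float = 1.0):
    """Inverse screening length K in 1/Angstrom.

    K = sqrt(8 pi e^2 N_A I / (1000 k T epsilon)); with ``epsilon=1`` this
    is the bare physical-constant product, passing the solvent dielectric
    gives the conventional Debye parameter.  Differentiable in I and T;
    K(0, T) = 0.
    """
    iv = float(np.min(value_of(ionic_strength)))
    if iv < 0:
        raise ValueError("ionic strength must be non-negative")
    if float(np.min(value_of(temperature))) <= 0:
        raise ValueError("temperature must be positive")
    if not is_tensor(ionic_strength) and iv == 0.0:
        return 0.0
    c = 8.0 * math.pi * _E_ESU ** 2 * _N_AVOGADRO / (1000.0 * _K_ERG * epsilon)
    k2_cm = ad.div(ad.mul(ionic_strength, c), temperature)
    return ad.mul(ad.sqrt(k2_cm), 1e-8)  # cm^-1 -> A^-1


# ---------------------------------------------------------------------------
# clash-group corrections
# ---------------------------------------------------------------------------

@dataclass
class ClashGroupTable:
    """Per-group distance corrections t_g (Angstrom) and sample counts.

    t_g is the 10th percentile of the observed gap d - (R_i + R_j) for the
    group, so the clash threshold distance of a pair is R_i + R_j + t_g.
    """

    t: dict
    counts: dict

    def __post_init__(self):
        if set(self.t) != set(CLASH_GROUPS):
            raise ValueError(f"expected the six groups {CLASH_GROUPS}")

    def as_array(self, group_ids: np.ndarray) -> np.ndarray:
        lut = np.array([self.t[g] for g in CLASH_GROUPS])
        return lut[group_ids]


def detect_hbond_pairs(table: AtomTable, params: ParameterSet,
                       coords: np.ndarray | None = None) -> set[tuple[int, int]]:
    """Geometric hydrogen-bond detection.

    A donor H and an acceptor within 2.5 Angstrom with a D-H...A angle
    above 110 deg count as hydrogen bonded; both the (H, A) and the
    (D, A) pair are returned (sorted index pairs).
    """
    x = table.coords if coords is None else coords
    hs = np.where(table.is_donor_h)[0]
    accs = np.where(table.is_acceptor)[0]
    out: set[tuple[int, int]] = set()
    if len(hs) == 0 or len(accs) == 0:
        return out
    d = np.linalg.norm(x[hs][:, None, :] - x[accs][None, :, :], axis=-1)
    for hi, ai in zip(*np.where(d <= 2.5)):
        h, acc = int(hs[hi]), int(accs[ai])
        don = int(table.donor_heavy[h])
        if don < 0 or acc == don or table.residue_index[acc] == table.residue_index[h]:
            continue
        ang = geometry.bond_angle(x[don], x[h], x[acc])
        if ang > math.radians(110.0):
            out.add(tuple(sorted((h, acc))))
            out.add(tuple(sorted((don, acc))))
    return out


def _rigid_group_pairs(table: AtomTable, params: ParameterSet) -> set[tuple[int, int]]:
    """Atom pairs inside the same rigid planar group, plus the proline
    special pairs (preceding carbonyl C/O with the proline CD)."""
    groups = params.tables.get("rigid_groups", {})
    out: set[tuple[int, int]] = set()
    nres = table.n_residues
    res_atoms: dict[int, dict] = {i: {} for i in range(nres)}
    for k in range(table.n_atoms):
        res_atoms[table.residue_index[k]][table.atom_name[k]] = k
    for i in range(nres):
        rn = table.residue_names[i]
        for grp in groups.get(rn, []):
            ids = [res_atoms[i][a] for a in grp if a in res_atoms[i]]
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    out.add(tuple(sorted((ids[a], ids[b]))))
        if rn == "PRO" and i > 0 and "CD" in res_atoms[i]:
            cd = res_atoms[i]["CD"]
            for nm in ("C", "O"):
                if nm in res_atoms[i - 1]:
                    out.add(tuple(sorted((res_atoms[i - 1][nm], cd))))
    return out


def collect_clash_pairs(table: AtomTable, params: ParameterSet,
                        coords: np.ndarray | None = None,
                        bonds: set | None = None,
                        hbond_pairs: set | None = None):
    """Atom pairs within the clash cutoff, with exclusions and group labels.

    Excluded: covalently connected pairs -- directly bonded or sharing a
    bonded neighbor (1-2 and 1-3; their separation is fixed by bond
    lengths and angles, like the rigid groups) -- except disulfides,
    pairs inside a rigid planar group (aromatic rings, the proline
    carbonyl/CD pairs), and backbone pairs of the same residue.  The
    remaining pairs get a group id indexing
    :data:`gradff.params.CLASH_GROUPS`.

    Returns ``(i, j, group_id)`` integer arrays.
    """
    x = table.coords if coords is None else coords
    n = table.n_atoms
    if n < 2:
        z = np.empty(0, int)
        return z, z, z
    if bonds is None:
        bonds = covalent_bonds(x, table.element)
    if hbond_pairs is None:
        hbond_pairs = detect_hbond_pairs(table, params, coords=x)
    rigid = _rigid_group_pairs(table, params)
    adj: dict[int, set] = {k: set() for k in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)

    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    ii, jj = np.where(np.triu(d <= params.clash_cutoff, k=1))

    gid = {g: k for k, g in enumerate(CLASH_GROUPS)}
    is_don_heavy = np.zeros(n, bool)
    if table.donor_heavy is not None:
        parents = table.donor_heavy[table.donor_heavy >= 0]
        is_don_heavy[parents] = True
    donorish = is_don_heavy | table.is_donor_h
    out_i, out_j, out_g = [], [], []
    ridx = table.residue_index
    for a, b in zip(ii, jj):
        a, b = int(a), int(b)
        pair = (a, b)
        is_ss = (table.is_sulfur[a] and table.is_sulfur[b]
                 and table.res_name[a] == "CYS" and table.res_name[b] == "CYS"
                 and d[a, b] <= params.disulfide_cutoff)
        covalent_12_13 = (pair in bonds) or bool(adj[a] & adj[b])
        if covalent_12_13 and not is_ss:
            continue
        if pair in rigid:
            continue
        same_res = ridx[a] == ridx[b]
        both_bb = table.is_backbone[a] and table.is_backbone[b]
        if same_res and both_bb:
            continue
        if is_ss:
            g = gid["disulfide"]
        elif same_res:
            g = gid["same_residue"]
        elif pair in hbond_pairs:
            g = gid["hbond"]
        elif (both_bb and abs(int(ridx[a]) - int(ridx[b])) == 1
              and table.chain_index[a] == table.chain_index[b]):
            g = gid["consecutive_backbone"]
        elif (donorish[a] and table.is_acceptor[b]) or \
                (donorish[b] and table.is_acceptor[a]):
            g = gid["donor_acceptor"]
        else:
            g = gid["other"]
        out_i.append(a)
        out_j.append(b)
        out_g.append(g)
    return np.array(out_i, int), np.array(out_j, int), np.array(out_g, int)


def fit_clash_corrections(refs: list[StructureModel],
                          params: ParameterSet | None = None) -> ClashGroupTable:
    """Fit per-group corrections from a reference structure set.

    For every retained pair within the clash cutoff the gap
    d - (R_i + R_j) is collected; t_g is the per-group 10th percentile
    (linear interpolation between order statistics).  Groups with fewer
    than ``params.min_group_count`` samples raise
    :class:`CalibrationError` naming the group.
    """
    params = params or ParameterSet()
    gaps: dict[str, list[float]] = {g: [] for g in CLASH_GROUPS}
    for s in refs:
        s = add_polar_hydrogens(s)
        table = assign_atom_annotations(s, params)
        i, j, g = collect_clash_pairs(table, params)
        if len(i) == 0:
            continue
        d = np.linalg.norm(table.coords[i] - table.coords[j], axis=-1)
        gap = d - (table.radius[i] + table.radius[j])
        for k, gname in enumerate(CLASH_GROUPS):
            gaps[gname].extend(gap[g == k].tolist())
    t, counts = {}, {}
    for gname in CLASH_GROUPS:
        vals = np.asarray(gaps[gname])
        counts[gname] = len(vals)
        if len(vals) < max(params.min_group_count, 1):
            if params.min_group_count <= 0 and len(vals) == 0:
                t[gname] = 0.0
                continue
            raise CalibrationError(
                f"clash group {gname!r} has {len(vals)} samples "
                f"(minimum {params.min_group_count})")
        t[gname] = float(np.percentile(vals, params.clash_percentile,
                                       method="linear"))
    return ClashGroupTable(t=t, counts=counts)


# ---------------------------------------------------------------------------
# periodic kernel densities
# ---------------------------------------------------------------------------

@dataclass
class PeriodicKDE:
    """Mixture of wrapped-Gaussian product kernels on (-pi, pi]^k.

    Integrates to 1 over the periodic domain by construction (wrapping is
    truncated at +-``wraps`` periods, negligible for bandwidths below
    ~40 deg).  ``log_density`` is differentiable in the query angles.
    """

    centers: np.ndarray      # (m, k)
    bandwidth: np.ndarray    # (k,)
    wraps: int = 2
    floor: float = 1e-12

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.bandwidth = np.atleast_1d(np.asarray(self.bandwidth, float))
        if np.any(self.bandwidth <= 0):
            raise ValueError("bandwidths must be positive")

    @property
    def ndim(self) -> int:
        return self.centers.shape[1]

    def density(self, x):
        """Density at query points x of shape (n, k) (or (n,) for k=1)."""
        xv = value_of(x)
        if xv.ndim == 1 and self.ndim == 1:
            x = ad.expand_dims(x, 1) if is_tensor(x) else xv[:, None]
        m = len(self.centers)
        offsets = 2.0 * np.pi * np.arange(-self.wraps, self.wraps + 1)
        prod = None
        for k in range(self.ndim):
            h = self.bandwidth[k]
            xk = x[:, k] if not is_tensor(x) else x[:, k]
            diff = ad.expand_dims(xk, 1) - self.centers[None, :, k]   # (n, m)
            z = ad.expand_dims(diff, 2) + offsets[None, None, :]      # (n, m, w)
            kern = ad.tsum(ad.exp(ad.mul(ad.mul(z, z), -0.5 / h ** 2)), axis=2)
            kern = ad.mul(kern, 1.0 / (h * math.sqrt(2.0 * math.pi)))
            prod = kern if prod is None else ad.mul(prod, kern)
        return ad.mul(ad.tsum(prod, axis=1), 1.0 / m)

    def log_density(self, x):
        return ad.log(self.density(x) + self.floor)

    def max_density_bound(self) -> float:
        """A strict upper bound of the density anywhere on the domain."""
        bound = 1.0
        for h in self.bandwidth:
            tail = 1.0 + 2.0 * math.exp(-0.5 * (math.pi / h) ** 2) * self.wraps
            bound *= tail / (h * math.sqrt(2.0 * math.pi))
        return bound * 1.0000001

    def mode_estimate(self, grid: int = 360) -> np.ndarray:
        """Grid-scan estimate of the global mode (for 1-D and 2-D)."""
        axes = [np.linspace(-np.pi, np.pi, grid, endpoint=False)] * self.ndim
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        dens = np.asarray(value_of(self.density(pts)))
        return pts[int(np.argmax(dens))]

    def integral(self, grid: int = 360) -> float:
        """Trapezoid-free Riemann quadrature of the density over the domain."""
        axes = [np.linspace(-np.pi, np.pi, grid, endpoint=False)] * self.ndim
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        cell = (2.0 * np.pi / grid) ** self.ndim
        total = 0.0
        step = 200000
        for a in range(0, len(pts), step):
            total += float(np.sum(value_of(self.density(pts[a:a + step])))) * cell
        return total


def _circular_std(samples: np.ndarray) -> float:
    z = np.exp(1j * samples)
    r = abs(np.mean(z))
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return math.sqrt(-2.0 * math.log(r))


def fit_torsion_density(samples: np.ndarray, params: ParameterSet | None = None,
                        seed: int = 0) -> PeriodicKDE:
    """Fit a periodic KDE to angle samples of shape (n, k) or (n,).

    Bandwidth per dimension follows the circular Silverman rule
    (config-overridable); centers are subsampled to
    ``params.max_kde_centers`` with the given seed.
    """
    params = params or ParameterSet()
    samples = np.asarray(samples, float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if samples.shape[0] < params.min_density_samples:
        raise CalibrationError(
            f"{samples.shape[0]} samples below minimum "
            f"{params.min_density_samples}")
    n, k = samples.shape
    samples = geometry.wrap_angle(samples)
    if params.kde_bandwidth is not None:
        h = np.full(k, float(params.kde_bandwidth))
    else:
        factor = (4.0 / ((k + 2.0) * n)) ** (1.0 / (k + 4.0))
        h = np.array([max(_circular_std(samples[:, j]) * factor, 0.035)
                      for j in range(k)])
    if n > params.max_kde_centers:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, params.max_kde_centers, replace=False)
        centers = samples[idx]
    else:
        centers = samples
    return PeriodicKDE(centers=centers, bandwidth=h, floor=params.density_floor)


# ---------------------------------------------------------------------------
# peptide-geometry Gaussians
# ---------------------------------------------------------------------------

@dataclass
class PeptideGaussian:
    mean: float
    sigma: float

    def neg_log_excess(self, x):
        """-ln G(x) with the constant offset removed: (x - mu)^2 / (2 sigma^2)."""
        z = ad.mul(x - self.mean, 1.0 / self.sigma)
        return ad.mul(ad.mul(z, z), 0.5)


def fit_peptide_gaussians(obs: list, params: ParameterSet | None = None,
                          min_observations: int | None = None) -> dict:
    """Sample mean/std Gaussians for the two peptide-bond angles and the
    N-C bond length, from non-excluded observations."""
    params = params or ParameterSet()
    min_obs = params.min_group_count if min_observations is None else min_observations
    usable = [o for o in obs if not o.excluded]
    if len(usable) < min_obs:
        raise CalibrationError(
            f"{len(usable)} peptide-bond observations below minimum {min_obs}")
    cols = {
        "angle_ca_n_cp": np.array([o.angle_ca_n_cp for o in usable]),
        "angle_cap_cp_n": np.array([o.angle_cap_cp_n for o in usable]),
        "dist_n_cp": np.array([o.dist_n_cp for o in usable]),
    }
    out = {}
    for name, vals in cols.items():
        out[name] = PeptideGaussian(
            mean=float(np.mean(vals)),
            sigma=float(max(np.std(vals, ddof=1) if len(vals) > 1 else 0.0,
                            params.peptide_sigma_floor)),
        )
    return out


# ---------------------------------------------------------------------------
# density model + calibration container
# ---------------------------------------------------------------------------

@dataclass
class DensityModel:
    """Fitted periodic densities and peptide Gaussians."""

    backbone: dict = field(default_factory=dict)   # res type -> PeriodicKDE (2-D)
    omega: PeriodicKDE | None = None               # 1-D, shared
    chi: dict = field(default_factory=dict)        # res type -> PeriodicKDE
    peptide: dict = field(default_factory=dict)    # name -> PeptideGaussian


def fit_density_model(refs: list[StructureModel],
                      params: ParameterSet | None = None,
                      seed: int = 0,
                      topo: Topology | None = None) -> DensityModel:
    """Fit all torsion densities and peptide Gaussians from reference
    structures; residue types without enough samples are skipped with a
    warning (energy setup will fail only if such a type is evaluated)."""
    params = params or ParameterSet()
    topo = topo or load_topology()
    bb: dict[str, list] = {}
    om: list[float] = []
    chis: dict[str, list] = {}
    pep_obs: list = []
    for s in refs:
        tset = geometry.torsion_set(s, topo)
        for i, rt in enumerate(tset.residue_type):
            if tset.phi_mask[i] and tset.psi_mask[i]:
                bb.setdefault(rt, []).append((tset.phi[i], tset.psi[i]))
            if tset.omega_mask[i]:
                om.append(tset.omega[i])
            nchi = topo[rt].n_chi if rt in topo else 0
            if nchi and np.all(tset.chi_mask[i, :nchi]):
                chis.setdefault(rt, []).append(tset.chi[i, :nchi].tolist())
        pep_obs.extend(geometry.peptide_geometry(
            s, max_bond_distance=params.chain_break_distance))

    model = DensityModel()
    for rt, vals in bb.items():
        try:
            model.backbone[rt] = fit_torsion_density(np.array(vals), params, seed)
        except CalibrationError as err:
            log.warning("backbone density for %s skipped: %s", rt, err)
    if len(om) >= params.min_density_samples:
        model.omega = fit_torsion_density(np.array(om), params, seed)
    else:
        raise CalibrationError(f"only {len(om)} omega samples")
    for rt, vals in chis.items():
        try:
            model.chi[rt] = fit_torsion_density(np.array(vals), params, seed)
        except CalibrationError as err:
            log.warning("chi density for %s skipped: %s", rt, err)
    model.peptide = fit_peptide_gaussians(pep_obs, params)
    return model


@dataclass
class Calibration:
    """Everything :func:`gradff.energies.total_energy` needs."""

    params: ParameterSet
    clash: ClashGroupTable
    densities: DensityModel
    seed: int = 0
    version: str = "1"

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def kde(k: PeriodicKDE):
            return {"centers": np.round(k.centers, 5).tolist(),
                    "bandwidth": np.round(k.bandwidth, 6).tolist()}

        return {
            "version": self.version,
            "seed": self.seed,
            "clash": {"t": self.clash.t, "counts": self.clash.counts},
            "densities": {
                "backbone": {t: kde(k) for t, k in self.densities.backbone.items()},
                "omega": kde(self.densities.omega),
                "chi": {t: kde(k) for t, k in self.densities.chi.items()},
                "peptide": {n: {"mean": g.mean, "sigma": g.sigma}
                            for n, g in self.densities.peptide.items()},
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True,
                           default_flow_style=None)

    @classmethod
    def load(cls, path: str | Path, params: ParameterSet | None = None) -> "Calibration":
        params = params or ParameterSet()
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def kde(d):
            return PeriodicKDE(centers=np.array(d["centers"]),
                               bandwidth=np.array(d["bandwidth"]),
                               floor=params.density_floor)

        dens = DensityModel(
            backbone={t: kde(d) for t, d in raw["densities"]["backbone"].items()},
            omega=kde(raw["densities"]["omega"]),
            chi={t: kde(d) for t, d in raw["densities"]["chi"].items()},
            peptide={n: PeptideGaussian(**g)
                     for n, g in raw["densities"]["peptide"].items()},
        )
        return cls(params=params,
                   clash=ClashGroupTable(t=dict(raw["clash"]["t"]),
                                         counts=dict(raw["clash"]["counts"])),
                   densities=dens,
                   seed=int(raw.get("seed", 0)),
                   version=str(raw.get("version", "1")))


def fit_calibration(refs: list[StructureModel],
                    params: ParameterSet | None = None,
                    seed: int = 0) -> Calibration:
    """Fit clash corrections, densities and peptide Gaussians in one go."""
    params = params or ParameterSet()
    return Calibration(
        params=params,
        clash=fit_clash_corrections(refs, params),
        densities=fit_density_model(refs, params, seed=seed),
        seed=seed,
    )


_DEFAULT_CACHE: dict = {}


def default_calibration(seed: int = 0, n_reference: int = 375,
                        params: ParameterSet | None = None) -> Calibration:
    """Calibration fitted on the package's own synthetic reference set.

    The set interleaves jittered helices, strands and disulfide-bridged
    constructs (2:2:1) so that every residue type clears the per-density
    sample minimum and every clash group is populated.  Cached per
    (seed, n_reference) within the process.
    """
    key = (seed, n_reference, id(params) if params is not None else None)
    if key not in _DEFAULT_CACHE:
        from .fixtures import build_reference_set

        refs = build_reference_set(
            n_reference,
            mix=("helix", "strand", "helix", "strand", "cys_bridge"),
            seed=seed)
        _DEFAULT_CACHE[key] = fit_calibration(refs, params, seed=seed)
    return _DEFAULT_CACHE[key]
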