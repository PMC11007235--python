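"""Differentiable geometry: distances, dihedrals, torsions, exposure,
peptide-bond observations and torsion-space forward kinematics."""

import numpy as np
import pytest

from gradff import autodiff as ad
from gradff import fixtures as fx
from gradff import geometry as geo
from gradff import structure_io as sio
from gradff.params import ParameterSet
from gradff.topology import load_topology

from conftest import fd_gradient


def _synthetic_table(coords, residue_index=None):
    n = len(coords)
    ridx = np.arange(n) if residue_index is None else np.asarray(residue_index)
    nres = int(ridx.max()) + 1
    return sio.AtomTable(
        coords=np.asarray(coords, float),
        q=np.zeros(n), radius=np.full(n, 1.7),
        is_donor_h=np.zeros(n, bool), is_acceptor=np.zeros(n, bool),
        is_sulfur=np.zeros(n, bool), is_backbone=np.zeros(n, bool),
        residue_index=ridx, chain_index=np.zeros(n, int),
        element=np.array(["C"] * n), atom_name=np.array(["CX"] * n),
        res_name=np.array(["ALA"] * n), residue_names=["ALA"] * nres,
        donor_heavy=-np.ones(n, int), acceptor_base=-np.ones(n, int),
    )


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = geo.pairwise_distances(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert np.allclose(ad.value_of(d), [[0, 5], [5, 0]])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-10, 10, size=(50, 3))
        d = ad.value_of(geo.pairwise_distances(x))
        oracle = np.zeros((50, 50))
        for i in range(50):
            for j in range(50):
                oracle[i, j] = np.sqrt(sum((x[i][k] - x[j][k]) ** 2
                                           for k in range(3)))
        assert np.abs(d - oracle).max() < 1e-10

    def test_cutoff_returns_close_pairs_only(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0]])
        i, j, d = geo.pairwise_distances(x, cutoff=2.0)
        assert list(zip(i, j)) == [(0, 1)]
        assert np.allclose(d, 1.0)


class TestDihedral:
    def test_cis_zero_trans_pi(self):
        cis = [np.array(p, float) for p in
               ([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])]
        assert abs(float(geo.dihedral(*cis))) < 1e-12
        trans = [np.array(p, float) for p in
                 ([-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0])]
        assert abs(abs(float(geo.dihedral(*trans))) - np.pi) < 1e-12

    def test_reversal_preserves_and_reflection_flips_sign(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            d = float(geo.dihedral(*p))
            assert np.isclose(float(geo.dihedral(*p[::-1])), d, atol=1e-12)
            m = p * np.array([1.0, 1.0, -1.0])  # mirror
            assert np.isclose(float(geo.dihedral(*m)), -d, atol=1e-12)

    def test_place_atom_roundtrip_against_rotation_oracle(self):
        """place_atom + dihedral agree with an explicit axis-angle rotation."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        a, b, c = rng.normal(size=(3, 3)) * 3
        r, th = 1.5, np.radians(109.5)
        d0 = np.asarray(geo.place_atom(a, b, c, r, th, 0.0))
        for tau in np.radians([60.0, -60.0, 145.0]):
            d_place = np.asarray(geo.place_atom(a, b, c, r, th, tau))
            axis = (a - b) / np.linalg.norm(a - b)
            d_rot = a + Rotation.from_rotvec(axis * tau).apply(d0 - a)
            assert np.abs(d_place - d_rot).max() < 1e-9
            assert np.isclose(float(geo.dihedral(d_place, a, b, c)), tau)

    def test_degenerate_collinear_masked_to_zero(self):
        p = [np.array([0.0, 0, 0]), np.array([1.0, 0, 0]),
             np.array([2.0, 0, 0]), np.array([3.0, 0, 0])]
        assert float(geo.dihedral(*p)) == 0.0


class TestTorsions:
    def test_helix_angles_recovered(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAAAA", preset="helix"))
        t = geo.backbone_torsions(s)
        assert np.abs(t.phi[1:] - np.radians(-57)).max() < 1e-6
        assert np.abs(t.psi[1:-1] - np.radians(-47)).max() < 1e-6
        assert np.abs(np.abs(t.omega[1:]) - np.pi).max() < 1e-6

    def test_termini_masked(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAA"))
        t = geo.backbone_torsions(s)
        assert not t.phi_mask[0] and t.phi_mask[1]
        assert not t.psi_mask[-1] and t.psi_mask[0]
        assert not t.omega_mask[0] and t.omega_mask[1]

    def test_single_residue_all_masked(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="A"))
        t = geo.backbone_torsions(s)
        assert not (t.phi_mask.any() or t.psi_mask.any() or t.omega_mask.any())

    @pytest.mark.parametrize("seq,expected", [("G", 0), ("A", 0), ("K", 4),
                                              ("R", 5), ("V", 1), ("W", 2)])
    def test_chi_slot_counts(self, seq, expected):
        s = fx.build_peptide(fx.FixtureSpec(sequence=f"A{seq}A"))
        t = geo.chi_torsions(s)
        assert t.n_valid_chi(1) == expected


class TestExposure:
    def test_isolated_atom_fully_exposed(self):
        t = _synthetic_table([[0.0, 0, 0]])
        a, r, sc = geo.solvent_exposure(t, ParameterSet())
        assert np.allclose(ad.value_of(a), 1.0)

    def test_enclosed_atom_buried(self):
        """30 neighbors at 3.5 A drive exposure below 0.1 (stated formula)."""
        rng = np.random.default_rng(0)
        pts = [[0.0, 0, 0]]
        for _ in range(30):
            v = rng.normal(size=3)
            pts.append((3.5 * v / np.linalg.norm(v)).tolist())
        t = _synthetic_table(pts)
        a, _, _ = geo.solvent_exposure(t, ParameterSet())
        assert ad.value_of(a)[0] < 0.1

    def test_monotone_in_neighbor_distance(self):
        params = ParameterSet()
        prev = None
        for d in np.linspace(8.0, 3.0, 11):
            t = _synthetic_table([[0.0, 0, 0], [d, 0, 0]])
            a, _, _ = geo.solvent_exposure(t, params)
            e = ad.value_of(a)[0]
            if prev is not None:
                assert e < prev
            prev = e

    def test_own_residue_does_not_bury(self):
        t = _synthetic_table([[0.0, 0, 0], [1.5, 0, 0]], residue_index=[0, 0])
        a, _, _ = geo.solvent_exposure(t, ParameterSet())
        assert np.allclose(ad.value_of(a), 1.0)


class TestPeptideGeometry:
    def test_ideal_bond_values(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAA"))
        obs = geo.peptide_geometry(s)
        assert len(obs) == 3
        for o in obs:
            assert abs(o.dist_n_cp - 1.329) < 1e-6
            assert not o.excluded

    def test_no_observation_across_chains(self):
        s = fx.build_disulfide_bridge()
        obs = geo.peptide_geometry(s)
        nres_a = sum(1 for r in s.residues if r.chain_id == "A")
        for o in obs:
            assert (o.res_index < nres_a) == (o.prev_index < nres_a)

    def test_broken_chain_flagged(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAA"))
        coords = s.coords.copy()
        last = s.residues[-1].atom_indices
        coords[last] += np.array([10.0, 0, 0])
        obs = geo.peptide_geometry(s.with_coords(coords))
        assert obs[-1].excluded and not obs[0].excluded


class TestRebuild:
    def test_roundtrip_identity(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AKLEGVFSTW"))
        t = geo.torsion_set(s)
        keys, coords = geo.rebuild_from_torsions(t)
        rebuilt = ad.value_of(coords)
        # same atom order by construction of the fixture
        assert geo.superimpose_rmsd(s.coords, rebuilt) < 1e-3

    def test_upstream_residues_unaffected_by_phi_change(self):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAAAA"))
        t = geo.torsion_set(s)
        keys, c0 = geo.rebuild_from_torsions(t)
        t.phi[3] += 0.3
        keys, c1 = geo.rebuild_from_torsions(t)
        c0, c1 = ad.value_of(c0), ad.value_of(c1)
        upstream = [k for k, (ri, _) in enumerate(keys) if ri < 3]
        assert np.abs(c0[upstream] - c1[upstream]).max() < 1e-9
        downstream = [k for k, (ri, _) in enumerate(keys) if ri > 3]
        assert np.abs(c0[downstream] - c1[downstream]).max() > 0.1

    def test_omega_rotation_matches_axis_angle_oracle(self):
        from scipy.spatial.transform import Rotation

        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAA"))
        t = geo.torsion_set(s)
        keys, c0 = geo.rebuild_from_torsions(t)
        c0 = ad.value_of(c0)
        row = {kk: r for r, kk in enumerate(keys)}
        delta = np.radians(37.0)
        t.omega[2] = t.omega[2] + delta
        _, c1 = geo.rebuild_from_torsions(t)
        c1 = ad.value_of(c1)
        # rotating omega(2) pivots everything from CA(2) on about C(1)->N(2)
        p_c1, p_n2 = c0[row[(1, "C")]], c0[row[(2, "N")]]
        axis = (p_n2 - p_c1) / np.linalg.norm(p_n2 - p_c1)
        rot = Rotation.from_rotvec(axis * delta)
        moved = [row[(2, "CA")], row[(2, "C")], row[(3, "N")], row[(3, "CA")]]
        expected = p_n2 + rot.apply(c0[moved] - p_n2)
        assert np.abs(c1[moved] - expected).max() < 1e-6

    def test_missing_topology_entry_errors(self):
        t = geo.TorsionSet(
            phi=np.zeros(1), psi=np.zeros(1), omega=np.zeros(1),
            phi_mask=np.zeros(1, bool), psi_mask=np.zeros(1, bool),
            omega_mask=np.zeros(1, bool), chi=np.zeros((1, 5)),
            chi_mask=np.zeros((1, 5), bool), residue_type=["XXX"])
        with pytest.raises(KeyError):
            geo.rebuild_from_torsions(t)


class TestRigidInvariance:
    def test_torsions_and_exposure_invariant(self, helix10):
        rng = np.random.default_rng(11)
        t0 = geo.torsion_set(helix10)
        tab = sio.assign_atom_annotations(helix10)
        a0, r0, s0 = (ad.value_of(v) for v in
                      geo.solvent_exposure(tab, ParameterSet()))
        for _ in range(5):
            R, shift = geo.random_rigid_transform(rng)
            s2 = helix10.with_coords(helix10.coords @ R.T + shift)
            t2 = geo.torsion_set(s2)
            assert np.abs(geo.wrap_angle(t2.phi - t0.phi)).max() < 1e-9
            assert np.abs(geo.wrap_angle(t2.chi - t0.chi)).max() < 1e-9
            tab2 = sio.assign_atom_annotations(s2)
            a2, _, _ = geo.solvent_exposure(tab2, ParameterSet())
            assert np.abs(ad.value_of(a2) - a0).max() < 1e-9


class TestGeometryGradients:
    def test_dihedral_gradient_matches_fd(self):
        rng = np.random.default_rng(13)
        p0 = rng.normal(size=(4, 3))

        def f(x):
            xt = ad.Tensor(x)
            return float(ad.value_of(geo.dihedral(xt[0], xt[1], xt[2], xt[3])))

        xt = ad.Tensor(p0)
        geo.dihedral(xt[0], xt[1], xt[2], xt[3]).backward()
        num = fd_gradient(f, p0)
        assert np.abs(num - xt.grad).max() < 1e-4

    def test_exposure_gradient_matches_fd(self):
        rng = np.random.default_rng(17)
        x0 = rng.uniform(-3, 3, size=(8, 3))
        t = _synthetic_table(x0)
        params = ParameterSet()

        def f(x):
            a, r, _ = geo.solvent_exposure(t, params, coords=ad.Tensor(x))
            return float(ad.value_of(ad.tsum(a)))

        xt = ad.Tensor(x0)
        a, _, _ = geo.solvent_exposure(t, params, coords=xt)
        ad.tsum(a).backward()
        num = fd_gradient(f, x0)
        denom = np.maximum(1.0, np.abs(num) + np.abs(xt.grad))
        assert np.max(np.abs(num - xt.grad) / denom) < 1e-4
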