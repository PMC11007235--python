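"""The eleven energy terms: analytic examples, scalar-loop oracles,
sign/nonnegativity semantics, gating, aggregation and gradients."""

import numpy as np
import pytest

from gradff import autodiff as ad
from gradff import calibration as cal
from gradff import energies as en
from gradff import fixtures as fx
from gradff import geometry as geo
from gradff import structure_io as sio
from gradff.params import ParameterSet

from conftest import fd_gradient


def _table(coords, *, q=None, elements=None, residue_index=None,
           res_names=None, atom_names=None, donor_h=None, donor_heavy=None,
           acceptor=None, acceptor_base=None, radius=1.7):
    n = len(coords)
    ridx = np.arange(n) if residue_index is None else np.asarray(residue_index)
    nres = int(ridx.max()) + 1
    el = np.array(["C"] * n) if elements is None else np.asarray(elements)
    rn = np.array(["ALA"] * n) if res_names is None else np.asarray(res_names)
    return sio.AtomTable(
        coords=np.asarray(coords, float),
        q=np.zeros(n) if q is None else np.asarray(q, float),
        radius=np.full(n, radius) if np.isscalar(radius) else np.asarray(radius),
        is_donor_h=np.zeros(n, bool) if donor_h is None else np.asarray(donor_h),
        is_acceptor=np.zeros(n, bool) if acceptor is None else np.asarray(acceptor),
        is_sulfur=el == "S",
        is_backbone=np.zeros(n, bool),
        residue_index=ridx, chain_index=np.zeros(n, int),
        element=el,
        atom_name=np.array(["X"] * n) if atom_names is None else np.asarray(atom_names),
        res_name=rn,
        residue_names=[rn[np.where(ridx == r)[0][0]] for r in range(nres)],
        donor_heavy=-np.ones(n, int) if donor_heavy is None else np.asarray(donor_heavy),
        acceptor_base=-np.ones(n, int) if acceptor_base is None else np.asarray(acceptor_base),
    )


class TestElectrostatics:
    def test_scalar_coulomb_example(self):
        """+1/-1 at 5 A, eps=80, I=0: E = 332*(-1)/(80*5) = -0.83 kcal/mol."""
        t = _table([[0.0, 0, 0], [5.0, 0, 0]], q=[1.0, -1.0])
        p = ParameterSet(ionic_strength=0.0)
        per_res, (i, j, e) = en.electrostatics(t, p)
        assert np.isclose(float(ad.value_of(e)[0]), 332.0 * -1 / (80 * 5))
        assert np.isclose(float(np.sum(ad.value_of(per_res))),
                          332.0 * -1 / (80 * 5))

    def test_zero_charge_contributes_nothing(self, helix10, calib):
        p0 = ParameterSet()
        p0.tables = dict(p0.tables)
        p0.tables["charges"] = {}
        t = sio.assign_atom_annotations(helix10, p0)
        per_res, _ = en.electrostatics(t, p0)
        assert np.all(ad.value_of(per_res) == 0.0)

    def test_screening_strictly_reduces_magnitude(self):
        t = _table([[0.0, 0, 0], [5.0, 0, 0]], q=[1.0, -1.0])
        e0 = float(np.sum(ad.value_of(
            en.electrostatics(t, ParameterSet(ionic_strength=0.0))[0])))
        e1 = float(np.sum(ad.value_of(
            en.electrostatics(t, ParameterSet(ionic_strength=0.15))[0])))
        e2 = float(np.sum(ad.value_of(
            en.electrostatics(t, ParameterSet(ionic_strength=0.5))[0])))
        assert abs(e1) < abs(e0)
        assert abs(e2) < abs(e1)

    def test_sign_follows_charge_product(self):
        for qa, qb in [(1, 1), (-1, -1), (1, -1)]:
            t = _table([[0.0, 0, 0], [4.0, 0, 0]], q=[qa, qb])
            e = float(np.sum(ad.value_of(
                en.electrostatics(t, ParameterSet(ionic_strength=0.0))[0])))
            assert np.sign(e) == np.sign(qa * qb)

    def test_matches_scalar_double_loop_oracle(self, helix10, calib):
        """Tensorized energies equal an independent per-pair scalar loop."""
        p = calib.params
        t = sio.assign_atom_annotations(helix10, p)
        per_res, (i, j, e) = en.electrostatics(t, p)
        kappa = float(ad.value_of(cal.debye_huckel_kappa(
            p.ionic_strength, p.temperature, p.dielectric)))
        ev = ad.value_of(e)
        for k in range(len(i)):
            d = float(np.linalg.norm(t.coords[i[k]] - t.coords[j[k]]))
            expected = (332.0 * t.q[i[k]] * t.q[j[k]] / (p.dielectric * d)
                        * np.exp(-d * kappa))
            # inside the switching region the smooth cutoff multiplies in
            if d <= p.elec_cutoff - 1.0:
                assert abs(ev[k] - expected) < 1e-10


class TestHydrogenBonds:
    def _hbond_table(self, theta_dha=np.pi, d_ha=1.9):
        """Donor N-H and acceptor O=C with exact geometry."""
        h = np.zeros(3)
        n = h + 1.01 * np.array([-np.sin(np.pi - theta_dha),
                                 np.cos(np.pi - theta_dha), 0.0]) \
            if theta_dha != np.pi else np.array([-1.01, 0.0, 0.0])
        o = np.array([d_ha, 0.0, 0.0])
        ang = np.radians(115.0)
        c = o + 1.23 * np.array([-np.cos(ang), np.sin(ang), 0.0])
        return _table(
            [n, h, o, c], elements=["N", "H", "O", "C"],
            residue_index=[0, 0, 1, 1],
            donor_h=[False, True, False, False],
            donor_heavy=[-1, 0, -1, -1],
            acceptor=[False, False, True, False],
            acceptor_base=[-1, -1, 3, -1])

    def test_no_polar_hydrogens_zero(self):
        t = _table([[0.0, 0, 0], [3.0, 0, 0]])
        per_res, _ = en.hydrogen_bonds(t, ParameterSet())
        assert np.all(ad.value_of(per_res) == 0.0)

    def test_ideal_linear_bond_reaches_well_minimum(self):
        t = self._hbond_table()
        per_res, _ = en.hydrogen_bonds(t, ParameterSet())
        assert np.isclose(float(np.sum(ad.value_of(per_res))), -1.0, atol=1e-9)

    def test_bent_bond_heavily_penalized(self):
        """At theta_DHA = 90 deg the cosine-power factor caps |E| below w/4."""
        n = np.array([0.0, 1.01, 0.0])  # D-H perpendicular to H...A
        h = np.zeros(3)
        o = np.array([1.9, 0.0, 0.0])
        ang = np.radians(115.0)
        c = o + 1.23 * np.array([-np.cos(ang), np.sin(ang), 0.0])
        t = _table([n, h, o, c], elements=["N", "H", "O", "C"],
                   residue_index=[0, 0, 1, 1],
                   donor_h=[False, True, False, False],
                   donor_heavy=[-1, 0, -1, -1],
                   acceptor=[False, False, True, False],
                   acceptor_base=[-1, -1, 3, -1])
        per_res, _ = en.hydrogen_bonds(t, ParameterSet())
        assert 0 < -float(np.sum(ad.value_of(per_res))) < 0.25

    def test_energy_nonpositive_on_fixture(self, helix10, calib):
        t = sio.assign_atom_annotations(helix10, calib.params)
        per_res, _ = en.hydrogen_bonds(t, calib.params)
        assert np.all(ad.value_of(per_res) <= 1e-12)
        assert float(np.sum(ad.value_of(per_res))) < -0.5  # helix has H-bonds


class TestDisulfide:
    def test_no_cysteines_zero(self, helix10):
        t = sio.assign_atom_annotations(helix10)
        per_res, _ = en.disulfide(t, ParameterSet())
        assert np.all(ad.value_of(per_res) == 0.0)

    def test_ideal_bridge_reaches_minimum(self, calib):
        s = fx.build_disulfide_bridge()
        t = sio.assign_atom_annotations(s)
        per_res, _ = en.disulfide(t, ParameterSet())
        assert np.isclose(float(np.sum(ad.value_of(per_res))), -1.0, atol=1e-6)

    def test_stretched_bridge_above_minimum(self):
        s = fx.build_disulfide_bridge()
        cys = [r for r in s.residues if r.name == "CYS"]
        sg0, sg1 = (r.atom_ids["SG"] for r in cys)
        coords = s.coords.copy()
        u = coords[sg1] - coords[sg0]
        # move chain B so the S-S distance becomes 2.4 A
        shift = (2.4 / np.linalg.norm(u) - 1.0) * u
        b_atoms = [i for r in s.residues if r.chain_id == "B"
                   for i in r.atom_indices]
        coords[b_atoms] += shift
        t = sio.assign_atom_annotations(s.with_coords(coords))
        per_res, _ = en.disulfide(t, ParameterSet())
        e = float(np.sum(ad.value_of(per_res)))
        assert -1.0 < e < 0.0


class TestSolvationAndVdw:
    def test_zero_exposure_zero_solvation(self, helix10):
        t = sio.assign_atom_annotations(helix10)
        pol, hyd = en.solvation(t, np.zeros(t.n_residues), ParameterSet())
        assert np.all(ad.value_of(pol) == 0.0)
        assert np.all(ad.value_of(hyd) == 0.0)

    def test_linear_scaling_with_exposure(self, helix10):
        t = sio.assign_atom_annotations(helix10)
        expo = np.zeros(t.n_residues)
        expo[1] = 0.1
        pol1, hyd1 = en.solvation(t, expo, ParameterSet())
        pol9, hyd9 = en.solvation(t, expo * 9.0, ParameterSet())
        assert np.allclose(ad.value_of(pol9), 9.0 * ad.value_of(pol1))
        assert np.allclose(ad.value_of(hyd9), 9.0 * ad.value_of(hyd1))

    def test_vdw_saturation_limits(self, helix10):
        t = sio.assign_atom_annotations(helix10)
        p = ParameterSet()
        zero = ad.value_of(en.vdw(t, np.ones(t.n_atoms), p))
        assert np.allclose(zero, 0.0)
        full = ad.value_of(en.vdw(t, np.zeros(t.n_atoms), p))
        expected = [p.coefficient(rn, "vdw") for rn in t.residue_names]
        assert np.allclose(full, expected)

    def test_vdw_matches_per_atom_loop_oracle(self, helix10, calib):
        t = sio.assign_atom_annotations(helix10)
        p = calib.params
        atom_exp, _, _ = geo.solvent_exposure(t, p)
        got = ad.value_of(en.vdw(t, atom_exp, p))
        expo = ad.value_of(atom_exp)
        for r in range(t.n_residues):
            heavy = np.where((t.residue_index == r) & (t.element != "H"))[0]
            acc = 0.0
            for a in heavy:
                acc += 1.0 - expo[a]
            expected = p.coefficient(t.residue_names[r], "vdw") * acc / len(heavy)
            assert abs(got[r] - expected) < 1e-10


class TestClash:
    def test_at_threshold_energy_equals_weight(self, calib):
        tg = calib.clash.t["other"]
        s = fx.build_clash_pair(0.0, radius_sum=3.4, t_g=tg)
        t = sio.assign_atom_annotations(s)
        per_res, _ = en.clash(t, calib.clash, calib.params)
        assert np.isclose(float(np.sum(ad.value_of(per_res))), 1.0, atol=1e-6)

    def test_penetration_ratio_is_e(self, calib):
        tg = calib.clash.t["other"]
        e0 = float(np.sum(ad.value_of(en.clash(
            sio.assign_atom_annotations(fx.build_clash_pair(0.0, 3.4, tg)),
            calib.clash, calib.params)[0])))
        e1 = float(np.sum(ad.value_of(en.clash(
            sio.assign_atom_annotations(fx.build_clash_pair(-0.1, 3.4, tg)),
            calib.clash, calib.params)[0])))
        assert np.isclose(e1 / e0, np.e, rtol=1e-6)

    def test_gated_to_zero_outside_threshold(self, calib):
        s = fx.build_clash_pair(1.0, radius_sum=3.4, t_g=calib.clash.t["other"])
        t = sio.assign_atom_annotations(s)
        per_res, _ = en.clash(t, calib.clash, calib.params)
        assert np.all(ad.value_of(per_res) == 0.0)

    def test_nonnegative_everywhere(self, noisy_helix, calib):
        t = sio.assign_atom_annotations(noisy_helix)
        per_res, _ = en.clash(t, calib.clash, calib.params)
        assert np.all(ad.value_of(per_res) >= 0.0)

    def test_matches_scalar_loop_oracle(self, noisy_helix, calib):
        p = calib.params
        t = sio.assign_atom_annotations(noisy_helix, p)
        per_res, (i, j, e) = en.clash(t, calib.clash, p)
        ev = ad.value_of(e)
        lut = {g: calib.clash.t[g] for g in calib.clash.t}
        from gradff.params import CLASH_GROUPS
        ii, jj, gg = cal.collect_clash_pairs(t, p)
        assert np.array_equal(i, ii) and np.array_equal(j, jj)
        for k in range(len(i)):
            d = float(np.linalg.norm(t.coords[i[k]] - t.coords[j[k]]))
            tg = lut[CLASH_GROUPS[gg[k]]]
            gap = t.radius[i[k]] + t.radius[j[k]] + tg - d
            expected = np.exp(10.0 * gap) if gap >= 0 else 0.0
            assert abs(ev[k] - expected) <= 1e-10 * max(1.0, abs(expected))


class TestEntropyTerms:
    def test_backbone_entropy_masks_chain_start(self, helix10, calib):
        tset = geo.torsion_set(helix10)
        e = ad.value_of(en.backbone_entropy(
            tset, calib.densities, calib.params, helix10.coords))
        # first residue: phi masked and omega masked -> no contribution at all
        assert e[0] == 0.0
        assert np.all(np.isfinite(e))

    def test_trans_omega_is_near_density_mode(self, helix10, calib):
        om = calib.densities.omega
        at_pi = float(np.asarray(ad.value_of(om.log_density(np.array([np.pi]))))[0])
        off = float(np.asarray(ad.value_of(om.log_density(np.array([2.0]))))[0])
        assert at_pi > off + 5.0

    def test_kernel_centered_density_lower_nll_at_center(self, calib):
        p = ParameterSet(min_density_samples=1, kde_bandwidth=0.2)
        center = np.array([[np.radians(-57.0), np.radians(-47.0)]])
        kde = cal.fit_torsion_density(center, p)
        at = float(np.asarray(ad.value_of(kde.log_density(center)))[0])
        away = float(np.asarray(ad.value_of(kde.log_density(
            center + np.radians(90.0))))[0])
        assert -at < -away

    def test_sidechain_entropy_zero_for_gly_ala(self, calib):
        s = sio.add_polar_hydrogens(
            fx.build_peptide(fx.FixtureSpec(sequence="GAGA")))
        bd = en.total_energy(s, calib, track_gradient=False)
        assert np.allclose(bd.terms["entropy_sidechain"], 0.0, atol=1e-9)

    def test_exposed_lysine_pays_almost_nothing(self, calib):
        s = sio.add_polar_hydrogens(fx.build_peptide(fx.FixtureSpec("K")))
        bd = en.total_energy(s, calib, track_gradient=False)
        S = calib.params.coefficient("LYS", "entropy")
        assert bd.terms["entropy_sidechain"][0] < 0.1 * S

    def test_salt_bridge_gates_full_entropy_cost(self, calib):
        """A lysine whose NZ forms a salt bridge pays ~ the full constant."""
        lys = sio.add_polar_hydrogens(fx.build_peptide(fx.FixtureSpec("K")))
        glu = fx.build_peptide(fx.FixtureSpec("E"), chain_id="B")
        rk = lys.residues[0]
        nz = lys.coords[rk.atom_ids["NZ"]]
        ce = lys.coords[rk.atom_ids["CE"]]
        u = (nz - ce) / np.linalg.norm(nz - ce)
        re_ = glu.residues[0]
        oe1 = glu.coords[re_.atom_ids["OE1"]]
        shift = (nz + 2.6 * u) - oe1
        glu = glu.with_coords(glu.coords + shift)
        merged = sio.StructureModel(
            lys.array + glu.array,
            coords64=np.concatenate([lys.coords, glu.coords]))
        p0 = ParameterSet(ionic_strength=0.0)
        calib0 = cal.Calibration(params=p0, clash=calib.clash,
                                 densities=calib.densities)
        bd = en.total_energy(merged, calib0, track_gradient=False)
        S = p0.coefficient("LYS", "entropy")
        # strong electrostatic pair fires the gate
        assert bd.term_totals()["electrostatics"] < -1.0
        assert bd.terms["entropy_sidechain"][0] > 0.8 * S


class TestViolationTerms:
    def test_peptide_gaussian_zero_at_mean_half_at_sigma(self):
        g = cal.PeptideGaussian(mean=1.33, sigma=0.01)
        assert g.neg_log_excess(1.33) == 0.0
        assert np.isclose(float(g.neg_log_excess(1.34)), 0.5)

    def test_ideal_fixture_near_zero_violation(self, helix10, calib):
        bd = en.total_energy(helix10, calib, track_gradient=False)
        per_bond = bd.term_totals()["peptide_violation"] / 9.0
        assert per_bond < 0.05

    def test_chain_break_contributes_zero(self, calib):
        s = fx.build_peptide(fx.FixtureSpec(sequence="AAAA"))
        coords = s.coords.copy()
        coords[s.residues[-1].atom_indices] += np.array([10.0, 0, 0])
        bd = en.total_energy(s.with_coords(coords), calib, track_gradient=False)
        assert bd.terms["peptide_violation"][-1] == 0.0

    def test_violations_nonnegative_on_random_fixtures(self, calib):
        for seed in (1, 2, 3):
            s = sio.add_polar_hydrogens(fx.build_peptide(
                fx.FixtureSpec("AKLEGVFSTW", noise_sigma=0.25, seed=seed)))
            bd = en.total_energy(s, calib, track_gradient=False)
            for term in ("clash", "peptide_violation", "sidechain_violation"):
                assert np.all(bd.terms[term] >= 0.0), term

    def test_sidechain_violation_periodicity(self, calib):
        kde = calib.densities.chi["SER"]
        q = np.array([[1.0]])
        a = float(np.asarray(ad.value_of(kde.log_density(q)))[0])
        b = float(np.asarray(ad.value_of(kde.log_density(q + 2 * np.pi)))[0])
        assert abs(a - b) < 1e-9

    def test_gly_ala_zero_sidechain_violation(self, calib):
        s = fx.build_peptide(fx.FixtureSpec(sequence="GAGA"))
        bd = en.total_energy(s, calib, track_gradient=False)
        assert np.allclose(bd.terms["sidechain_violation"], 0.0)


class TestTotalEnergy:
    def test_empty_structure_zero(self, calib):
        import biotite.structure as struc

        empty = sio.StructureModel(struc.AtomArray(0))
        bd = en.total_energy(empty, calib)
        assert bd.total == 0.0

    def test_total_equals_sum_of_terms(self, helix10, calib):
        bd = en.total_energy(helix10, calib, track_gradient=False)
        assert np.isclose(bd.total, sum(bd.term_totals().values()),
                          rtol=1e-6)

    def test_distant_copies_are_additive(self, helix10, calib):
        bd1 = en.total_energy(helix10, calib, track_gradient=False)
        far = helix10.with_coords(helix10.coords + np.array([100.0, 0, 0]))
        arr = far.array.copy()
        arr.chain_id = np.full(arr.array_length(), "B")
        dimer = sio.StructureModel(
            helix10.array + arr,
            coords64=np.concatenate([helix10.coords, far.coords]))
        bd2 = en.total_energy(dimer, calib, track_gradient=False)
        assert np.isclose(bd2.total, 2.0 * bd1.total, rtol=1e-9, atol=1e-9)

    def test_rigid_motion_invariance(self, helix10, calib):
        bd0 = en.total_energy(helix10, calib, track_gradient=False)
        rng = np.random.default_rng(23)
        for _ in range(3):
            R, shift = geo.random_rigid_transform(rng)
            s2 = helix10.with_coords(helix10.coords @ R.T + shift)
            bd2 = en.total_energy(s2, calib, track_gradient=False)
            for k in bd0.terms:
                assert abs(bd2.term_totals()[k] - bd0.term_totals()[k]) < 1e-6

    def test_gradient_matches_finite_differences_spot(self, noisy_helix, calib):
        model = en.EnergyModel(noisy_helix, calib)
        x0 = noisy_helix.coords.copy()
        gr = model.evaluate(x0).gradient()
        rng = np.random.default_rng(7)
        h = 1e-4
        for a, b in zip(rng.integers(0, len(x0), 10), rng.integers(0, 3, 10)):
            xp = x0.copy()
            xp[a, b] += h
            xm = x0.copy()
            xm[a, b] -= h
            fd = (model.evaluate(xp, track_gradient=False).total
                  - model.evaluate(xm, track_gradient=False).total) / (2 * h)
            assert abs(fd - gr[a, b]) / max(1.0, abs(fd), abs(gr[a, b])) < 1e-4

    def test_missing_density_raises_setup_error(self, helix10, calib):
        dens = cal.DensityModel(backbone={}, omega=calib.densities.omega,
                                chi=calib.densities.chi,
                                peptide=calib.densities.peptide)
        broken = cal.Calibration(params=calib.params, clash=calib.clash,
                                 densities=dens)
        with pytest.raises(en.SetupError):
            en.EnergyModel(helix10, broken)
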