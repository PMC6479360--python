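"""Pose scoring, per-residue energies and NIP interface prediction."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ppiatlas import docking_nip as dn
from ppiatlas import structure_model as sm
from ppiatlas import synthetic_data as sd

IDENTITY = dn.Pose(np.eye(3), np.zeros(3), 0.0)


def single_atom_chain(chain_id, xyz, charge=0.0, number=1):
    return sm.ChainStructure(chain_id=chain_id, residues=[
        sm.Residue(number, "A", [sm.Atom("C", np.asarray(xyz, float), 1.9,
                                         charge=charge, name="CA")])])


class TestPoseInterface:
    def test_distant_ligand_empty(self, toy_complex):
        far = dn.Pose(np.eye(3), np.array([500.0, 0, 0]), 0.0)
        assert dn.pose_interface(toy_complex.receptor, toy_complex.ligand, far) == \
            frozenset()

    @pytest.mark.parametrize("dist,inside", [(4.9, True), (5.1, False)])
    def test_cutoff_contract(self, dist, inside):
        rec = single_atom_chain("A", [0, 0, 0])
        lig = single_atom_chain("B", [dist, 0, 0])
        iface = dn.pose_interface(rec, lig, IDENTITY)
        assert (1 in iface) is inside

    def test_matches_all_pairs_distance_oracle(self, toy_complex):
        pose = dn.Pose(np.eye(3), np.array([2.0, 1.0, -1.0]), 0.0)
        iface = dn.pose_interface(toy_complex.receptor, toy_complex.ligand, pose)
        r = toy_complex.receptor
        l_coords = np.vstack([a.coord for res in toy_complex.ligand.residues
                              for a in res.atoms])
        lt = pose.transform(l_coords)
        expected = set()
        for res in r.residues:
            for a in res.atoms:
                if (np.linalg.norm(lt - a.coord, axis=1) < 5.0).any():
                    expected.add(res.author_number)
        assert iface == frozenset(expected)

    def test_rotation_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            dn.Pose(np.eye(3) * 2.0, np.zeros(3), 0.0)


class TestScorePose:
    def test_separated_pose_scores_zero(self):
        rec = single_atom_chain("A", [0, 0, 0], charge=1.0)
        lig = single_atom_chain("B", [100.0, 0, 0], charge=-1.0)
        assert dn.score_pose(rec, lig, IDENTITY) == pytest.approx(0.0, abs=1e-9)

    def test_electrostatic_closed_form_small_charges(self):
        q = 0.1
        rec = single_atom_chain("A", [0, 0, 0], charge=q)
        lig = single_atom_chain("B", [4.0, 0, 0], charge=-q)
        params = dn.EnergyModelParams()
        got = dn.score_pose(rec, lig, IDENTITY, params, include_desolvation=False)
        elec = dn.COULOMB_CONSTANT * (-q * q) / (4.0 * 4.0 * 4.0)
        s6 = (3.8 / 4.0) ** 6
        vdw = params.vdw_weight * min(params.vdw_cap,
                                      params.vdw_eps * (s6 * s6 - 2 * s6))
        assert got == pytest.approx(elec + vdw, rel=1e-9)

    def test_electrostatics_truncated_at_one_au_per_pair(self):
        rec = single_atom_chain("A", [0, 0, 0], charge=1.0)
        lig = single_atom_chain("B", [4.0, 0, 0], charge=-1.0)
        params = dn.EnergyModelParams()
        got = dn.score_pose(rec, lig, IDENTITY, params, include_desolvation=False)
        # raw Coulomb would be -5.19 a.u.; the pair term is capped at -1
        s6 = (3.8 / 4.0) ** 6
        vdw = params.vdw_weight * min(params.vdw_cap,
                                      params.vdw_eps * (s6 * s6 - 2 * s6))
        assert got == pytest.approx(-1.0 + vdw, rel=1e-9)

    def test_clashing_pose_is_finite(self, toy_complex):
        clash = dn.Pose(np.eye(3), np.array([-30.0, 0.0, 0.0]), 0.0)
        e = dn.score_pose(toy_complex.receptor, toy_complex.ligand, clash,
                          include_desolvation=False)
        assert np.isfinite(e)

    def test_bound_orientation_beats_random_decoys(self, toy_complex):
        """The planted-charge interface makes the as-built pose the most
        favorable; random decoys must essentially never score better."""
        params = dn.EnergyModelParams()
        e_true = dn.score_pose(toy_complex.receptor, toy_complex.ligand,
                               IDENTITY, params)
        poses = sd.make_pose_ensemble(toy_complex, n_near=100, n_decoy=100, seed=5)
        decoys = poses[100:140]
        wins = sum(e_true < dn.score_pose(toy_complex.receptor, toy_complex.ligand,
                                          d, params)
                   for d in decoys)
        assert wins >= int(0.95 * len(decoys))


class TestResidueBindingEnergy:
    def test_separated_pose_all_zero(self):
        rec = single_atom_chain("A", [0, 0, 0], charge=1.0)
        lig = single_atom_chain("B", [100.0, 0, 0], charge=-1.0)
        energies = dn.residue_binding_energy(rec, lig, IDENTITY)
        assert all(abs(e) < 1e-9 for e in energies.values())

    def test_single_contact_pair_carries_full_energy(self):
        rec = sm.ChainStructure("A", [
            sm.Residue(1, "A", [sm.Atom("C", [0.0, 0, 0], 1.9, charge=0.2)]),
            sm.Residue(2, "A", [sm.Atom("C", [0.0, 0, 50.0], 1.9)])])
        lig = single_atom_chain("B", [4.0, 0, 0], charge=-0.2)
        energies = dn.residue_binding_energy(rec, lig, IDENTITY,
                                             include_desolvation=False)
        total = dn.score_pose(rec, lig, IDENTITY, include_desolvation=False)
        assert energies[1] == pytest.approx(total, rel=1e-9)
        assert energies[2] == pytest.approx(0.0, abs=1e-12)

    def test_additivity_on_toy_complex(self, toy_complex):
        params = dn.EnergyModelParams()
        per_res = dn.residue_binding_energy(toy_complex.receptor,
                                            toy_complex.ligand, IDENTITY, params)
        total = dn.score_pose(toy_complex.receptor, toy_complex.ligand,
                              IDENTITY, params)
        assert abs(sum(per_res.values()) - total) < 1e-6


class TestFlagLowEnergy:
    def test_strictly_below_threshold(self):
        flagged = dn.flag_low_energy({1: -2.5, 2: -2.0, 3: 0.5})
        assert flagged == frozenset({1})

    def test_all_positive_empty(self):
        assert dn.flag_low_energy({1: 0.1, 2: 3.0}) == frozenset()

    def test_planted_hot_spots_flagged(self, toy_complex):
        """The three opposite-charge contact residues dominate the binding
        energy and are the flagged set."""
        per_res = dn.residue_binding_energy(toy_complex.receptor,
                                            toy_complex.ligand, IDENTITY)
        hot = {i + 1 for i, r in enumerate(toy_complex.receptor.residues)
               if r.atoms[0].charge > 0}
        flagged = dn.flag_low_energy(per_res, threshold=-0.9)
        assert hot <= flagged
        assert flagged <= toy_complex.true_interface_receptor


def _toy_poses(interfaces, scores):
    return [dn.Pose(np.eye(3), np.zeros(3), s, pose_id=i,
                    interface_residues=frozenset(f))
            for i, (f, s) in enumerate(zip(interfaces, scores))]


class TestComputeNip:
    def test_always_present_residue_gets_nip_one(self):
        surface = set(range(1, 11))
        poses = _toy_poses([[1, k % 9 + 2] for k in range(100)], [-1.0] * 100)
        prof = dn.compute_nip(poses, 100, surface)
        assert prof.nip[1] == pytest.approx(1.0)

    def test_random_level_residue_gets_nip_zero(self):
        surface = set(range(1, 5))
        # every residue appears in exactly half the poses: f_i = f_rand
        poses = _toy_poses([[1, 2] if k % 2 else [3, 4] for k in range(100)],
                           [-1.0] * 100)
        prof = dn.compute_nip(poses, 100, surface)
        assert all(abs(v) < 1e-12 for v in prof.nip.values())

    def test_affine_formula(self):
        # residue 1 in 55 of 100 poses; overall coverage tuned to f_rand = 0.1
        surface = set(range(1, 21))
        interfaces = []
        for k in range(100):
            iface = [1] if k < 55 else []
            # pad coverage so total = 200 residue-slots -> f_rand = 0.1
            iface += [2 + (k % 19)] if len(iface) else [2 + (k % 19), 2 + ((k + 7) % 19)]
            interfaces.append(iface)
        total = sum(len(i) for i in interfaces)
        poses = _toy_poses(interfaces, [-1.0] * 100)
        prof = dn.compute_nip(poses, 100, surface)
        f_rand = total / (100 * 20)
        assert prof.f_rand == pytest.approx(f_rand)
        assert prof.nip[1] == pytest.approx((0.55 - f_rand) / (1 - f_rand))

    def test_mean_f_equals_f_rand(self, toy_complex, toy_surface):
        poses = sd.make_pose_ensemble(toy_complex, seed=3)
        dn.annotate_interfaces(poses, toy_complex.receptor, toy_complex.ligand)
        prof = dn.compute_nip(poses, 100, toy_surface)
        assert np.mean(list(prof.f_i.values())) == pytest.approx(prof.f_rand)

    def test_requires_enough_poses_and_interfaces(self):
        poses = _toy_poses([[1]] * 10, [-1.0] * 10)
        with pytest.raises(ValueError):
            dn.compute_nip(poses, 100, {1, 2})
        bare = [dn.Pose(np.eye(3), np.zeros(3), -1.0, pose_id=0)] * 100
        with pytest.raises(ValueError):
            dn.compute_nip(bare, 100, {1, 2})

    def test_degenerate_full_coverage_rejected(self):
        poses = _toy_poses([[1, 2]] * 100, [-1.0] * 100)
        with pytest.raises(ValueError):
            dn.compute_nip(poses, 100, {1, 2})


class TestPredictedCoreRim:
    def _profile(self, nips):
        return dn.NIPProfile(f_i={}, nip=nips, f_rand=0.05, n_top=100)

    def test_cutoff_inclusive(self):
        core = dn.predicted_core(self._profile({1: 0.1, 2: 0.099, 3: 0.5}))
        assert core == frozenset({1, 3})

    def test_all_below_cutoff_warns_empty(self):
        with pytest.warns(UserWarning, match="no confident interface"):
            core = dn.predicted_core(self._profile({1: 0.01}))
        assert core == frozenset()

    def test_core_monotone_in_cutoff(self, toy_complex, toy_surface):
        poses = sd.make_pose_ensemble(toy_complex, seed=4)
        dn.annotate_interfaces(poses, toy_complex.receptor, toy_complex.ligand)
        prof = dn.compute_nip(poses, 100, toy_surface)
        assert dn.predicted_core(prof, 1.0) <= dn.predicted_core(prof, 0.1)

    def test_empty_core_gives_empty_rim(self, toy_complex, toy_surface):
        assert dn.predicted_rim(frozenset(), toy_complex.receptor,
                                toy_surface) == frozenset()

    @pytest.mark.parametrize("dist,inside", [(9.5, True), (10.5, False)])
    def test_rim_distance_contract(self, dist, inside):
        rec = sm.ChainStructure("A", [
            sm.Residue(1, "A", [sm.Atom("C", [0.0, 0, 0], 1.9)]),
            sm.Residue(2, "A", [sm.Atom("C", [dist, 0, 0], 1.9)])])
        rim = dn.predicted_rim(frozenset({1}), rec, {1, 2})
        assert (2 in rim) is inside

    def test_rim_matches_distance_oracle(self, toy_complex, toy_surface):
        core = frozenset(list(sorted(toy_complex.true_interface_receptor))[:5])
        rim = dn.predicted_rim(core, toy_complex.receptor, toy_surface)
        coords = {r.author_number: r.atoms[0].coord
                  for r in toy_complex.receptor.residues}
        core_xyz = np.vstack([coords[c] for c in core])
        expected = {p for p in toy_surface - core
                    if (np.linalg.norm(core_xyz - coords[p], axis=1) < 10.0).any()}
        assert rim == frozenset(expected)


class TestLowEnergyEnrichment:
    def test_proportional_expectation(self):
        labels = {**{i: "rim" for i in range(916)},
                  **{i: "core" for i in range(916, 2062)}}
        flagged = frozenset(list(range(201)) + list(range(916, 916 + 470)))
        rows = {r["region"]: r for r in dn.low_energy_enrichment(labels, flagged)}
        assert rows["rim"]["expected"] == pytest.approx(298.08, abs=0.005)
        assert rows["core"]["o_over_e"] == pytest.approx(470 / 372.92, rel=1e-4)

    def test_zero_flagged_reported_absent(self):
        rows = dn.low_energy_enrichment({1: "rim", 2: "core"}, frozenset())
        assert all(r["expected"] is None for r in rows)

    def test_uniform_flagging_gives_unit_o_over_e(self, rng):
        labels = {i: ("rim" if i < 800 else "core") for i in range(2000)}
        flagged = frozenset(rng.choice(2000, size=600, replace=False).tolist())
        rows = {r["region"]: r for r in dn.low_energy_enrichment(labels, flagged)}
        assert rows["rim"]["o_over_e"] == pytest.approx(1.0, abs=0.1)
        assert rows["core"]["o_over_e"] == pytest.approx(1.0, abs=0.1)

    def test_unlabelled_flagged_residue_rejected(self):
        with pytest.raises(ValueError):
            dn.low_energy_enrichment({1: "rim"}, frozenset({2}))


class TestPoseEnsembleIO:
    def test_round_trip_byte_identical(self, toy_complex):
        poses = sd.make_pose_ensemble(toy_complex, n_near=100, n_decoy=100, seed=9)
        text = dn.write_pose_ensemble(poses)
        back = dn.read_pose_ensemble(text)
        assert dn.write_pose_ensemble(back) == text
        np.testing.assert_allclose(back[7].rotation, poses[7].rotation, atol=1e-7)
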