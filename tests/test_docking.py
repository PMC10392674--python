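"""Pose generation, two-stage selection, matched-core initialization and
substituent annealing."""
import numpy as np
import pytest

from gpcrforge.docking import (LigandPose, SiteRegion, anneal_substituents,
                               generate_poses, matched_core_init,
                               refine_pose, rotate_torsion, stage1_select,
                               stage2_dealanize_rescore, load_ligand,
                               save_ligand)
from gpcrforge.fixtures import make_ligand
from gpcrforge.forcefield import LigandScorer
from gpcrforge.geometry import rmsd, rotation_about_axis
from gpcrforge.repack import alanize


@pytest.fixture(scope="module")
def ring_ligand():
    ligand, _ = make_ligand(2, seed=7)
    return ligand


class TestGeneratePoses:
    def test_count_and_centroids_inside_site(self, ring_ligand):
        site = SiteRegion(centre=np.array([5.0, -2.0, 1.0]), radius=4.0)
        poses = generate_poses(ring_ligand, site, 500, seed=3)
        assert len(poses) == 500
        for pose in poses:
            assert np.linalg.norm(pose.centroid() - site.centre) <= 4.0 + 1e-9

    def test_bit_identical_from_same_seed(self, ring_ligand):
        site = SiteRegion(centre=np.zeros(3), radius=3.0)
        a = generate_poses(ring_ligand, site, 50, seed=11)
        b = generate_poses(ring_ligand, site, 50, seed=11)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.coords, pb.coords)

    def test_rotation_uniformity(self, ring_ligand):
        """Quaternion sampling: E[(q_i . q_j)^2] = 1/4 for uniform
        rotations; the empirical mean over many pairs must agree."""
        rng = np.random.default_rng(0)
        from gpcrforge.geometry import random_unit_quaternion
        q = np.array([random_unit_quaternion(rng) for _ in range(10_000)])
        dots = (q[:5000] * q[5000:]).sum(axis=1)
        mean_sq = np.mean(dots ** 2)
        # Var[(q.q')^2] = 1/4 - 1/16 under uniformity; 3 sigma of the mean
        sigma = np.sqrt((0.25 - 0.0625) / 5000)
        assert abs(mean_sq - 0.25) < 3 * sigma

    def test_needs_at_least_one_pose(self, ring_ligand):
        site = SiteRegion(centre=np.zeros(3), radius=3.0)
        with pytest.raises(ValueError):
            generate_poses(ring_ligand, site, 0, seed=1)


class TestStage1:
    def test_keeps_exactly_100_of_1000(self, ff, planted_complex):
        receptor, ligand, planted, truth = planted_complex
        alanized = alanize(receptor, [tuple(k) for k
                                      in truth["pocket_residues"]])
        site = SiteRegion(np.array(truth["site_centre"]),
                          truth["site_radius"])
        poses = generate_poses(ligand, site, 1000, seed=5)
        kept = stage1_select(poses, alanized, ff, keep=100)
        assert len(kept) == 100
        assert all(p.stage == "stage1" for p in kept)

    def test_keep_larger_than_pose_count(self, ff, planted_complex):
        receptor, ligand, planted, truth = planted_complex
        alanized = alanize(receptor, [tuple(k) for k
                                      in truth["pocket_residues"]])
        site = SiteRegion(np.array(truth["site_centre"]),
                          truth["site_radius"])
        poses = generate_poses(ligand, site, 20, seed=5)
        kept = stage1_select(poses, alanized, ff, keep=100,
                             clash_ceiling=np.inf)
        assert len(kept) == 20

    def test_returns_the_exact_minimum_energies(self, ff, planted_complex):
        receptor, ligand, planted, truth = planted_complex
        alanized = alanize(receptor, [tuple(k) for k
                                      in truth["pocket_residues"]])
        site = SiteRegion(np.array(truth["site_centre"]),
                          truth["site_radius"])
        poses = generate_poses(ligand, site, 300, seed=6)
        kept = stage1_select(poses, alanized, ff, keep=30,
                             clash_ceiling=np.inf)
        scorer = LigandScorer(alanized, ff)
        all_scores = sorted(scorer.score(ligand, q.coords).total
                            for q in poses)
        got = [q.score.total for q in kept]
        assert np.allclose(got, all_scores[:30], atol=1e-9)


class TestStage2:
    def test_no_alanizable_site_preserves_ranking(self, ff):
        """Without truncated residues stage 2 only rescopes the same
        receptor, so the ordering matches stage 1."""
        from gpcrforge.core import Structure, build_ideal_helix
        helix = build_ideal_helix("ADSAA")
        receptor = Structure(residues=helix.residues)
        ligand, _ = make_ligand(1, seed=2)
        site = SiteRegion(centre=np.array([6.0, 0.0, 3.0]), radius=3.0)
        poses = generate_poses(ligand, site, 60, seed=9)
        kept = stage1_select(poses, receptor, ff, keep=10,
                             clash_ceiling=np.inf)
        final, _ = stage2_dealanize_rescore(kept, receptor, ff,
                                            refine_top=0)
        assert np.allclose([q.score.total for q in final],
                           sorted(q.score.total for q in kept), atol=1e-9)

    def test_pose_order_permutation_invariance(self, ff, planted_complex):
        receptor, ligand, planted, truth = planted_complex
        alanized = alanize(receptor, [tuple(k) for k
                                      in truth["pocket_residues"]])
        site = SiteRegion(np.array(truth["site_centre"]),
                          truth["site_radius"])
        poses = generate_poses(ligand, site, 200, seed=4)
        kept = stage1_select(poses, alanized, ff, keep=8)
        final_a, _ = stage2_dealanize_rescore(kept, alanized, ff,
                                              refine_top=0)
        final_b, _ = stage2_dealanize_rescore(kept[::-1], alanized, ff,
                                              refine_top=0)
        ea = sorted(q.score.total for q in final_a)
        eb = sorted(q.score.total for q in final_b)
        assert np.allclose(ea, eb, atol=1e-9)

    def test_output_subset_of_input(self, ff, planted_complex):
        receptor, ligand, planted, truth = planted_complex
        alanized = alanize(receptor, [tuple(k) for k
                                      in truth["pocket_residues"]])
        site = SiteRegion(np.array(truth["site_centre"]),
                          truth["site_radius"])
        poses = generate_poses(ligand, site, 300, seed=8)
        kept = stage1_select(poses, alanized, ff, keep=12)
        input_ids = {id(q) for q in poses}
        assert all(any(np.array_equal(k.coords, q.coords) for q in poses)
                   for k in kept)
        assert len(kept) <= 12


class TestMatchedCore:
    def test_self_superposition_zero_rmsd(self, ring_ligand):
        pose = LigandPose(ring_ligand, ring_ligand.coords())
        new, core_rmsd = matched_core_init(
            pose, ring_ligand, [(i, i) for i in range(6)])
        assert core_rmsd < 1e-6

    def test_recovers_known_rigid_transform(self, ring_ligand):
        R = rotation_about_axis([1.0, -2.0, 0.7], 111.0)
        t = np.array([4.0, 5.0, -6.0])
        moved = LigandPose(ring_ligand, ring_ligand.coords() @ R.T + t)
        new, core_rmsd = matched_core_init(
            moved, ring_ligand, [(i, i) for i in range(6)])
        assert core_rmsd < 1e-6
        assert np.abs(new.coords - moved.coords).max() < 1e-6

    def test_matches_independent_superposition_oracle(self, ring_ligand,
                                                      rng):
        """Noisy correspondence: our Kabsch RMSD equals scipy's
        quaternion-based superposition on the same atoms."""
        from scipy.spatial.transform import Rotation
        R = rotation_about_axis([0.3, 0.4, 0.5], 77.0)
        target = ring_ligand.coords()[:6] @ R.T + rng.normal(
            scale=0.1, size=(6, 3)) + np.array([1.0, 2.0, 3.0])
        ref_pose = LigandPose(ring_ligand, np.vstack(
            [target, ring_ligand.coords()[6:]]))
        _, core_rmsd = matched_core_init(ref_pose, ring_ligand,
                                         [(i, i) for i in range(6)])
        mobile = ring_ligand.coords()[:6]
        est, oracle_ssd = Rotation.align_vectors(
            target - target.mean(axis=0), mobile - mobile.mean(axis=0))
        fitted = est.apply(mobile - mobile.mean(axis=0))
        oracle = np.sqrt(np.mean(np.sum(
            (fitted - (target - target.mean(axis=0))) ** 2, axis=1)))
        assert core_rmsd == pytest.approx(oracle, abs=1e-6)

    def test_too_few_or_collinear_atoms_rejected(self, ring_ligand):
        pose = LigandPose(ring_ligand, ring_ligand.coords())
        with pytest.raises(ValueError):
            matched_core_init(pose, ring_ligand, [(0, 0), (1, 1)])
        coords = ring_ligand.coords().copy()
        coords[:3] = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        straight = LigandPose(ring_ligand, coords)
        with pytest.raises(ValueError, match="collinear"):
            matched_core_init(straight, ring_ligand,
                              [(0, 0), (1, 1), (2, 2)])


class TestAnneal:
    def _receptor(self):
        from gpcrforge.core import Structure, build_ideal_helix
        import copy
        helix = build_ideal_helix("AADAA")
        st = Structure(residues=[copy.deepcopy(r) for r in helix.residues])
        for r in st.residues:
            for a in r.atoms:
                a.coord = a.coord + np.array([5.0, 0.0, 0.0])
        return st

    def test_rigid_ligand_returned_unchanged(self, ff):
        ligand, _ = make_ligand(0, seed=0)
        pose = LigandPose(ligand, ligand.coords())
        out = anneal_substituents(pose, self._receptor(), ff, seed=1)
        assert np.array_equal(out.coords, pose.coords)

    def test_best_so_far_never_worse_than_input(self, ff):
        ligand, _ = make_ligand(2, seed=3)
        pose = LigandPose(ligand, ligand.coords())
        receptor = self._receptor()
        start = LigandScorer(receptor, ff).score(ligand, pose.coords).total
        out = anneal_substituents(pose, receptor, ff, cycles=3,
                                  steps_per_cycle=40, seed=2)
        assert out.score.total <= start + 1e-9

    def test_single_torsion_finds_scan_minimum(self, ff):
        # brute-force 1-degree torsion scan as the oracle
        ligand, _ = make_ligand(1, seed=0)
        receptor = self._receptor()
        scorer = LigandScorer(receptor, ff)
        base = ligand.coords()
        tors = ligand.rotatable_torsions[0]
        energies = [scorer.score(ligand, rotate_torsion(
            base, ligand, tors, float(ang))).total for ang in range(360)]
        best_ang = int(np.argmin(energies))
        pose = LigandPose(ligand, base)
        out = anneal_substituents(pose, receptor, ff, cycles=10,
                                  steps_per_cycle=60, seed=4)
        from gpcrforge.geometry import dihedral
        delta = (dihedral(*(out.coords[i] for i in tors))
                 - dihedral(*(base[i] for i in tors))) % 360
        miss = min(abs(delta - best_ang), 360 - abs(delta - best_ang))
        assert miss <= 15.0


class TestLigandIO:
    def test_yaml_roundtrip(self, tmp_path, ring_ligand):
        path = tmp_path / "ligand.yaml"
        save_ligand(ring_ligand, path)
        back = load_ligand(path)
        assert len(back.atoms) == len(ring_ligand.atoms)
        assert np.allclose(back.coords(), ring_ligand.coords())
        assert back.rotatable_torsions == ring_ligand.rotatable_torsions

    def test_disconnected_ligand_rejected(self):
        from gpcrforge.core import Atom
        from gpcrforge.docking import Ligand
        atoms = [Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [10, 0, 0])]
        with pytest.raises(ValueError, match="connected"):
            Ligand(atoms=atoms, bonds=[])
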