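"""Pose sampling, geometric scoring, clustering and rigid refinement."""

import numpy as np
import pytest

import degradock as dd
from degradock import config
from degradock.conformers import Conformer
from degradock.docking import (Pose, ReceptorContext, grid_points,
                               score_pose)
from degradock.geometry import (quaternion_to_matrix, rmsd_no_superposition,
                                rotvec_to_matrix)
from degradock.structure import SiteDefinition, structure_coords

from conftest import make_structure_from_atoms


def single_atom_conformer(name="pt"):
    return Conformer(elements=["C"], coords=np.zeros((1, 3)), name=name)


def random_conformer(rng, n):
    return Conformer(elements=list(rng.choice(["C", "N", "O"], n)),
                     coords=rng.uniform(-2, 2, (n, 3)))


@pytest.fixture(scope="module")
def small_receptor():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-8, 8, (50, 3))
    elements = rng.choice(["C", "N", "O", "S"], 50).tolist()
    return make_structure_from_atoms(coords, elements)


def site_at(center, radius):
    return SiteDefinition(residues=[], centroid=np.asarray(center, dtype=float),
                          radius=radius)


class TestSampling:
    def test_grid_within_radius_two_has_33_points(self):
        pts = grid_points(2.0)
        assert len(pts) == 33
        assert all(np.dot(p, p) <= 4.0 + 1e-12 for p in pts)

    def test_single_orientation_one_pose_per_grid_point(self, small_receptor):
        site = site_at([0, 0, 0], 2.0)
        poses = dd.sample_poses(small_receptor, site, [single_atom_conformer()],
                                n_orientations=1, seed=4)
        assert len(poses) == 33

    def test_centroids_stay_inside_site_sphere(self, small_receptor):
        site = site_at([1, 2, 3], 3.0)
        rng = np.random.default_rng(1)
        poses = dd.sample_poses(small_receptor, site, [random_conformer(rng, 6)],
                                n_orientations=3, seed=2)
        for p in poses:
            assert np.linalg.norm(p.coords.mean(axis=0) - site.centroid) <= \
                site.radius + 1e-9

    def test_same_seed_identical_pose_list(self, small_receptor):
        site = site_at([0, 0, 0], 2.0)
        rng = np.random.default_rng(5)
        conf = random_conformer(rng, 5)
        a = dd.sample_poses(small_receptor, site, [conf], n_orientations=4, seed=9)
        b = dd.sample_poses(small_receptor, site, [conf], n_orientations=4, seed=9)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.coords, pb.coords)

    def test_pose_coords_recomputable_from_transform(self, small_receptor):
        site = site_at([0, 0, 0], 2.0)
        rng = np.random.default_rng(6)
        poses = dd.sample_poses(small_receptor, site, [random_conformer(rng, 7)],
                                n_orientations=2, seed=3)
        for p in poses[:10]:
            assert np.allclose(p.coords, p.recompute_coords(), atol=1e-12)


class TestScoring:
    def test_single_contact(self):
        st = make_structure_from_atoms([[0.0, 0.0, 0.0]], ["C"])
        pose = Pose(conformer=single_atom_conformer(), quaternion=np.array([1, 0, 0, 0]),
                    translation=np.array([3.5, 0, 0]), coords=np.array([[3.5, 0.0, 0.0]]))
        score_pose(st, pose)
        assert (pose.contacts, pose.clashes, pose.score) == (1, 0, 1.0)

    def test_overlap_scores_as_clash(self):
        st = make_structure_from_atoms([[0.0, 0.0, 0.0]], ["C"])
        pose = Pose(conformer=single_atom_conformer(), quaternion=np.array([1, 0, 0, 0]),
                    translation=np.array([1.0, 0, 0]), coords=np.array([[1.0, 0.0, 0.0]]))
        score_pose(st, pose)
        assert pose.clashes >= 1
        assert pose.score <= -5.0 + pose.contacts

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            st = make_structure_from_atoms(rng.uniform(-6, 6, (50, 3)),
                                           rng.choice(["C", "N", "O"], 50).tolist())
            rec_coords, _ = structure_coords(st)  # PDB-roundtripped coordinates
            lig = rng.uniform(-6, 6, (15, 3))
            pose = Pose(conformer=Conformer(elements=["C"] * 15, coords=lig),
                        quaternion=np.array([1, 0, 0, 0]),
                        translation=lig.mean(axis=0), coords=lig)
            score_pose(st, pose)
            d = np.linalg.norm(lig[:, None] - rec_coords[None], axis=-1)
            contacts = int(((d >= 3.0) & (d <= 4.5)).sum())
            clashes = int((d < 3.0).sum())
            assert pose.contacts == contacts
            assert pose.clashes == clashes
            assert pose.score == 1.0 * contacts - 5.0 * clashes

    def test_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(3)
        rec = rng.uniform(-5, 5, (30, 3))
        lig = rng.uniform(-5, 5, (8, 3))
        st = make_structure_from_atoms(rec, ["C"] * 30)
        pose = Pose(conformer=Conformer(elements=["C"] * 8, coords=lig),
                    quaternion=np.array([1, 0, 0, 0]), translation=lig.mean(axis=0),
                    coords=lig)
        score_pose(st, pose)
        R = rotvec_to_matrix(np.array([1.0, -0.4, 0.2]))
        shift = np.array([7.0, 1.0, -4.0])
        st2 = make_structure_from_atoms(rec @ R.T + shift, ["C"] * 30)
        pose2 = Pose(conformer=pose.conformer, quaternion=pose.quaternion,
                     translation=pose.translation,
                     coords=lig @ R.T + shift)
        score_pose(st2, pose2)
        assert (pose2.contacts, pose2.clashes, pose2.score) == \
            (pose.contacts, pose.clashes, pose.score)


class TestClustering:
    def _pose(self, coords, score):
        coords = np.asarray(coords, dtype=float)
        return Pose(conformer=Conformer(elements=["C"] * len(coords), coords=coords),
                    quaternion=np.array([1, 0, 0, 0]),
                    translation=coords.mean(axis=0), coords=coords,
                    contacts=int(max(score, 0)), clashes=0, score=float(score))

    def test_identical_poses_one_cluster(self):
        coords = np.random.default_rng(1).uniform(-2, 2, (5, 3))
        result = dd.cluster_poses([self._pose(coords, 3)] * 5)
        assert len(result.poses) == 1
        assert result.cluster_sizes == [5]

    def test_distant_poses_two_clusters(self):
        a = np.zeros((4, 3))
        result = dd.cluster_poses([self._pose(a, 5), self._pose(a + 10.0, 4)])
        assert len(result.poses) == 2
        assert result.poses[0].score >= result.poses[1].score

    def test_three_jittered_seed_groups_give_three_clusters(self):
        rng = np.random.default_rng(21)
        seeds = [rng.uniform(-2, 2, (6, 3)) + offset
                 for offset in (np.zeros(3), np.array([12.0, 0, 0]),
                                np.array([0, 12.0, 0]))]
        poses = []
        for k, base in enumerate(seeds):
            for i in range(17 if k == 0 else 16):  # 49 jittered + ...
                poses.append(self._pose(base + rng.normal(0, 0.3, base.shape),
                                        score=rng.integers(0, 20)))
        result = dd.cluster_poses(poses, rmsd_threshold=4.0)
        assert len(result.poses) == 3
        assert sum(result.cluster_sizes) == len(poses)

    def test_representatives_pairwise_beyond_threshold(self):
        rng = np.random.default_rng(30)
        poses = [self._pose(rng.uniform(-8, 8, (5, 3)), rng.integers(0, 10))
                 for _ in range(40)]
        result = dd.cluster_poses(poses, rmsd_threshold=4.0)
        reps = result.poses
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                assert rmsd_no_superposition(reps[i].coords, reps[j].coords) > 4.0


class TestRefinement:
    def test_refined_score_never_decreases(self, compact_receptor):
        rec, lig, planted = compact_receptor
        ctx = ReceptorContext.build(rec.structure, rec.docking_site())
        refined = dd.refine_pose(ctx, planted)
        assert refined.score >= planted.score

    def test_clash_relief_increases_min_separation(self):
        rng = np.random.default_rng(4)
        rec_coords = rng.uniform(-6, 6, (40, 3))
        st = make_structure_from_atoms(rec_coords, ["C"] * 40)
        # drop a single-atom ligand 2.5 A from one receptor atom
        lig = rec_coords[0] + np.array([2.5, 0, 0])
        pose = Pose(conformer=single_atom_conformer(),
                    quaternion=np.array([1, 0, 0, 0]), translation=lig,
                    coords=lig[None, :])
        score_pose(st, pose)
        before = np.linalg.norm(rec_coords - lig, axis=1).min()
        refined = dd.refine_pose(st, pose, max_steps=80)
        rec_all, _ = structure_coords(st)
        after = np.linalg.norm(rec_all - refined.coords[0], axis=1).min()
        assert after >= before

    def test_centroid_stays_near_site(self, compact_receptor):
        rec, lig, planted = compact_receptor
        site = rec.docking_site()
        ctx = ReceptorContext.build(rec.structure, site)
        refined = dd.refine_pose(ctx, planted)
        assert np.linalg.norm(refined.coords.mean(axis=0) - site.centroid) <= \
            site.radius + 2.0 + 1e-6


class TestExport:
    def test_receptor_ligand_multimodel_pdb(self, compact_receptor, tmp_path):
        rec, lig, planted = compact_receptor
        out = tmp_path / "poses.pdb"
        dd.docking.poses_to_pdb(rec.structure, [planted, planted], out)
        text = out.read_text()
        assert text.count("MODEL") == 2
        assert "LIG L" in text
        # ligand coordinates survive the 3-decimal round trip
        lig_lines = [l for l in text.splitlines() if " LIG L" in l][:lig.n_atoms]
        coords = np.array([[float(l[30:38]), float(l[38:46]), float(l[46:54])]
                           for l in lig_lines])
        assert np.allclose(coords, planted.coords, atol=1e-3)


class TestRecovery:
    def test_planted_pose_recovered_across_seeds(self, compact_receptor):
        """Enrichment: redocking a compact molded binder recovers the planted
        placement within 2 A in at least 8 of 10 seeds."""
        rec, lig, planted = compact_receptor
        ctx = ReceptorContext.build(rec.structure, rec.docking_site())
        hits = 0
        for seed in range(10):
            result = dd.dock_ligand(ctx, [lig], n_orientations=8, seed=seed)
            if rmsd_no_superposition(result.best_pose.coords, planted.coords) <= 2.0:
                hits += 1
        assert hits >= 8
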