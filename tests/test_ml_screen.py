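"""Interaction featurization, training-pair construction and the forest."""

import numpy as np
import pytest

import degradock as dd
from degradock.conformers import Conformer
from degradock.docking import Pose, score_pose
from degradock.features import (DISTANCE_BINS, FEATURE_NAMES, LIGAND_CLASSES,
                                N_FEATURES, PROTEIN_CLASSES, featurize_pose)
from degradock.fixtures import child_seed
from degradock.forest import SchemaError, TrainedForest, train_forest
from degradock.structure import structure_coords

from conftest import make_structure_from_atoms


def scored_pose(structure, coords, elements):
    coords = np.asarray(coords, dtype=float)
    pose = Pose(conformer=Conformer(elements=list(elements), coords=coords),
                quaternion=np.array([1, 0, 0, 0]),
                translation=coords.mean(axis=0), coords=coords)
    return score_pose(structure, pose)


class TestFeaturize:
    def test_far_ligand_all_contact_features_zero(self):
        st = make_structure_from_atoms(np.zeros((3, 3)) + [[0, 0, 0], [2, 0, 0], [0, 2, 0]],
                                       ["C", "N", "O"])
        pose = scored_pose(st, np.full((4, 3), 50.0), ["C"] * 4)
        vec = featurize_pose(st, pose)
        assert np.all(vec[:62] == 0)       # bins, hbonds, hydrophobic
        assert vec[62] == 0                # buried fraction
        assert vec[64] == 4                # heavy atoms

    def test_single_pair_lands_in_exactly_one_bin(self):
        st = make_structure_from_atoms([[0.0, 0.0, 0.0]], ["O"])
        pose = scored_pose(st, [[3.0, 0.0, 0.0]], ["C"])
        vec = featurize_pose(st, pose)
        target = FEATURE_NAMES.index("cnt_OC_2.5_3.5")
        contact_bins = vec[:60]
        assert contact_bins[target] == 1
        assert contact_bins.sum() == 1

    def test_matches_brute_force_bin_counts(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            st = make_structure_from_atoms(
                rng.uniform(-5, 5, (30, 3)),
                rng.choice(["C", "N", "O", "S", "P"], 30).tolist())
            rec_coords, rec_elements = structure_coords(st)
            lig_elements = rng.choice(["C", "N", "O", "F"], 10).tolist()
            lig = rng.uniform(-5, 5, (10, 3))
            vec = featurize_pose(st, scored_pose(st, lig, lig_elements))
            # brute-force oracle
            expected = np.zeros(60)
            hb = hydro = 0
            buried = set()
            for i, (lc, le) in enumerate(zip(lig, lig_elements)):
                for rc, re in zip(rec_coords, rec_elements):
                    dist = float(np.linalg.norm(lc - rc))
                    for b, (lo, hi) in enumerate(DISTANCE_BINS):
                        if lo <= dist < hi:
                            p = PROTEIN_CLASSES.index(re) if re in PROTEIN_CLASSES else 4
                            l = LIGAND_CLASSES.index(le) if le in LIGAND_CLASSES else 3
                            expected[(p * 4 + l) * 3 + b] += 1
                    if dist <= 3.5 and re in "NO" and le in "NO":
                        hb += 1
                    if dist <= 4.5 and re == "C" and le == "C":
                        hydro += 1
                    if dist <= 4.5:
                        buried.add(i)
            assert np.array_equal(vec[:60], expected)
            assert vec[60] == hb and vec[61] == hydro
            assert vec[62] == pytest.approx(len(buried) / 10)

    def test_feature_vector_length_and_names(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 65
        assert len(set(FEATURE_NAMES)) == N_FEATURES


@pytest.fixture(scope="module")
def complexes():
    out = []
    for r, radius in enumerate([7.0, 8.0, 9.0, 10.0]):
        rec = dd.make_toy_receptor(radius, seed=100 + r)
        lig = dd.make_cognate_ligand(radius, seed=200 + 10 * r)
        planted = dd.plant_cognate_ligand(rec, lig, seed=300 + 10 * r)
        out.append(dd.CognateComplex(receptor=rec, ligand=lig, planted=planted))
    return out


class TestTrainingSet:
    def test_counts_and_balance(self, complexes):
        X, y = dd.build_training_set(complexes, seed=1)
        assert X.shape == (8, N_FEATURES)
        assert sorted(y.tolist()) == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_same_seed_identical(self, complexes):
        X1, y1 = dd.build_training_set(complexes, seed=5)
        X2, y2 = dd.build_training_set(complexes, seed=5)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)

    def test_derangement_has_no_fixed_points(self):
        from degradock.fixtures import derange_receptors
        rng = np.random.default_rng(9)
        for n_rec in (2, 3, 5):
            cognate = list(range(n_rec)) * 3
            assignment = derange_receptors(len(cognate), cognate, rng, n_rec)
            assert all(a != c for a, c in zip(assignment, cognate))

    def test_single_receptor_raises(self, complexes):
        with pytest.raises(Exception):
            dd.build_training_set(complexes[:1], seed=0)


def _separable_set(n_per_class=20, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, noise, (n_per_class, 6))
    X1 = rng.normal(2.0, noise, (n_per_class, 6))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestForest:
    def test_default_tree_count_is_500(self):
        from degradock import config
        assert config.N_TREES == 500
        X, y = _separable_set(5)
        f = train_forest(X, y, seed=1)
        assert f.n_trees == 500 and len(f.trees) == 500

    def test_separable_set_learned_perfectly(self):
        X, y = _separable_set()
        f = train_forest(X, y, n_trees=50, seed=3)
        scores = f.classify_many(X)
        assert np.all((scores >= 0.5) == (y == 1))
        assert f.classify(X[y == 1][0]) >= 0.9
        assert f.classify(X[y == 0][0]) <= 0.1

    def test_scores_bounded(self):
        X, y = _separable_set(8, noise=2.0, seed=4)
        f = train_forest(X, y, n_trees=25, seed=4)
        s = f.classify_many(np.random.default_rng(0).normal(1, 3, (30, 6)))
        assert np.all((s >= 0) & (s <= 1))

    def test_single_class_raises(self):
        X = np.random.default_rng(1).normal(0, 1, (10, 4))
        with pytest.raises(ValueError):
            train_forest(X, np.ones(10, dtype=int), n_trees=5, seed=0)

    def test_votes_match_sklearn_tree_oracle_small_forests(self):
        """On <=5-tree forests our traversal votes equal per-tree sklearn
        predictions, and the score equals the hand-tallied vote fraction."""
        X, y = _separable_set(10, noise=1.0, seed=7)
        f = train_forest(X, y, n_trees=5, seed=7)
        skl = f._sklearn_model
        probe = np.random.default_rng(2).normal(1, 1.5, (40, 6))
        for x in probe:
            ours = f.tree_votes(x)
            theirs = [int(est.predict(x[None, :])[0]) for est in skl.estimators_]
            assert ours == theirs
            assert f.classify(x) == pytest.approx(sum(ours) / 5)

    def test_json_roundtrip_identical_predictions(self, tmp_path):
        X, y = _separable_set(12, noise=0.8, seed=11)
        f = train_forest(X, y, n_trees=20, seed=11)
        path = tmp_path / "model.json"
        f.save(path)
        g = TrainedForest.load(path)
        probe = np.random.default_rng(3).normal(1, 2, (50, 6))
        assert np.array_equal(f.classify_many(probe), g.classify_many(probe))
        assert g.feature_names == f.feature_names
        assert g.oob_accuracy == f.oob_accuracy

    def test_schema_mismatch_raises(self):
        X, y = _separable_set(6)
        f = train_forest(X, y, n_trees=5, seed=1)
        with pytest.raises(SchemaError):
            f.classify(np.zeros(7))
        with pytest.raises(SchemaError):
            f.classify(np.zeros(6), feature_names=("a",) * 6)

    def test_oob_accuracy_stable_under_sample_permutation(self):
        X, y = _separable_set(25, noise=1.2, seed=13)
        f1 = train_forest(X, y, n_trees=100, seed=13)
        perm = np.random.default_rng(5).permutation(len(y))
        f2 = train_forest(X[perm], y[perm], n_trees=100, seed=13)
        assert abs(f1.oob_accuracy - f2.oob_accuracy) <= 0.05
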