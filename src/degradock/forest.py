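"""Random-forest binder classifier.

Training delegates to scikit-learn (bagged CART trees, Gini impurity,
sqrt(F) candidate features per split, grown to purity), after which every
tree is exported to plain arrays.  Prediction is the package's own traversal:
the binder score of a feature vector is the fraction of trees whose leaf
majority class is "binder", exactly as a hand tally over per-tree votes.
The exported representation serializes to versioned JSON and round-trips to
identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import config

MODEL_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """Raised when feature names at prediction time differ from training."""


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # (n_nodes, n_classes) class counts at each node

    def vote(self, x: np.ndarray) -> int:
        node = 0
        while self.children_left[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        counts = self.value[node]
        return int(np.argmax(counts))


@dataclass
class TrainedForest:
    """Exported forest: trees, feature schema, seed and OOB accuracy."""

    trees: list[_Tree]
    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    oob_accuracy: float | None = None
    classes: tuple[int, ...] = (0, 1)
    _sklearn_model: RandomForestClassifier | None = field(default=None, repr=False)

    def classify(self, vector: np.ndarray,
                 feature_names: tuple[str, ...] | None = None) -> float:
        """Fraction of trees voting the positive class, in [0, 1]."""
        if feature_names is not None and tuple(feature_names) != tuple(self.feature_names):
            raise SchemaError("feature names do not match the trained schema")
        x = np.asarray(vector, dtype=float)
        if x.shape[-1] != len(self.feature_names):
            raise SchemaError(
                f"expected {len(self.feature_names)} features, got {x.shape[-1]}")
        votes = sum(t.vote(x) for t in self.trees)
        return votes / len(self.trees)

    def classify_many(self, matrix: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
        return np.array([self.classify(row) for row in X])

    def tree_votes(self, vector: np.ndarray) -> list[int]:
        """Per-tree hard votes (for oracle tallies and inspection)."""
        x = np.asarray(vector, dtype=float)
        return [t.vote(x) for t in self.trees]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "model": "random_forest_binder",
            "n_trees": self.n_trees,
            "seed": self.seed,
            "oob_accuracy": self.oob_accuracy,
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TrainedForest":
        payload = json.loads(text)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')}")
        trees = [
            _Tree(
                children_left=np.asarray(t["children_left"], dtype=int),
                children_right=np.asarray(t["children_right"], dtype=int),
                feature=np.asarray(t["feature"], dtype=int),
                threshold=np.asarray(t["threshold"], dtype=float),
                value=np.asarray(t["value"], dtype=float),
            )
            for t in payload["trees"]
        ]
        return cls(trees=trees,
                   feature_names=tuple(payload["feature_names"]),
                   n_trees=payload["n_trees"],
                   seed=payload["seed"],
                   oob_accuracy=payload["oob_accuracy"],
                   classes=tuple(payload["classes"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedForest":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _export_tree(est) -> _Tree:
    t = est.tree_
    return _Tree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        value=t.value[:, 0, :].copy(),
    )


def train_forest(features: np.ndarray, labels, n_trees: int = config.N_TREES,
                 seed: int = 0,
                 feature_names: tuple[str, ...] | None = None) -> TrainedForest:
    """Train the binder classifier (bagging, Gini, sqrt-features, full depth)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training requires both classes")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    if feature_names is None:
        from .features import FEATURE_NAMES
        feature_names = FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES) else \
            tuple(f"f{i}" for i in range(X.shape[1]))
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        min_samples_leaf=1,
        bootstrap=True,
        oob_score=True,
        random_state=int(seed) % (2 ** 31 - 1),
        n_jobs=1,
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample OOB coverage warnings
        clf.fit(X, y)
    oob = float(clf.oob_score_) if hasattr(clf, "oob_score_") else None
    forest = TrainedForest(
        trees=[_export_tree(est) for est in clf.estimators_],
        feature_names=tuple(feature_names),
        n_trees=n_trees,
        seed=seed,
        oob_accuracy=oob,
    )
    forest._sklearn_model = clf
    return forest
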