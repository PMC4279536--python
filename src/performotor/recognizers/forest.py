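"""Bootstrap random forest for freezing-of-gait detection.

Ten trees by default, each grown to maximum size without pruning on a
bootstrap resample, with sqrt(p) random feature subsetting per split; the
reported confidence is the fraction of trees voting for each class. The
per-tree bootstrap indices are recorded on the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from ..features import FeatureMatrix


@dataclass
class ForestModel:
    trees: List[DecisionTreeClassifier]
    bootstrap_indices: List[np.ndarray]
    classes: np.ndarray
    seed: int
    feature_names: Optional[List[str]] = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_proba(self, X: Union[np.ndarray, FeatureMatrix]) -> np.ndarray:
        """Vote fractions: (n, k) rows summing to 1."""
        if isinstance(X, FeatureMatrix):
            X = X.X
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes)))
        for tree in self.trees:
            pred = tree.predict(X)
            for i, c in enumerate(self.classes):
                votes[:, i] += pred == c
        return votes / self.n_trees

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]


def train_forest(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Optional[np.ndarray] = None,
    n_trees: int = 10,
    seed: int = 0,
) -> ForestModel:
    names = None
    if isinstance(X, FeatureMatrix):
        names = X.names
        if labels is None:
            labels = X.labels
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF09]))
    n = X.shape[0]
    trees: List[DecisionTreeClassifier] = []
    boots: List[np.ndarray] = []
    for k in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
    return ForestModel(
        trees=trees,
        bootstrap_indices=boots,
        classes=classes,
        seed=int(seed),
        feature_names=names,
    )
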