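"""SVM bradykinesia classifier and the feature-combination search.

RBF kernel, C = 1, gamma = 1/p on standardized features; multi-class via
one-vs-rest decision shape with pairwise-coupled sigmoid calibration for
the confidence output (sklearn's ``probability=True``). The feature
combination search scores every non-empty subset of operator families by
cross-validated accuracy and reports the best, mirroring how the selected
subset (approximate entropy, cross-correlation, range) was identified.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ..features import FeatureMatrix


@dataclass
class MarginModel:
    pipeline: Pipeline
    classes: np.ndarray
    seed: int
    kernel: str = "rbf"
    C: float = 1.0
    feature_names: Optional[List[str]] = None

    def predict_proba(self, X: Union[np.ndarray, FeatureMatrix]) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.X
        return self.pipeline.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]

    def decision_function(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.X
        return self.pipeline.decision_function(np.asarray(X, dtype=float))


def _make_pipeline(kernel: str, C: float, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel=kernel,
                    C=C,
                    gamma="auto",  # 1/p on standardized features
                    probability=True,
                    decision_function_shape="ovr",
                    random_state=seed,
                ),
            ),
        ]
    )


def train_svm(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Optional[np.ndarray] = None,
    kernel: str = "rbf",
    C: float = 1.0,
    seed: int = 0,
) -> MarginModel:
    names = None
    if isinstance(X, FeatureMatrix):
        names = X.names
        if labels is None:
            labels = X.labels
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    pipe = _make_pipeline(kernel, C, int(seed))
    pipe.fit(X, y)
    return MarginModel(
        pipeline=pipe,
        classes=pipe.named_steps["svc"].classes_,
        seed=int(seed),
        kernel=kernel,
        C=C,
        feature_names=names,
    )


def feature_combination_search(
    X: np.ndarray,
    labels: np.ndarray,
    groups: Dict[str, Sequence[int]],
    cv: int = 3,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
) -> Tuple[Tuple[str, ...], Dict[Tuple[str, ...], float]]:
    """Exhaustively score every non-empty combination of feature groups.

    ``groups`` maps a family name (e.g. 'apen', 'range', 'crosscorr') to the
    column indices it owns. Returns (best combination, score table). Ties
    break toward fewer groups, then lexicographic order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    names = sorted(groups)
    table: Dict[Tuple[str, ...], float] = {}
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=int(seed))
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            idx = np.concatenate([np.asarray(groups[g], dtype=int) for g in combo])
            pipe = _make_pipeline(kernel, C, int(seed))
            scores = cross_val_score(pipe, X[:, idx], y, cv=skf, scoring="accuracy")
            table[combo] = float(np.mean(scores))
    best = max(table, key=lambda c: (table[c], -len(c), tuple(reversed(c))))
    return best, table
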