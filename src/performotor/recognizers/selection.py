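"""Wrapper feature selection via best-first search.

Subsets are scored by internal cross-validated accuracy of the supplied
learner. The search starts from the empty set, keeps an open list of
evaluated subsets ordered by score, and repeatedly expands the best
unexpanded subset by adding one unused feature; it stops after ``stall``
consecutive expansions without improving the incumbent, or after
``max_evals`` subset evaluations. Deterministic given the seed.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB

from ..features import FeatureMatrix


def wrapper_select(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Optional[np.ndarray] = None,
    learner: Optional[Callable[[], object]] = None,
    max_evals: int = 40,
    stall: int = 5,
    cv: int = 3,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> List[str]:
    """Best-first wrapper selection; returns the selected feature names.

    ``max_evals`` bounds the number of node *expansions* (each expansion
    scores every one-feature extension of the chosen subset); with
    ``max_evals=1`` only the empty set is expanded, i.e. the best single
    feature is returned. ``learner`` is a zero-argument factory for a fresh
    sklearn-style estimator (default GaussianNB, a fast wrapper learner).
    """
    if isinstance(X, FeatureMatrix):
        if feature_names is None:
            feature_names = X.names
        if labels is None:
            labels = X.labels
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("wrapper selection needs at least two classes")
    p = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if learner is None:
        learner = GaussianNB
    n_splits = min(cv, int(np.min(np.bincount(np.searchsorted(np.unique(y), y)))))
    n_splits = max(2, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))

    def score(subset: frozenset) -> float:
        if not subset:
            # majority-class baseline
            counts = np.bincount(np.searchsorted(np.unique(y), y))
            return counts.max() / counts.sum()
        idx = sorted(subset)
        return float(
            np.mean(cross_val_score(learner(), X[:, idx], y, cv=skf, scoring="accuracy"))
        )

    scores = {frozenset(): score(frozenset())}
    expanded: set = set()
    best_subset = frozenset()
    best_score = scores[best_subset]
    expansions = 0
    stalled = 0
    while expansions < max_evals and stalled < stall:
        frontier = [s for s in scores if s not in expanded]
        if not frontier:
            break
        # best unexpanded node; ties -> smaller subset, then lexicographic
        node = max(
            frontier, key=lambda s: (scores[s], -len(s), tuple(-j for j in sorted(s)))
        )
        expanded.add(node)
        expansions += 1
        improved = False
        for j in range(p):
            if j in node:
                continue
            child = node | {j}
            if child in scores:
                continue
            scores[child] = score(child)
            if scores[child] > best_score + 1e-12:
                best_score = scores[child]
                best_subset = child
                improved = True
        stalled = 0 if improved else stalled + 1
    if not best_subset and scores:
        # empty set never beats a real subset for reporting purposes: fall
        # back to the best evaluated non-empty subset if one ties the baseline
        nonempty = [s for s in scores if s]
        if nonempty:
            cand = max(
                nonempty,
                key=lambda s: (scores[s], -len(s), tuple(-j for j in sorted(s))),
            )
            if scores[cand] >= best_score - 1e-12:
                best_subset = cand
    return [feature_names[j] for j in sorted(best_subset)]
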