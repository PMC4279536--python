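"""C4.5 decision-tree induction: gain-ratio splits, pessimistic pruning.

Numeric-attribute trees only (all features here are real-valued). Candidate
thresholds are midpoints between consecutive sorted values where the class
changes; splits are scored by gain ratio = information gain / split info,
and the grown tree is pruned bottom-up with Quinlan's pessimistic error
estimate at confidence factor CF = 0.25. Leaf class distributions provide
the per-window confidences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.stats import norm

from ..features import FeatureMatrix


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def gain_ratio(values: np.ndarray, labels: np.ndarray, threshold: float):
    """(information gain, split info, gain ratio) of a binary split at
    ``threshold`` (left: value <= threshold)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    left = values <= threshold
    total = np.array([(labels == c).sum() for c in classes], dtype=float)
    lc = np.array([(labels[left] == c).sum() for c in classes], dtype=float)
    rc = total - lc
    n = len(labels)
    nl, nr = left.sum(), n - left.sum()
    gain = _entropy(total) - (nl * _entropy(lc) + nr * _entropy(rc)) / n
    split_info = _entropy(np.array([nl, nr], dtype=float))
    ratio = gain / split_info if split_info > 0 else 0.0
    return gain, split_info, ratio


@dataclass
class Node:
    dist: np.ndarray  # class distribution at the node (sums to 1)
    n: int
    errors: int  # training errors if this node were a leaf
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    root: Node
    classes: np.ndarray
    feature_names: Optional[List[str]] = None
    cf: float = 0.25

    def predict_proba(self, X: Union[np.ndarray, FeatureMatrix]) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.X
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes)))
        for i, x in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.dist
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes[np.argmax(self.predict_proba(X), axis=1)]

    def n_leaves(self) -> int:
        def count(node: Node) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)


def _pessimistic_errors(n: int, e: int, z: float) -> float:
    """Quinlan's upper-bound error count for a leaf with n cases, e errors."""
    if n == 0:
        return 0.0
    f = e / n
    ucb = (
        f
        + z * z / (2 * n)
        + z * np.sqrt(f / n - f * f / n + z * z / (4 * n * n))
    ) / (1 + z * z / n)
    return float(n * ucb)


def _best_split(X: np.ndarray, y_idx: np.ndarray, k: int):
    """Best (feature, threshold, gain_ratio) by C4.5's criterion, or None."""
    n, p = X.shape
    total = np.bincount(y_idx, minlength=k).astype(float)
    H = _entropy(total)
    best = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y_idx[order]
        # cumulative class counts after each position
        onehot = np.zeros((n, k))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        # candidate cut after position i where value and class pattern change
        diff_val = xs[1:] > xs[:-1]
        cand = np.nonzero(diff_val)[0]
        if len(cand) == 0:
            continue
        nl = (cand + 1).astype(float)
        nr = n - nl
        lc = cum[cand]
        rc = total[None, :] - lc
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = lc / nl[:, None]
            pr = rc / nr[:, None]
            Hl = -np.where(pl > 0, pl * np.log2(np.where(pl > 0, pl, 1)), 0).sum(1)
            Hr = -np.where(pr > 0, pr * np.log2(np.where(pr > 0, pr, 1)), 0).sum(1)
        gains = H - (nl * Hl + nr * Hr) / n
        fl = nl / n
        fr = nr / n
        split_info = -(fl * np.log2(fl) + fr * np.log2(fr))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(split_info > 0, gains / split_info, 0.0)
        ratios = np.where(gains > 1e-12, ratios, -np.inf)
        i = int(np.argmax(ratios))
        if ratios[i] == -np.inf:
            continue
        thr = (xs[cand[i]] + xs[cand[i] + 1]) / 2.0
        key = (ratios[i], -j, -thr)
        if best is None or key > best[0]:
            best = (key, j, thr)
    if best is None:
        return None
    return best[1], best[2]


def train_c45(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Optional[np.ndarray] = None,
    min_leaf: int = 2,
    cf: float = 0.25,
    max_depth: int = 25,
    prune: bool = True,
) -> TreeModel:
    """Grow a gain-ratio tree and apply pessimistic-error pruning."""
    names = None
    if isinstance(X, FeatureMatrix):
        names = X.names
        if labels is None:
            labels = X.labels
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    classes = np.unique(y)
    k = len(classes)
    y_idx = np.searchsorted(classes, y)
    z = float(norm.ppf(1 - cf))

    def grow(rows: np.ndarray, depth: int) -> Node:
        counts = np.bincount(y_idx[rows], minlength=k).astype(float)
        n = int(counts.sum())
        errors = int(n - counts.max())
        node = Node(dist=counts / n, n=n, errors=errors)
        if errors == 0 or n < 2 * min_leaf or depth >= max_depth:
            return node
        split = _best_split(X[rows], y_idx[rows], k)
        if split is None:
            return node
        j, thr = split
        left_mask = X[rows, j] <= thr
        if left_mask.sum() < min_leaf or (~left_mask).sum() < min_leaf:
            return node
        node.feature = j
        node.threshold = float(thr)
        node.left = grow(rows[left_mask], depth + 1)
        node.right = grow(rows[~left_mask], depth + 1)
        return node

    root = grow(np.arange(X.shape[0]), 0)

    def prune_node(node: Node) -> float:
        """Returns the pessimistic error count of the (possibly pruned) subtree."""
        leaf_err = _pessimistic_errors(node.n, node.errors, z)
        if node.is_leaf:
            return leaf_err
        subtree_err = prune_node(node.left) + prune_node(node.right)
        if prune and leaf_err <= subtree_err + 0.1:
            node.feature = node.threshold = node.left = node.right = None
            return leaf_err
        return subtree_err

    prune_node(root)
    return TreeModel(root=root, classes=classes, feature_names=names, cf=cf)
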