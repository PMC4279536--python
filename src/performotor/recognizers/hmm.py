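"""Supervised Gaussian hidden Markov model for severity/posture decoding.

Training is supervised: per-state diagonal-Gaussian emissions are fitted
from labelled windows, the transition matrix from empirical label-to-label
transition frequencies with Laplace smoothing (alpha = 1), and the initial
distribution from empirical class frequencies. Decoding uses the scaled
forward-backward recursion, yielding per-window state posteriors whose
argmax is the reported label sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from ..features import FeatureMatrix

_VAR_FLOOR = 1e-8


@dataclass
class HMMModel:
    """States are ordered class labels; emissions diagonal Gaussian."""

    states: np.ndarray  # ordered label values, shape (k,)
    initial_probs: np.ndarray  # (k,)
    transition_matrix: np.ndarray  # (k, k), rows sum to 1
    means: np.ndarray  # (k, p)
    variances: np.ndarray  # (k, p), all > 0
    feature_names: Optional[List[str]] = None

    def validate(self) -> "HMMModel":
        k = len(self.states)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("initial probs must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        return self


def _as_sequences(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Union[None, np.ndarray, Sequence[np.ndarray]],
):
    if isinstance(X, FeatureMatrix):
        arr, names = X.X, X.names
        if labels is None:
            labels = X.labels
    else:
        arr, names = np.asarray(X, dtype=float), None
    if labels is None:
        raise ValueError("labels required")
    if isinstance(labels, (list, tuple)) and len(labels) and np.ndim(labels[0]) == 1:
        seqs = [np.asarray(l, dtype=int) for l in labels]
    else:
        seqs = [np.asarray(labels, dtype=int)]
    return arr, names, seqs


def train_hmm(
    X: Union[np.ndarray, FeatureMatrix],
    labels: Union[None, np.ndarray, Sequence[np.ndarray]] = None,
    classes: Optional[Sequence[int]] = None,
    min_per_class: int = 10,
) -> HMMModel:
    """Fit a supervised HMM from labelled windows.

    ``labels`` may be one sequence or a list of per-session sequences (the
    transition counts then never bridge session boundaries). Every class in
    ``classes`` (default: the classes present) must appear at least
    ``min_per_class`` times.
    """
    arr, names, seqs = _as_sequences(X, labels)
    flat = np.concatenate(seqs)
    if len(flat) != arr.shape[0]:
        raise ValueError("label count does not match feature rows")
    present, counts = np.unique(flat, return_counts=True)
    if classes is None:
        states = present
    else:
        states = np.asarray(sorted(classes), dtype=int)
        for c in states:
            if c not in present:
                raise ValueError(f"missing class {int(c)} in training labels")
    count_map = dict(zip(present.tolist(), counts.tolist()))
    for c in states:
        if count_map.get(int(c), 0) < min_per_class:
            raise ValueError(
                f"class {int(c)} has fewer than {min_per_class} windows"
            )
    k, p = len(states), arr.shape[1]
    means = np.zeros((k, p))
    variances = np.zeros((k, p))
    for i, c in enumerate(states):
        rows = arr[flat == c]
        means[i] = rows.mean(axis=0)
        variances[i] = np.maximum(rows.var(axis=0), _VAR_FLOOR)
    state_idx = {int(c): i for i, c in enumerate(states)}
    trans = np.ones((k, k))  # Laplace alpha=1
    for seq in seqs:
        for a, b in zip(seq[:-1], seq[1:]):
            trans[state_idx[int(a)], state_idx[int(b)]] += 1
    trans /= trans.sum(axis=1, keepdims=True)
    initial = np.array([count_map[int(c)] for c in states], dtype=float)
    initial /= initial.sum()
    return HMMModel(
        states=states,
        initial_probs=initial,
        transition_matrix=trans,
        means=means,
        variances=variances,
        feature_names=names,
    ).validate()


def _log_emissions(model: HMMModel, X: np.ndarray) -> np.ndarray:
    """(n, k) diagonal-Gaussian log densities."""
    diff = X[:, None, :] - model.means[None, :, :]
    return -0.5 * (
        np.log(2 * np.pi * model.variances).sum(axis=1)[None, :]
        + (diff**2 / model.variances[None, :, :]).sum(axis=2)
    )


def decode_posteriors(
    model: HMMModel, X: Union[np.ndarray, FeatureMatrix]
) -> np.ndarray:
    """Scaled forward-backward state posteriors, one row per window.

    Rows sum to 1; argmax (ties resolved toward the lower severity, i.e.
    the earlier state) gives the decoded label sequence.
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape} does not match model "
            f"({model.means.shape[1]} features)"
        )
    n, k = X.shape[0], len(model.states)
    logB = _log_emissions(model, X)
    # per-row shift for numerical stability, cancels in the posterior
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.zeros((n, k))
    c = np.zeros(n)
    alpha[0] = model.initial_probs * B[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    A = model.transition_matrix
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.ones((n, k))
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def decode_labels(model: HMMModel, X) -> np.ndarray:
    post = decode_posteriors(model, X)
    return model.states[np.argmax(post, axis=1)]
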