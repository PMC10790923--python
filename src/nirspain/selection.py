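"""ReliefF feature weighting with the square-root k-rule and elbow cut-off.

The implementation is the deterministic full-pass variant: every training
sample serves as a reference, so no sampling seed is involved. Distances are
Manhattan on internally min-max-normalised features. For each reference, its
k nearest same-class neighbours (hits) decrease each feature's weight and its
k nearest other-class neighbours (misses) increase it by the range-normalised
absolute difference, averaged over references and k. For binary labels the
class-prior miss weighting reduces to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


class SelectionError(ValueError):
    pass


@dataclass
class RankedFeatureSet:
    feature_names: list  # ordered by descending weight
    weights: np.ndarray  # same order
    k: int
    cutoff: int  # number of features kept
    method: str  # "elbow_auto" or "manual"

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if np.any(np.diff(w) > 1e-12):
            raise SelectionError("weights must be sorted non-increasing")
        if not (1 <= self.cutoff <= len(w)):
            raise SelectionError("cutoff out of range")

    @property
    def selected(self):
        return self.feature_names[: self.cutoff]


def choose_k(n_features: int) -> int:
    """k = round(sqrt(n_features)) (half-even), bumped to the next odd number."""
    if n_features < 1:
        raise SelectionError("need at least one feature")
    k = int(np.round(np.sqrt(n_features)))  # numpy rounds half to even
    if k % 2 == 0:
        k += 1
    return max(k, 1)


def _minmax_normalise(X):
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    return (X - lo) / rng_safe


def relieff_weights(X, y, k) -> np.ndarray:
    """Deterministic full-pass ReliefF weights for binary labels.

    Every sample is used as a reference; neighbours are found by Manhattan
    distance in min-max-normalised feature space. Requires each class to have
    more than ``k`` members.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise SelectionError("X must be 2-D")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise SelectionError("relieff_weights expects binary labels")
    if counts.min() <= k:
        raise SelectionError(f"class with {counts.min()} members <= k={k}")
    Z = _minmax_normalise(X)
    m, p = Z.shape
    D = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(p)
    for i in range(m):
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        same = same[same != i]
        hits = same[np.argsort(D[i, same], kind="stable")[:k]]
        misses = other[np.argsort(D[i, other], kind="stable")[:k]]
        W += np.abs(Z[i] - Z[misses]).sum(axis=0) - np.abs(Z[i] - Z[hits]).sum(axis=0)
    return W / (m * k)


def elbow_cutoff(sorted_weights, collinear_tol=1e-9) -> int:
    """Number of features to keep, from the elbow of the sorted-weight curve.

    The elbow is the point of maximum perpendicular distance from the chord
    joining the first and last weight. When that point lies below the chord
    (the typical sharp drop) the cut is placed just before it; when above, at
    it. Near-collinear curves fall back to keeping every positive-weight
    feature; fewer than 3 weights keeps everything.
    """
    w = np.asarray(sorted_weights, float)
    n = len(w)
    if n < 3:
        return max(n, 1)
    x = np.arange(1, n + 1, dtype=float)
    dx, dy = n - 1.0, w[-1] - w[0]
    norm = np.hypot(dx, dy)
    # signed distance: positive above the chord, negative below
    signed = (dy * (x - 1.0) - dx * (w - w[0])) / norm * -1.0
    j = int(np.argmax(np.abs(signed)))
    if np.abs(signed[j]) < collinear_tol:
        kept = int(np.sum(w > 0))
        return max(kept, 1)
    if signed[j] < 0:  # elbow point is already in the flat tail
        return max(j, 1)
    return j + 1


def select_features(train_X, train_y, feature_names=None, k=None, manual_cutoff=None) -> RankedFeatureSet:
    """ReliefF ranking + cut-off on a training partition.

    ``k`` overrides the square-root rule (the fNIRS analyses use k=15, which
    the rule cannot produce from 96 features); ``manual_cutoff`` overrides the
    elbow.
    """
    X = np.asarray(train_X, float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if k is None:
        k = choose_k(X.shape[1])
    W = relieff_weights(X, train_y, k)
    order = np.argsort(-W, kind="stable")
    sorted_w = W[order]
    if manual_cutoff is not None:
        if not (1 <= manual_cutoff <= len(sorted_w)):
            raise SelectionError("manual_cutoff out of range")
        cutoff, method = int(manual_cutoff), "manual"
    else:
        cutoff, method = elbow_cutoff(sorted_w), "elbow_auto"
    return RankedFeatureSet(
        feature_names=[feature_names[i] for i in order],
        weights=sorted_w,
        k=k,
        cutoff=cutoff,
        method=method,
    )
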