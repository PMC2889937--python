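"""Feature ranking (ReliefF) and subset selection (correlation-based, CFS).

ReliefF weights features by how well they separate each instance from its
nearest neighbours of the opposite class relative to its own class, using
range-normalised Manhattan distance.  CFS searches for the feature subset
maximising

    merit(S) = k * mean(su_fc) / sqrt(k + k (k - 1) * mean(su_ff))

where su_fc / su_ff are symmetrical uncertainties between (discretised)
features and the class / each other, via best-first search with a stale
expansion stop.
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class LabeledTable:
    """A numeric feature table with binary labels (1 = target site)."""

    frame: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.frame) != self.labels.size:
            raise ValueError("labels and rows disagree in length")

    @property
    def feature_names(self) -> list:
        return list(self.frame.columns)

    @property
    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def check_two_classes(self, min_per_class: int = 1) -> None:
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] < min_per_class or counts[1] < min_per_class:
            raise ValueError(
                f"both classes required (counts: {counts[0]} neg / {counts[1]} pos)"
            )


@dataclass
class FeatureRanking:
    """(feature, ReliefF weight) pairs in descending weight order."""

    entries: list = field(default_factory=list)

    def names(self) -> list:
        return [name for name, _ in self.entries]

    def __iter__(self):
        return iter(self.entries)


def relieff_rank(table: LabeledTable, k_neighbors: int = 10,
                 n_sample: int | None = None, seed: int = 0) -> FeatureRanking:
    """ReliefF feature weights for a two-class table.

    For each sampled instance the k nearest hits (same class) and k nearest
    misses (other class) are found under range-normalised Manhattan distance;
    each feature's weight accumulates mean miss-differences minus mean
    hit-differences.  Constant features have zero difference by convention.
    """
    table.check_two_classes(min_per_class=2)
    X = table.X
    y = table.labels
    n, d = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_span > 0, rng_span, 1.0)
    Xn = (X - X.min(axis=0)) / scale
    Xn[:, rng_span == 0] = 0.0

    if n_sample is None or n_sample >= n:
        sample = np.arange(n)
    else:
        sample = np.sort(np.random.default_rng(seed).choice(n, n_sample, replace=False))

    D = cdist(Xn[sample], Xn, metric="cityblock")
    W = np.zeros(d)
    for row, i in enumerate(sample):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        k_hit = min(k_neighbors, same.size)
        k_miss = min(k_neighbors, other.size)
        hits = same[np.argsort(D[row, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(D[row, other], kind="stable")[:k_miss]]
        if k_hit:
            W -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / k_hit
        if k_miss:
            W += np.abs(Xn[misses] - Xn[i]).sum(axis=0) / k_miss
    W /= sample.size
    order = sorted(zip(table.feature_names, W), key=lambda t: (-t[1], t[0]))
    return FeatureRanking([(name, float(w)) for name, w in order])


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretisation into at most n_bins levels."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """2 * I(A; B) / (H(A) + H(B)) over discrete codes; 0 when degenerate."""
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    joint = _entropy(a.astype(np.int64) * (b.max() + 1) + b.astype(np.int64))
    return max(0.0, 2.0 * (ha + hb - joint) / (ha + hb))


def cfs_merit(su_fc: np.ndarray, su_ff: np.ndarray, subset) -> float:
    """CFS merit of a feature subset given precomputed SU matrices."""
    idx = list(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    rcf = float(np.mean(su_fc[idx]))
    if k == 1:
        rff = 0.0
    else:
        pairs = list(itertools.combinations(idx, 2))
        rff = float(np.mean([su_ff[i, j] for i, j in pairs]))
    denom = np.sqrt(k + k * (k - 1) * rff)
    return k * rcf / denom if denom > 0 else 0.0


def su_matrices(table: LabeledTable, n_bins: int | None = None):
    """Feature-class and feature-feature symmetrical uncertainty matrices."""
    X = table.X
    n, d = X.shape
    if n_bins is None:
        n_bins = max(2, min(10, int(np.sqrt(n))))
    codes = np.column_stack([_discretize(X[:, f], n_bins) for f in range(d)])
    y = table.labels
    su_fc = np.array([symmetrical_uncertainty(codes[:, f], y) for f in range(d)])
    su_ff = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            su_ff[i, j] = su_ff[j, i] = symmetrical_uncertainty(codes[:, i], codes[:, j])
    return su_fc, su_ff


def cfs_select(table: LabeledTable, stale_limit: int = 5,
               n_bins: int | None = None) -> tuple:
    """Best-first CFS subset selection; returns an ordered feature-name tuple."""
    table.check_two_classes()
    if len(table.feature_names) < 2:
        raise ValueError("need at least two features for subset selection")
    su_fc, su_ff = su_matrices(table, n_bins)
    d = su_fc.size

    best_merit = 0.0
    best_set: frozenset = frozenset()
    # heap of (-merit, sorted subset tuple); expansion = add one feature
    start: frozenset = frozenset()
    open_heap = [(0.0, tuple())]
    seen = {start}
    stale = 0
    while open_heap and stale < stale_limit:
        neg_merit, subset_t = heapq.heappop(open_heap)
        subset = frozenset(subset_t)
        improved = False
        for f in range(d):
            if f in subset:
                continue
            child = subset | {f}
            if child in seen:
                continue
            seen.add(child)
            merit = cfs_merit(su_fc, su_ff, child)
            heapq.heappush(open_heap, (-merit, tuple(sorted(child))))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_set = child
                improved = True
        stale = 0 if improved else stale + 1
    names = table.feature_names
    if not best_set:
        # degenerate table: fall back to the single best feature
        best_set = {int(np.argmax(su_fc))}
    return tuple(names[f] for f in sorted(best_set))
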