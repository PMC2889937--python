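"""Independent reference implementations used as test oracles.

These deliberately avoid the package's optimised code paths: structures are
enumerated exhaustively, boosting is a plain AdaBoost loop, AUC is the
Mann-Whitney rank statistic, and interval merging is a coverage-array union.
"""
from __future__ import annotations

import numpy as np

from mirspot.boosting import _fit_stump
from mirspot.energy import score_structure
from mirspot.sequences import CAN_PAIR, is_gu


def enumerate_structures(mirna, utr, anchor, params, require_seed=False,
                         first_i_max=None):
    """All admissible anchored pair lists (1-based), including G:U filters."""
    m = len(mirna)
    span = len(mirna) + 15
    jmin = max(1, anchor - span)
    out = []

    def extend(pairs, helix_len):
        i, j = pairs[-1]
        if helix_len >= 2:
            out.append(list(pairs))
        for i2 in range(i + 1, m + 1):
            a = i2 - i - 1
            if a > params.max_loop_side:
                break
            for j2 in range(j - 1, jmin - 1, -1):
                b = j - j2 - 1
                if b > params.max_loop_side:
                    break
                if (a or b) and helix_len < 2:
                    continue
                if (mirna[i2 - 1], utr[j2 - 1]) not in CAN_PAIR:
                    continue
                pairs.append((i2, j2))
                extend(pairs, helix_len + 1 if (a == 0 and b == 0) else 1)
                pairs.pop()

    starts = range(1, m + 1) if first_i_max is None else range(1, first_i_max + 1)
    for i0 in starts:
        if (mirna[i0 - 1], utr[anchor - 1]) in CAN_PAIR:
            extend([(i0, anchor)], 1)

    kept = []
    for pairs in out:
        gu = [is_gu(mirna[i - 1], utr[j - 1]) for i, j in pairs]
        if any(gu[:8]) or sum(gu) >= 5:
            continue
        if require_seed:
            if len(pairs) < 7 or any(
                pairs[k] != (k + 1, anchor - k) for k in range(7)
            ):
                continue
        kept.append(pairs)
    return kept


def brute_minimum(mirna, utr, anchor, params, require_seed=False,
                  first_i_max=None):
    """(min (energy, n_pairs), argmin pair lists) by exhaustive enumeration."""
    best = None
    argmin = []
    for pairs in enumerate_structures(mirna, utr, anchor, params,
                                      require_seed, first_i_max):
        e = score_structure(pairs, mirna, utr, params)
        key = (round(e, 9), len(pairs))
        if best is None or key < best:
            best, argmin = key, [pairs]
        elif key == best:
            argmin.append(pairs)
    return best, argmin


def plain_adaboost(table, n_iterations, alpha_cap=np.log(1e10),
                   weight_floor=1e-8):
    """Textbook AdaBoost.M1 over decision stumps (shared base learner).

    Returns [(stump, alpha)] with the standard early stops: discard and halt
    on weighted error >= 0.5, keep with capped alpha and halt on error 0.
    """
    X = table.X
    y = table.labels
    names = table.feature_names
    n = X.shape[0]
    orders = [np.argsort(X[:, f], kind="stable") for f in range(X.shape[1])]
    w = np.ones(n)
    committee = []
    for _ in range(n_iterations):
        stump, err = _fit_stump(X, y, w, orders, names)
        if err >= 0.5:
            break
        if err <= 0.0:
            committee.append((stump, alpha_cap))
            break
        alpha = np.log((1 - err) / err)
        committee.append((stump, alpha))
        pred = np.where(X[:, names.index(stump.feature_name)] <= stump.split_value,
                        stump.left_class, stump.right_class)
        w = w * np.where(pred != y, 0.5 / err, 0.5 / (1 - err))
        w = np.maximum(w, weight_floor)
    return committee


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)


def union_intervals(intervals):
    """Transitive closure of pairwise overlap (>= 1 shared position).

    Adjacent-but-disjoint intervals stay separate, unlike a coverage union.
    """
    groups = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                (s1, e1), (s2, e2) = groups[a], groups[b]
                if s1 <= e2 and s2 <= e1:
                    groups[a] = (min(s1, s2), max(e1, e2))
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return sorted(groups)


def relieff_direct(X, y, k_neighbors):
    """Direct-definition ReliefF (all instances, range-normalised Manhattan)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    scale = np.where(span > 0, span, 1.0)
    Xn = (X - X.min(axis=0)) / scale
    Xn[:, span == 0] = 0.0
    W = np.zeros(d)
    for i in range(n):
        dist = np.abs(Xn - Xn[i]).sum(axis=1)
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        kh = min(k_neighbors, same.size)
        km = min(k_neighbors, other.size)
        hits = same[np.argsort(dist[same], kind="stable")[:kh]]
        misses = other[np.argsort(dist[other], kind="stable")[:km]]
        W -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / kh
        W += np.abs(Xn[misses] - Xn[i]).sum(axis=0) / km
    return W / n
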