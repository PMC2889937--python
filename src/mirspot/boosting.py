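"""MultiBoost committee of decision stumps with FPR-calibrated thresholds.

MultiBoost runs AdaBoost weight updates inside subcommittees and resets the
instance weights by continuous-Poisson wagging at subcommittee boundaries;
with a single subcommittee it reduces exactly to AdaBoost.  The base learner
is the minimum-weighted-error decision stump over all features and midpoints
between consecutive distinct values.  Committee votes are mapped to a score
in [0, 1]; sensitive and specific operating points are calibrated from
out-of-fold cross-validation scores at 5% and 1% false-positive rates.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .selection import LabeledTable

#: alpha assigned to a stump with zero weighted error
ALPHA_CAP = math.log(1e10)
#: weight floor applied after boosting updates and wagging
WEIGHT_FLOOR = 1e-8


@dataclass(frozen=True)
class DecisionStump:
    """One-split base classifier: predicts ``left_class`` when
    feature <= split_value, else ``right_class``."""

    feature_name: str
    split_value: float
    left_class: int
    right_class: int
    alpha: float

    def decide(self, x: float) -> int:
        return self.left_class if x <= self.split_value else self.right_class


@dataclass
class RocCurve:
    """ROC points and area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class BoostedModel:
    """Weighted committee of decision stumps plus calibrated thresholds."""

    stumps: list
    n_iterations: int
    subcommittee_bounds: list
    feature_set: tuple
    thresholds: dict | None = None
    seed: int = 0
    energy_table_version: str = ""

    @property
    def alpha_total(self) -> float:
        return sum(s.alpha for s in self.stumps)

    def score(self, features: dict) -> float:
        """Normalised committee vote for the positive class, in [0, 1]."""
        missing = [s.feature_name for s in self.stumps if s.feature_name not in features]
        missing += [f for f in self.feature_set if f not in features]
        if missing:
            raise KeyError(f"feature vector lacks {sorted(set(missing))}")
        if not self.stumps:
            return 0.5
        margin = sum(
            s.alpha * (1.0 if s.decide(features[s.feature_name]) == 1 else -1.0)
            for s in self.stumps
        )
        return 0.5 * (margin / self.alpha_total + 1.0)

    def score_matrix(self, X: np.ndarray, feature_names: list) -> np.ndarray:
        """Vectorised scoring of an (n, d) matrix with named columns."""
        if not self.stumps:
            return np.full(X.shape[0], 0.5)
        col = {name: k for k, name in enumerate(feature_names)}
        margin = np.zeros(X.shape[0])
        for s in self.stumps:
            x = X[:, col[s.feature_name]]
            cls = np.where(x <= s.split_value, s.left_class, s.right_class)
            margin += s.alpha * np.where(cls == 1, 1.0, -1.0)
        return 0.5 * (margin / self.alpha_total + 1.0)

    def to_json(self) -> str:
        return json.dumps({
            "stumps": [
                {"feature": s.feature_name, "split": s.split_value,
                 "left": s.left_class, "right": s.right_class, "alpha": s.alpha}
                for s in self.stumps
            ],
            "n_iterations": self.n_iterations,
            "subcommittee_bounds": list(self.subcommittee_bounds),
            "feature_set": list(self.feature_set),
            "thresholds": self.thresholds,
            "seed": self.seed,
            "energy_table_version": self.energy_table_version,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BoostedModel":
        d = json.loads(text)
        return cls(
            stumps=[
                DecisionStump(s["feature"], s["split"], s["left"], s["right"], s["alpha"])
                for s in d["stumps"]
            ],
            n_iterations=d["n_iterations"],
            subcommittee_bounds=list(d["subcommittee_bounds"]),
            feature_set=tuple(d["feature_set"]),
            thresholds=d["thresholds"],
            seed=d["seed"],
            energy_table_version=d.get("energy_table_version", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "BoostedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _fit_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               orders: list, feature_names: list) -> tuple:
    """Best weighted-error stump; ties broken by (feature index, split, polarity)."""
    n, d = X.shape
    total = w.sum()
    best = None  # (error, f, k, polarity, split)
    for f in range(d):
        order = orders[f]
        xs = X[order, f]
        ws = w[order]
        ys = y[order]
        cpos = np.cumsum(ws * (ys == 1))
        cneg = np.cumsum(ws * (ys == 0))
        valid = np.flatnonzero(xs[:-1] < xs[1:])
        if valid.size == 0:
            continue
        # polarity 0: left_class=0/right_class=1; polarity 1: the reverse
        err0 = cpos[valid] + (cneg[-1] - cneg[valid])
        err1 = cneg[valid] + (cpos[-1] - cpos[valid])
        for pol, errs in ((0, err0), (1, err1)):
            k = int(np.argmin(errs))
            cand = (float(errs[k]), f, int(valid[k]), pol)
            if best is None or cand < best:
                best = cand
    if best is None:
        # all features constant: majority stump
        cls = int(w[y == 1].sum() >= w[y == 0].sum())
        err = min(w[y == 1].sum(), w[y == 0].sum())
        return DecisionStump(feature_names[0], math.inf, cls, cls, 0.0), err / total
    err, f, k, pol = best
    order = orders[f]
    xs = X[order, f]
    split = 0.5 * (xs[k] + xs[k + 1])
    left, right = (0, 1) if pol == 0 else (1, 0)
    return DecisionStump(feature_names[f], float(split), left, right, 0.0), err / total


def wagging_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    """Continuous-Poisson (standard exponential) weights standardised to sum n."""
    w = rng.exponential(1.0, n)
    w *= n / w.sum()
    return np.maximum(w, WEIGHT_FLOOR)


def subcommittee_boundaries(n_iterations: int, n_subcommittees: int) -> list:
    return sorted({
        math.ceil((k + 1) * n_iterations / n_subcommittees)
        for k in range(n_subcommittees)
    })


def train_multiboost(table: LabeledTable, n_iterations: int = 200, seed: int = 0,
                     n_subcommittees: int | None = None,
                     feature_set: tuple | None = None,
                     energy_table_version: str = "") -> BoostedModel:
    """Train a MultiBoost stump committee on a labeled feature table.

    ``n_subcommittees`` defaults to ceil(sqrt(n_iterations)); with 1 the
    procedure is plain AdaBoost.  A subcommittee terminates early when the
    stump's weighted error reaches 0.5 (stump discarded) or 0 (stump kept
    with a capped vote weight), after which wagging restarts the weights.
    """
    table.check_two_classes()
    names = table.feature_names
    if feature_set is not None:
        names = list(feature_set)
    X = table.frame[names].to_numpy(dtype=float)
    y = table.labels
    n = X.shape[0]
    if n_subcommittees is None:
        n_subcommittees = math.ceil(math.sqrt(n_iterations))
    bounds = subcommittee_boundaries(n_iterations, n_subcommittees)

    rng = np.random.default_rng(seed)
    orders = [np.argsort(X[:, f], kind="stable") for f in range(X.shape[1])]
    w = np.ones(n)
    stumps: list = []
    t = 0
    for k, end in enumerate(bounds):
        if k > 0:
            w = wagging_weights(rng, n)
        while t < end:
            t += 1
            stump, err = _fit_stump(X, y, w, orders, names)
            if err >= 0.5:
                t = end  # terminate subcommittee, discard stump
                break
            if err <= 0.0:
                stumps.append(DecisionStump(
                    stump.feature_name, stump.split_value,
                    stump.left_class, stump.right_class, ALPHA_CAP))
                t = end
                break
            alpha = math.log((1.0 - err) / err)
            stumps.append(DecisionStump(
                stump.feature_name, stump.split_value,
                stump.left_class, stump.right_class, alpha))
            pred = np.where(X[:, names.index(stump.feature_name)] <= stump.split_value,
                            stump.left_class, stump.right_class)
            wrong = pred != y
            w = w * np.where(wrong, 0.5 / err, 0.5 / (1.0 - err))
            w = np.maximum(w, WEIGHT_FLOOR)
    return BoostedModel(
        stumps=stumps,
        n_iterations=n_iterations,
        subcommittee_bounds=bounds,
        feature_set=tuple(names),
        seed=seed,
        energy_table_version=energy_table_version,
    )


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


@dataclass
class CrossValidationResult:
    oof_scores: np.ndarray
    labels: np.ndarray
    roc: RocCurve
    fold_models: list = field(default_factory=list)


def cross_validate(table: LabeledTable, folds: int = 10, seed: int = 0,
                   n_iterations: int = 200, n_subcommittees: int | None = None,
                   feature_set: tuple | None = None) -> CrossValidationResult:
    """Stratified k-fold out-of-fold scoring with a pooled ROC curve."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    table.check_two_classes(min_per_class=folds if folds <= len(table.frame) else 1)
    names = list(feature_set) if feature_set is not None else table.feature_names
    X = table.frame[names].to_numpy(dtype=float)
    y = table.labels
    oof = np.full(y.size, np.nan)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 31))
    models = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        sub = LabeledTable(table.frame.iloc[tr][names], y[tr])
        model = train_multiboost(
            sub, n_iterations=n_iterations,
            seed=(seed * 100003 + 7919 * (fold + 1)) % (2 ** 31),
            n_subcommittees=n_subcommittees)
        oof[te] = model.score_matrix(X[te], names)
        models.append(model)
    return CrossValidationResult(
        oof_scores=oof, labels=y, roc=roc_from_scores(oof, y), fold_models=models
    )


def calibrate_thresholds(oof_scores: np.ndarray, labels: np.ndarray,
                         sens_fpr: float = 0.05, spec_fpr: float = 0.01) -> dict:
    """Score thresholds meeting empirical FPR < sens_fpr and <= spec_fpr.

    Returns {"sens": s, "spec": s'} with s' >= s; each is the smallest score
    at which the empirical false-positive rate of "score >= threshold"
    predictions satisfies its bound.
    """
    scores = np.asarray(oof_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ValueError("both classes required for calibration")
    if np.min(scores) == np.max(scores):
        raise ValueError(
            "degenerate score distribution (all scores equal); "
            "the committee carries no ranking information"
        )
    neg = np.sort(scores[labels == 0])[::-1]
    n = neg.size

    def threshold_for(max_count: int) -> float:
        if max_count >= n:
            return float(np.min(scores))
        return float(np.nextafter(neg[max_count], np.inf))

    # strict: count/n < sens_fpr
    lim = int(round(sens_fpr * 1e6)) * n
    c_sens = lim // 10 ** 6 - 1 if lim % 10 ** 6 == 0 else lim // 10 ** 6
    c_sens = max(c_sens, 0)
    # non-strict: count/n <= spec_fpr
    c_spec = (int(round(spec_fpr * 1e6)) * n) // 10 ** 6
    sens = threshold_for(c_sens)
    spec = max(sens, threshold_for(c_spec))
    return {"sens": sens, "spec": spec}
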