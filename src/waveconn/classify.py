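"""Boosted decision-tree classification of the two subject groups.

A C4.5-style learner for continuous features — axis-aligned binary
splits chosen by gain ratio, with pessimistic (upper-confidence-bound)
error pruning — combined by AdaBoost.M1 with 10 boosting trials and
evaluated by stratified 6-fold cross-validation with confusion counts
pooled across folds.  The patient group is the positive class
throughout: sensitivity = TP / (TP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from waveconn.graphs import METRIC_NAMES

__all__ = [
    "DecisionTree",
    "AdaBoostM1",
    "ClassificationReport",
    "fit_tree",
    "adaboost",
    "cross_validate",
    "classification_sweep",
]

_EPS = 1e-12


@dataclass
class _Node:
    prediction: int
    counts: np.ndarray  # weighted class counts at this node
    n: float = 0.0  # weighted number of samples
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _pessimistic_errors(f_err: float, n: float, z: float) -> float:
    """Upper confidence bound on the error count of a leaf.

    Wilson-score upper limit of the binomial error rate at confidence
    ``CF`` (``z = Phi^{-1}(1 - CF)``), times n — the C4.5 pessimistic
    error estimate.
    """
    if n <= 0:
        return 0.0
    z2 = z * z
    ub = (f_err + z2 / (2 * n)
          + z * np.sqrt(f_err * (1 - f_err) / n + z2 / (4 * n * n)))
    ub /= 1 + z2 / n
    return float(ub * n)


@dataclass
class DecisionTree:
    """C4.5-style decision tree for continuous features.

    Parameters
    ----------
    min_samples_leaf : float
        Minimum weighted sample mass required in each child.
    max_depth : int
        Depth cap (safety bound; pruning is the main regulariser).
    prune_confidence : float
        CF of the pessimistic pruning rule; smaller prunes harder.
        0 disables pruning.
    """

    min_samples_leaf: float = 1.0
    max_depth: int = 12
    prune_confidence: float = 0.25
    n_classes: int = 2
    root: _Node | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "DecisionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if sample_weight is None:
            sample_weight = np.ones(y.size)
        w = np.asarray(sample_weight, dtype=float)
        self.n_classes = max(self.n_classes, int(y.max()) + 1) if y.size else 2
        self.root = self._grow(X, y, w, depth=0)
        if self.prune_confidence > 0:
            z = float(norm.ppf(1 - self.prune_confidence))
            self._prune(self.root, z)
        return self

    def _class_counts(self, y, w):
        counts = np.zeros(self.n_classes)
        np.add.at(counts, y, w)
        return counts

    def _grow(self, X, y, w, depth) -> _Node:
        counts = self._class_counts(y, w)
        node = _Node(prediction=int(np.argmax(counts)), counts=counts,
                     n=float(w.sum()))
        if depth >= self.max_depth or np.count_nonzero(counts) <= 1:
            return node
        split = self._best_split(X, y, w)
        if split is None:
            return node
        j, thr = split
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y[mask], w[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], w[~mask], depth + 1)
        return node

    def _best_split(self, X, y, w):
        total = w.sum()
        base = _entropy(self._class_counts(y, w))
        best = None
        best_ratio = _EPS
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xv, yv, wv = X[order, j], y[order], w[order]
            # cumulative weighted class counts over the sorted column
            onehot = np.zeros((yv.size, self.n_classes))
            onehot[np.arange(yv.size), yv] = wv
            cum = np.cumsum(onehot, axis=0)
            tot = cum[-1]
            boundaries = np.nonzero(np.diff(xv) > 0)[0]
            for b in boundaries:
                left, right = cum[b], tot - cum[b]
                wl, wr = left.sum(), right.sum()
                if wl < self.min_samples_leaf or wr < self.min_samples_leaf:
                    continue
                gain = base - (wl / total) * _entropy(left) \
                    - (wr / total) * _entropy(right)
                if gain <= _EPS:
                    continue
                pl, pr = wl / total, wr / total
                split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
                ratio = gain / split_info if split_info > _EPS else 0.0
                if ratio > best_ratio:
                    best_ratio = ratio
                    best = (j, float((xv[b] + xv[b + 1]) / 2.0))
        return best

    def _prune(self, node: _Node, z: float) -> float:
        """Bottom-up pessimistic pruning; returns the subtree's error bound."""
        n = node.n
        err_as_leaf = _pessimistic_errors(
            1.0 - (node.counts[node.prediction] / n if n > 0 else 0.0), n, z)
        if node.is_leaf:
            return err_as_leaf
        err_subtree = self._prune(node.left, z) + self._prune(node.right, z)
        if err_as_leaf <= err_subtree + _EPS:
            node.left = node.right = None
            node.feature = -1
            return err_as_leaf
        return err_subtree

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold \
                    else node.right
            out[i] = node.prediction
        return out

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)


def fit_tree(features, labels, sample_weight=None, **config) -> DecisionTree:
    """Fit a single gain-ratio decision tree (see :class:`DecisionTree`)."""
    return DecisionTree(**config).fit(features, labels, sample_weight)


@dataclass
class AdaBoostM1:
    """AdaBoost.M1 over gain-ratio trees with weighted voting.

    Boosting reweights the training set after every trial — up-weighting
    misclassified subjects — and stops early when a learner's weighted
    error reaches 0 (nothing left to fix) or 0.5 (no better than
    chance).
    """

    n_trials: int = 10
    tree_config: dict = field(default_factory=dict)
    learners: list[DecisionTree] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    n_classes: int = 2

    def fit(self, X, y) -> "AdaBoostM1":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = y.size
        self.n_classes = int(y.max()) + 1 if n else 2
        w = np.full(n, 1.0 / n)
        self.learners, self.alphas = [], []
        for _ in range(max(1, self.n_trials)):
            # weights rescaled to mean 1 so min_samples_leaf keeps its
            # sample-count meaning regardless of the boosting round
            tree = DecisionTree(**self.tree_config).fit(X, y, w * n)
            miss = tree.predict(X) != y
            err = float(w[miss].sum())
            if err == 0.0:
                self.learners.append(tree)
                self.alphas.append(np.log((n - 1) / _EPS))  # effectively decisive
                break
            if err >= 0.5:
                if not self.learners:  # keep one learner even if weak
                    self.learners.append(tree)
                    self.alphas.append(1.0)
                break
            beta = err / (1.0 - err)
            self.learners.append(tree)
            self.alphas.append(float(np.log(1.0 / beta)))
            w = np.where(miss, w, w * beta)
            w /= w.sum()
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.n_classes))
        for alpha, tree in zip(self.alphas, self.learners):
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += alpha
        return np.argmax(votes, axis=1)


def adaboost(features, labels, n_trials: int = 10, **tree_config) -> AdaBoostM1:
    """Fit a 10-trial (by default) boosted ensemble of gain-ratio trees."""
    return AdaBoostM1(n_trials=n_trials, tree_config=tree_config).fit(
        features, labels)


@dataclass
class ClassificationReport:
    """Pooled cross-validated confusion counts and derived rates.

    The positive class is the patient group: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }


def cross_validate(features, labels, n_folds: int = 6, seed: int = 0,
                   n_trials: int = 10, positive: int = 1,
                   **tree_config) -> ClassificationReport:
    """Stratified k-fold cross-validation of the boosted classifier.

    Subjects are divided into ``n_folds`` stratified folds; for each
    fold the ensemble is trained on the rest and tested on it, and the
    2x2 confusion counts are accumulated across folds so every subject
    is tested exactly once.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    if n_folds > min(np.bincount(y)):
        raise ValueError("n_folds exceeds the smaller class count")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        model = AdaBoostM1(n_trials=n_trials, tree_config=tree_config).fit(
            X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(((pred == positive) & (truth == positive)).sum())
        tn += int(((pred != positive) & (truth != positive)).sum())
        fp += int(((pred == positive) & (truth != positive)).sum())
        fn += int(((pred != positive) & (truth == positive)).sum())
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_sweep(table: pd.DataFrame, scale: int = 2,
                         method: str = "MODWT", n_folds: int = 6,
                         n_trials: int = 10, seed: int = 0,
                         metrics=METRIC_NAMES) -> pd.DataFrame:
    """One cross-validated report per (family, length) at one scale.

    Features are the eight graph metrics of each subject's network for
    that cell; labels are the group (patient = positive).  Returns a
    tidy table with accuracy, sensitivity, specificity and the pooled
    confusion counts.
    """
    sub = table[(table["scale"] == scale) & (table["method"] == method)]
    if sub.empty:
        raise ValueError(f"no rows at scale {scale} for method {method}")
    rows = []
    for (family, length), grp in sub.groupby(["family", "length"], sort=True):
        grp = grp.sort_values("subject_id")
        X = grp[list(metrics)].to_numpy()
        if np.isnan(X).any():
            raise ValueError(f"missing metric values in cell {family}{length}")
        y = (grp["group"] == "patient").astype(int).to_numpy()
        rep = cross_validate(X, y, n_folds=n_folds, seed=seed,
                             n_trials=n_trials)
        rows.append({"family": family, "length": int(length), "scale": scale,
                     "method": method, "seed": seed} | rep.as_dict())
    return pd.DataFrame(rows)
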