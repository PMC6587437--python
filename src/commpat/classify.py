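"""Diagnostic classification from the five community-quality features.

A Gaussian linear discriminant (shared pooled covariance, Bayes-rule
posteriors) and a k-nearest-neighbour classifier, evaluated by
leave-one-out or stratified 10-fold cross-validation with accuracy,
precision and recall, plus recursive feature elimination for ranking
feature importance.  Every tie (posterior, vote, distance, elimination)
is broken deterministically so reports are reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "case"


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary group labels."""

    x: np.ndarray
    y: np.ndarray  # string labels
    feature_names: list[str]
    subject_ids: list[str] = field(default_factory=list)
    threshold: float | tuple[float, ...] = float("nan")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if self.x.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if np.isnan(self.x).any():
            raise ValueError("feature table contains missing values")
        if len(self.y) != self.x.shape[0]:
            raise ValueError("label count must match row count")
        if len(np.unique(self.y)) != 2:
            raise ValueError("labels must be binary (two groups)")
        if len(self.feature_names) != self.x.shape[1]:
            raise ValueError("feature_names length mismatch")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(self.x.shape[0])]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        rows = np.arange(self.x.shape[0]) if rows is None else np.asarray(rows)
        cols = np.arange(self.x.shape[1]) if cols is None else np.asarray(cols)
        return FeatureTable(
            self.x[np.ix_(rows, cols)],
            self.y[rows],
            [self.feature_names[c] for c in cols],
            [self.subject_ids[r] for r in rows],
            self.threshold,
        )

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame, threshold: float) -> "FeatureTable":
        """Per-threshold feature vectors (Q, QGD, QLD, QDB, QNM)."""
        sub = metrics[metrics["threshold"] == threshold]
        if sub.empty:
            raise ValueError(f"no rows at threshold {threshold}")
        return cls(
            sub[list(METRIC_NAMES)].to_numpy(),
            sub["group"].to_numpy(),
            list(METRIC_NAMES),
            [str(s) for s in sub["subject_id"]],
            threshold,
        )

    @classmethod
    def from_metrics_concat(cls, metrics: pd.DataFrame) -> "FeatureTable":
        """Features concatenated across all thresholds (5 x n_thresholds columns)."""
        thresholds = sorted(metrics["threshold"].unique())
        wide = metrics.pivot_table(
            index=["subject_id", "group"], columns="threshold",
            values=list(METRIC_NAMES), sort=True,
        )
        names = [f"{m}@{t:g}" for m in METRIC_NAMES for t in thresholds]
        idx = wide.index
        return cls(
            wide.to_numpy(), idx.get_level_values("group").to_numpy(),
            names, [str(s) for s in idx.get_level_values("subject_id")],
            tuple(thresholds),
        )


@dataclass(frozen=True)
class LdaModel:
    """Gaussian class-conditional model with shared pooled covariance."""

    classes: tuple
    means: np.ndarray  # (2, p)
    covariance: np.ndarray  # (p, p)
    priors: np.ndarray  # (2,)
    ridge: float = 0.0


@dataclass
class ClassificationReport:
    scheme: str
    classifier: str
    accuracy: float
    precision: float
    recall: float
    fold_confusions: list[dict]
    seed: int
    threshold: float | tuple[float, ...] = float("nan")

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "classifier": self.classifier,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "fold_confusions": self.fold_confusions,
            "seed": self.seed,
            "threshold": list(self.threshold) if isinstance(self.threshold, tuple)
            else self.threshold,
        }


@dataclass(frozen=True)
class RfeRanking:
    scores: dict[str, float]
    elimination_order: list[list[str]]  # per outer fold, first-eliminated first
    seed: int

    def to_dict(self) -> dict:
        return {"scores": self.scores, "elimination_order": self.elimination_order,
                "seed": self.seed}


def lda_fit(features: FeatureTable, ridge_lambda: float = 1e-6) -> LdaModel:
    """Estimate class means, shared pooled covariance and empirical priors.

    If the pooled covariance is near-singular (condition number > 1e12) a
    ridge ``lambda * trace(S)/p`` is added and recorded on the model.
    """
    x, y = features.x, features.y
    classes = tuple(np.unique(y))
    p = x.shape[1]
    means, priors, scatter = [], [], np.zeros((p, p))
    for c in classes:
        xc = x[y == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        mu = xc.mean(axis=0)
        means.append(mu)
        priors.append(xc.shape[0] / x.shape[0])
        scatter += (xc - mu).T @ (xc - mu)
    cov = scatter / (x.shape[0] - len(classes))
    ridge = 0.0
    if np.linalg.cond(cov) > 1e12:
        ridge = ridge_lambda * np.trace(cov) / p
        if ridge == 0.0:  # all-zero covariance
            ridge = ridge_lambda
        cov = cov + ridge * np.eye(p)
        logger.info("singular pooled covariance; ridge %.3e applied", ridge)
    return LdaModel(classes, np.vstack(means), cov, np.asarray(priors), ridge)


def lda_predict(model: LdaModel, x: np.ndarray):
    """Posterior class probabilities by Bayes' rule and the MAP label.

    With the shared covariance, the Gaussian normalizing constant cancels;
    posteriors are the softmax of log prior - Mahalanobis/2.  An exact
    posterior tie resolves to the lower class id.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    p = model.means.shape[1]
    if x.shape[1] != p:
        raise ValueError(f"expected {p} features, got {x.shape[1]}")
    cov_inv = np.linalg.inv(model.covariance)
    log_post = np.empty((x.shape[0], len(model.classes)))
    for k, mu in enumerate(model.means):
        d = x - mu
        log_post[:, k] = np.log(model.priors[k]) - 0.5 * np.einsum(
            "ij,jk,ik->i", d, cov_inv, d)
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    best = np.argmax(post, axis=1)  # argmax takes the lower index on ties
    labels = np.asarray(model.classes)[best]
    if labels.shape[0] == 1:
        return labels[0], post[0]
    return labels, post


def knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, x: np.ndarray, k: int = 5
):
    """Majority vote among the k nearest training points (Euclidean).

    Callers are expected to pass standardized features.  A vote tie goes to
    the label of the single nearest neighbour; distance ties resolve to the
    lower training index (stable sort).
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y)
    if not (1 <= k <= train_x.shape[0]):
        raise ValueError(f"k={k} invalid for training size {train_x.shape[0]}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = []
    for row in x:
        dist = np.linalg.norm(train_x - row, axis=1)
        order = np.argsort(dist, kind="stable")[:k]
        votes = train_y[order]
        vals, counts = np.unique(votes, return_counts=True)
        winners = vals[counts == counts.max()]
        out.append(votes[0] if len(winners) > 1 else winners[0])
    return out[0] if len(out) == 1 else np.asarray(out)


def performance(y_true, y_pred, positive_class: str = POSITIVE_CLASS):
    """(accuracy %, precision %, recall %) with the case group positive.

    Zero predicted positives yields precision 0 (flagged in the log);
    likewise recall when no actual positives exist.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and predictions")
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    acc = 100.0 * np.mean(y_true == y_pred)
    if tp + fp == 0:
        logger.info("no predicted positives; precision defined as 0")
        prec = 0.0
    else:
        prec = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no actual positives; recall defined as 0")
        rec = 0.0
    else:
        rec = 100.0 * tp / (tp + fn)
    return float(acc), float(prec), float(rec)


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified folds: per-class shuffle, round-robin deal."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def _fit_predict(train: FeatureTable, test_x: np.ndarray, classifier: str, k: int):
    if classifier == "lda":
        model = lda_fit(train)
        labels, _ = lda_predict(model, test_x)
        return np.atleast_1d(labels)
    if classifier == "knn":
        mu = train.x.mean(axis=0)
        sd = train.x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return np.atleast_1d(
            knn_predict((train.x - mu) / sd, train.y, (test_x - mu) / sd, k)
        )
    raise ValueError(f"unknown classifier {classifier!r}")


def cross_validate(
    features: FeatureTable,
    classifier: str = "lda",
    scheme: str = "loo",
    seed: int = 0,
    k_neighbors: int = 5,
    n_folds: int = 10,
) -> ClassificationReport:
    """LOO or stratified k-fold cross-validation with pooled performance.

    Standardization (for KNN) is fitted on the training folds only; the
    test fold never influences the trained model.  Aggregate accuracy /
    precision / recall are pooled over all held-out predictions.
    """
    n = features.x.shape[0]
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        counts = np.bincount(np.unique(features.y, return_inverse=True)[1])
        if counts.min() < n_folds:
            raise ValueError(
                f"stratified {n_folds}-fold needs >= {n_folds} subjects per class"
            )
        folds = stratified_folds(features.y, n_folds, seed)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    y_pred = np.empty(n, dtype=features.y.dtype)
    fold_confusions = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train = features.subset(train_idx)
        pred = _fit_predict(train, features.x[test_idx], classifier, k_neighbors)
        y_pred[test_idx] = pred
        yt = features.y[test_idx]
        fold_confusions.append({
            "fold": f,
            "tp": int(np.sum((yt == POSITIVE_CLASS) & (pred == POSITIVE_CLASS))),
            "fp": int(np.sum((yt != POSITIVE_CLASS) & (pred == POSITIVE_CLASS))),
            "fn": int(np.sum((yt == POSITIVE_CLASS) & (pred != POSITIVE_CLASS))),
            "tn": int(np.sum((yt != POSITIVE_CLASS) & (pred != POSITIVE_CLASS))),
        })
    acc, prec, rec = performance(features.y, y_pred)
    return ClassificationReport(
        scheme, classifier, acc, prec, rec, fold_confusions, seed, features.threshold
    )


def _cv_accuracy(features: FeatureTable, classifier: str, seed: int, k: int) -> float:
    """Inner evaluation for RFE: stratified 3-fold accuracy (LOO if tiny)."""
    counts = np.bincount(np.unique(features.y, return_inverse=True)[1])
    n_folds = min(3, int(counts.min()))
    if n_folds < 2:
        raise ValueError("inner CV needs >= 2 subjects per class")
    folds = stratified_folds(features.y, n_folds, seed)
    n = features.x.shape[0]
    correct = 0
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        pred = _fit_predict(
            features.subset(train_idx), features.x[test_idx], classifier, k
        )
        correct += int(np.sum(pred == features.y[test_idx]))
    return correct / n


def _univariate_separation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|standardized mean difference| per feature; RFE's tie-break key."""
    classes = np.unique(y)
    a, b = x[y == classes[0]], x[y == classes[1]]
    pooled = np.sqrt((a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)) / 2)
    pooled[pooled == 0] = 1.0
    return np.abs(a.mean(axis=0) - b.mean(axis=0)) / pooled


def rfe_rank(
    features: FeatureTable,
    classifier: str = "lda",
    seed: int = 0,
    n_outer_folds: int = 10,
    k_neighbors: int = 5,
) -> RfeRanking:
    """Recursive feature elimination with fold-averaged importance scores.

    Within each outer stratified fold's training data, the feature whose
    removal yields the highest inner-CV accuracy is eliminated (ties to the
    lower feature index) until one feature remains.  A feature eliminated
    at position i (1-based) in a p-feature table has rank p - i + 1; its
    score is the fold-mean of (p - rank)/(p - 1), so the last survivor
    scores 1 and the first casualty 0.
    """
    p = features.x.shape[1]
    names = features.feature_names
    if p == 1:
        return RfeRanking({names[0]: 1.0}, [], seed)
    counts = np.bincount(np.unique(features.y, return_inverse=True)[1])
    n_outer = min(n_outer_folds, int(counts.min()))
    if n_outer < 2:
        raise ValueError("RFE needs >= 2 subjects per class")
    folds = stratified_folds(features.y, n_outer, seed)
    n = features.x.shape[0]
    rank_sums = np.zeros(p)
    orders = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        separation = _univariate_separation(features.x[train_idx], features.y[train_idx])
        remaining = list(range(p))
        eliminated: list[int] = []
        while len(remaining) > 1:
            accs = {
                feat: _cv_accuracy(
                    features.subset(train_idx, [c for c in remaining if c != feat]),
                    classifier, seed + f, k_neighbors,
                )
                for feat in remaining
            }
            best_acc = max(accs.values())
            # ties: drop the candidate with the weakest univariate group
            # separation (content-based, so column order never matters)
            tied = [feat for feat, a in accs.items() if a > best_acc - 1e-12]
            best_feat = min(tied, key=lambda feat: separation[feat])
            remaining.remove(best_feat)
            eliminated.append(best_feat)
        ranks = np.empty(p)
        for i, feat in enumerate(eliminated):  # i=0 first eliminated -> rank p
            ranks[feat] = p - i
        ranks[remaining[0]] = 1
        rank_sums += ranks
        orders.append([names[i] for i in eliminated + remaining])
    mean_ranks = rank_sums / len(folds)
    scores = {names[i]: float((p - mean_ranks[i]) / (p - 1)) for i in range(p)}
    return RfeRanking(scores, orders, seed)
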