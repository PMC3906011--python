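"""Discriminative classification in the generative score space.

Two classifiers, matching the study design: a K-nearest-neighbor rule with
K = 3 (Euclidean metric, deterministic tie handling: distance ties resolve
to the lower sample index, vote ties to the class of the nearest neighbor)
and a linear support-vector machine with a fixed regularization constant.
The score-space features are unnormalized probabilities (spread well below
one), so the hinge loss must outweigh the margin penalty for the SVM to
fit at all; the default C = 100 reflects that scale, and with it the
hard-margin solution is recovered on separable toys.
Evaluation is leave-one-out cross-validation; the scalar
accuracy is the unweighted mean of the per-class recalls.  "Separation"
performance is resubstitution — training and evaluating on the same
samples — which measures how cleanly the classes can be divided, not how
well the rule generalizes; for K-NN the query sample is excluded from its
own neighbor search so the score is not trivially perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import svm as _svm

__all__ = [
    "EvaluationReport",
    "knn_predict",
    "linear_svm",
    "loo_evaluate",
    "separation_evaluate",
    "accuracy_curve",
    "decision_boundary_grid",
    "knn_loo_mean_recall",
]


@dataclass
class EvaluationReport:
    """Per-class precision/recall plus the pooled per-fold predictions."""

    classifier: str
    mode: str  # 'loo' | 'resubstitution'
    classes: tuple
    precision: dict
    recall: dict
    mean_recall: float
    predictions: np.ndarray
    true_labels: np.ndarray
    feature_subset: tuple = ()

    def recompute_metrics(self) -> tuple[dict, dict, float]:
        """Re-derive the metrics from the stored predictions (self-audit)."""
        return _metrics(self.true_labels, self.predictions, self.classes)


def _metrics(y: np.ndarray, pred: np.ndarray, classes) -> tuple[dict, dict, float]:
    precision, recall = {}, {}
    for c in classes:
        predicted_c = pred == c
        actual_c = y == c
        precision[c] = float(np.mean(y[predicted_c] == c)) if predicted_c.any() else 0.0
        recall[c] = float(np.mean(pred[actual_c] == c)) if actual_c.any() else 0.0
    mean_recall = float(np.mean([recall[c] for c in classes]))
    return precision, recall, mean_recall


def knn_predict(train_points: np.ndarray, train_labels: np.ndarray, query: np.ndarray, K: int = 3):
    """Majority label among the K Euclidean-nearest training points.

    Distance ties resolve to the lower training-sample index (stable sort);
    vote ties resolve to the class of the single nearest neighbor.  Accepts
    a single query vector or a 2-D array of queries.
    """
    X = np.asarray(train_points, dtype=float)
    y = np.asarray(train_labels)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the {X.shape[0]} training points")
    q = np.asarray(query, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    d2 = ((q[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")[:, :K]
    out = np.empty(q.shape[0], dtype=y.dtype)
    for i in range(q.shape[0]):
        votes = y[order[i]]
        classes, counts = np.unique(votes, return_counts=True)
        top = counts == counts.max()
        if top.sum() == 1:
            out[i] = classes[np.argmax(counts)]
        else:
            out[i] = votes[0]  # vote tie: nearest neighbor decides
    return out[0] if single else out


def linear_svm(train_points: np.ndarray, train_labels: np.ndarray, C: float = 100.0):
    """Fit a maximum-margin linear separator (sklearn SVC, linear kernel)."""
    y = np.asarray(train_labels)
    if np.unique(y).size < 2:
        raise ValueError("linear SVM needs both classes present")
    clf = _svm.SVC(kernel="linear", C=C)
    clf.fit(np.asarray(train_points, dtype=float), y)
    return clf


def _predict(classifier: str, Xtr, ytr, Xte, K: int, svm_C: float):
    if classifier == "knn":
        return np.atleast_1d(knn_predict(Xtr, ytr, Xte, K=K))
    if classifier == "svm":
        return linear_svm(Xtr, ytr, C=svm_C).predict(np.atleast_2d(Xte))
    raise ValueError(f"unknown classifier '{classifier}'")


def _subset(X: np.ndarray, feature_subset) -> np.ndarray:
    if feature_subset is None:
        return X
    return X[:, list(feature_subset)]


def loo_evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    feature_subset=None,
    classifier: str = "knn",
    K: int = 3,
    svm_C: float = 100.0,
) -> EvaluationReport:
    """Leave-one-out evaluation: n folds, each sample predicted by a model
    trained on the other n-1; metrics pooled over folds."""
    X = _subset(np.asarray(scores, dtype=float), feature_subset)
    y = np.asarray(labels)
    classes = tuple(np.unique(y))
    if any(np.sum(y == c) < 2 for c in classes) or len(classes) < 2:
        raise ValueError("need at least two samples of each of two classes")
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.arange(n) != i
        pred[i] = _predict(classifier, X[mask], y[mask], X[i], K, svm_C)[0]
    precision, recall, mean_recall = _metrics(y, pred, classes)
    return EvaluationReport(
        classifier=classifier,
        mode="loo",
        classes=classes,
        precision=precision,
        recall=recall,
        mean_recall=mean_recall,
        predictions=pred,
        true_labels=y,
        feature_subset=tuple(feature_subset) if feature_subset is not None else (),
    )


def separation_evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    feature_subset=None,
    classifier: str = "knn",
    K: int = 3,
    svm_C: float = 100.0,
) -> EvaluationReport:
    """Resubstitution: train on all samples, evaluate on the same samples.

    Reported separately from LOO, never conflated.  For K-NN the query is
    excluded from its own neighbor search (a sample trivially matching
    itself would make the score meaningless).
    """
    X = _subset(np.asarray(scores, dtype=float), feature_subset)
    y = np.asarray(labels)
    classes = tuple(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need two classes")
    n = len(y)
    if classifier == "knn":
        pred = np.empty(n, dtype=y.dtype)
        for i in range(n):
            mask = np.arange(n) != i  # self-match excluded
            pred[i] = knn_predict(X[mask], y[mask], X[i], K=K)
    else:
        pred = _predict(classifier, X, y, X, K, svm_C)
    precision, recall, mean_recall = _metrics(y, pred, classes)
    return EvaluationReport(
        classifier=classifier,
        mode="resubstitution",
        classes=classes,
        precision=precision,
        recall=recall,
        mean_recall=mean_recall,
        predictions=pred,
        true_labels=y,
        feature_subset=tuple(feature_subset) if feature_subset is not None else (),
    )


def accuracy_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    ranking,
    k_max: int,
    classifiers=("knn", "svm"),
    K: int = 3,
    svm_C: float = 100.0,
) -> dict:
    """LOO mean recall using the top-k ranked features, for k = 1..k_max.

    ``ranking`` is an ordered sequence of feature indices (best first), or
    an object with an ``order`` attribute.
    """
    order = list(getattr(ranking, "order", ranking))
    if k_max > len(order):
        raise ValueError("k_max exceeds the number of ranked features")
    out = {}
    for clf in classifiers:
        out[clf] = np.array(
            [
                loo_evaluate(scores, labels, order[:k], clf, K=K, svm_C=svm_C).mean_recall
                for k in range(1, k_max + 1)
            ]
        )
    return out


@dataclass
class BoundaryGrid:
    """A labeled rectangular grid over a 2-D feature space."""

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray  # (resolution, resolution), [i, j] -> (x[j], y[i])
    classifier: str = ""


def decision_boundary_grid(
    scores_2d: np.ndarray,
    labels: np.ndarray,
    classifier: str = "knn",
    resolution: int = 50,
    margin: float = 0.1,
    K: int = 3,
    svm_C: float = 100.0,
) -> BoundaryGrid:
    """Classify every node of a grid spanning the data range +/- 10%.

    The implied decision boundary is the set of grid edges across which the
    label changes.  The grid has ``resolution**2`` nodes.
    """
    X = np.asarray(scores_2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("decision_boundary_grid needs exactly 2 features")
    y = np.asarray(labels)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo, hi = lo - margin * span, hi + margin * span
    gx = np.linspace(lo[0], hi[0], resolution)
    gy = np.linspace(lo[1], hi[1], resolution)
    nodes = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    pred = _predict(classifier, X, y, nodes, K, svm_C)
    return BoundaryGrid(x=gx, y=gy, labels=pred.reshape(resolution, resolution), classifier=classifier)


def _binary_codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("expected exactly two classes")
    return (labels == classes[1]).astype(np.int8), classes


def knn_loo_mean_recall(X: np.ndarray, y: np.ndarray, K: int = 3) -> float:
    """Fast vectorized LOO mean recall of the K-NN rule (two classes)."""
    codes, _ = _binary_codes(np.asarray(y))
    X = np.asarray(X, dtype=float)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    return float(_loo_knn_mean_recall_from_d2(d2[None], codes, K)[0])


def _loo_knn_mean_recall_from_d2(D: np.ndarray, codes: np.ndarray, K: int) -> np.ndarray:
    """LOO K-NN mean recall for a batch of (n, n) squared-distance matrices.

    ``D`` has shape (..., n, n); the diagonal (self-distance) is excluded.
    Binary class codes and odd K make vote ties impossible; distance ties
    resolve to the lower index via the stable argsort, matching
    ``knn_predict``.
    """
    n = D.shape[-1]
    Dm = D.copy()
    idx = np.arange(n)
    Dm[..., idx, idx] = np.inf
    nbr = np.argsort(Dm, axis=-1, kind="stable")[..., :K]
    votes = codes[nbr].sum(axis=-1)
    pred = (2 * votes > K).astype(np.int8)
    mask1 = codes == 1
    r1 = pred[..., mask1].mean(axis=-1)
    r0 = 1.0 - pred[..., ~mask1].mean(axis=-1)
    return (r0 + r1) / 2.0
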