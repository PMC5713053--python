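"""Spectral regression discriminant analysis (SRDA) and evaluation metrics.

SRDA recasts linear discriminant analysis as regression: the class
structure is encoded as c-1 response vectors obtained by Gram-Schmidt
orthogonalization of the class-membership indicator vectors against the
constant vector, and each response is regressed on the centered feature
matrix with a ridge penalty,

    min_w ||X_c w - y_k||^2 + alpha ||w||^2 .

The resulting projection spans the LDA discriminant subspace without
any dense eigendecomposition; classification assigns the nearest class
centroid (Euclidean) in the projected space, ties going to the smaller
class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.metrics import cohen_kappa_score, confusion_matrix

__all__ = ["SRDAModel", "Metrics", "fit_srda", "predict_srda", "evaluate", "f_measure"]


@dataclass
class SRDAModel:
    projection: np.ndarray  # (D, n_classes - 1)
    class_centroids: np.ndarray  # (n_classes, n_classes - 1)
    classes: np.ndarray
    feature_mean: np.ndarray
    regularization: float

    @property
    def training_feature_count(self) -> int:
        return self.projection.shape[0]


@dataclass
class Metrics:
    """Multi-class agreement summary: accuracy, Cohen's kappa, per-class
    precision/recall/F-measure and the confusion matrix (rows = truth)."""

    accuracy: float
    kappa: float
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    confusion: np.ndarray
    undefined_rates: int = 0  # count of P/R cells with a zero denominator


def _response_vectors(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Orthonormal class responses: Gram-Schmidt of indicator vectors
    against the constant vector, dropping the (spanned) last one."""
    n = labels.size
    basis = [np.ones(n) / np.sqrt(n)]
    responses = []
    for k in classes:
        v = (labels == k).astype(float)
        for b in basis:
            v = v - (v @ b) * b
        nrm = np.linalg.norm(v)
        if nrm > 1e-12:
            v /= nrm
            basis.append(v)
            responses.append(v)
    # indicators + constant are linearly dependent -> c-1 usable responses
    return np.column_stack(responses[: classes.size - 1])


def fit_srda(
    features: np.ndarray, labels: np.ndarray, alpha: float = 0.01
) -> SRDAModel:
    """Fit an SRDA model by ridge-regularized least squares.

    ``alpha`` is the ridge coefficient; the small default keeps the
    normal equations well conditioned when features outnumber trials, as
    they do for fused EEG feature vectors.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if x.ndim != 2:
        raise ValueError("features must be a 2-D trials x D matrix")
    if x.shape[0] != y.size:
        raise ValueError("one label per trial required")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a discriminant")
    if np.min(counts) < 2:
        raise ValueError("need at least 2 trials per class")
    mean = x.mean(axis=0)
    xc = x - mean
    resp = _response_vectors(y, classes)
    d = x.shape[1]
    # normal equations with ridge; D x D solve (D <= a few hundred here)
    gram = xc.T @ xc + alpha * np.eye(d)
    proj = linalg.solve(gram, xc.T @ resp, assume_a="pos")
    embedded = xc @ proj
    centroids = np.vstack([embedded[y == k].mean(axis=0) for k in classes])
    return SRDAModel(proj, centroids, classes, mean, float(alpha))


def predict_srda(model: SRDAModel, features: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment in the discriminant space."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.training_feature_count:
        raise ValueError(
            f"expected {model.training_feature_count} features, got {x.shape[1]}"
        )
    z = (x - model.feature_mean) @ model.projection
    # squared distances to centroids; argmin takes the first (= smallest
    # class index) on exact ties
    d2 = ((z[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
    return model.classes[np.argmin(d2, axis=1)]


def evaluate(
    true_labels: np.ndarray, pred_labels: np.ndarray, n_classes: int = 4
) -> Metrics:
    """Accuracy, Cohen's kappa and per-class precision/recall/F-measure.

    Zero-denominator precision or recall cells (a class never predicted,
    or absent from the truth) are reported as 0 and counted in
    ``undefined_rates``.
    """
    y_t = np.asarray(true_labels).ravel()
    y_p = np.asarray(pred_labels).ravel()
    if y_t.size == 0 or y_t.size != y_p.size:
        raise ValueError("label vectors must be non-empty and equal-length")
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_t, y_p, labels=labels)
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    undefined = int(np.sum(pred_tot == 0) + np.sum(true_tot == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
        recall = np.where(true_tot > 0, tp / np.maximum(true_tot, 1), 0.0)
    pr = precision + recall
    f = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    acc = float(tp.sum() / cm.sum())
    kappa = float(cohen_kappa_score(y_t, y_p, labels=labels))
    return Metrics(acc, kappa, precision, recall, f, cm, undefined)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both rates vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
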