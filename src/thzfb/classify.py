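"""KNN and PLS-DA classifiers with calibration/prediction accounting.

Both classifiers are written from first principles so that every
numeric choice (distance, vote tie-breaks, latent-variable extraction,
response threshold, accuracy rounding) is explicit and testable.

* KNN: lazy learner; a query takes the majority vote among its k
  Euclidean-nearest training samples.  Vote ties are broken by the
  nearest neighbour among the tied classes, then by the lowest class
  index — a fixed deterministic rule.
* PLS-DA: the two classes are dummy-coded 0/1 and a univariate partial
  least squares regression is fit on mean-centred features; the class
  cut is at a predicted response of 0.5 (exactly 0.5 goes to class 0).
  Features are centred but not variance-scaled: the absolute amplitude
  level is itself the discriminative signal.

Accuracies are reported the way detection tables print them:
100 * (1 - misclassified / n), rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError, RankDeficiencyError
from .spectra import LabeledSpectralSet


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

@dataclass
class KNNModel:
    training_features: np.ndarray
    training_labels: np.ndarray
    k: int


def knn_fit(features: np.ndarray, labels: np.ndarray, k: int = 3) -> KNNModel:
    """Store the training data verbatim (KNN has no training stage)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise InvalidArgumentError("features must be a 2-D matrix")
    if labels.size != features.shape[0]:
        raise InvalidArgumentError("one label per training row required")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > features.shape[0]:
        raise InvalidArgumentError(
            f"k = {k} exceeds the number of training rows ({features.shape[0]})"
        )
    return KNNModel(training_features=features, training_labels=labels, k=int(k))


def knn_predict(model: KNNModel, queries: np.ndarray) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training rows."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.training_features.shape[1]:
        raise InvalidArgumentError(
            f"query dimension {queries.shape[1]} does not match training "
            f"dimension {model.training_features.shape[1]}"
        )
    distances = cdist(queries, model.training_features)
    classes = np.unique(model.training_labels)
    out = np.empty(queries.shape[0], dtype=classes.dtype)
    for i, row in enumerate(distances):
        order = np.argsort(row, kind="stable")[: model.k]
        votes = model.training_labels[order]
        counts = {c: 0 for c in classes}
        for v in votes:
            counts[v] += 1
        best = max(counts.values())
        tied = [c for c in classes if counts[c] == best]
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            # nearest neighbour among tied classes, then lowest class index
            first_rank = {c: int(np.nonzero(votes == c)[0][0]) for c in tied}
            out[i] = min(tied, key=lambda c: (first_rank[c], c))
    return out


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray   # (p, a) weight vectors
    x_loadings: np.ndarray  # (p, a) loadings
    y_loadings: np.ndarray  # (a,) response loadings
    coefficients: np.ndarray
    threshold: float
    classes: np.ndarray
    metadata: dict = _field(default_factory=dict)


def plsda_fit(
    features: np.ndarray, labels: np.ndarray, n_components: int = 2
) -> PLSDAModel:
    """Fit a two-class PLS-DA model.

    The sorted class values are dummy-coded 0/1; latent components are
    extracted sequentially (weight vector = dominant covariance
    direction between the residual features and residual response,
    then score/loading deflation), yielding the regression vector
    b = W (P^T W)^-1 q on centred data.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2:
        raise InvalidArgumentError("features must be a 2-D matrix")
    if labels.size != x.shape[0]:
        raise InvalidArgumentError("one label per row required")
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidArgumentError(
            f"PLS-DA requires exactly two classes, found {classes.size}"
        )
    if n_components < 1:
        raise InvalidArgumentError("n_components must be >= 1")
    y = (labels == classes[1]).astype(float)
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xr = x - x_mean
    yr = y - y_mean
    rank = np.linalg.matrix_rank(xr)
    if n_components > rank:
        raise RankDeficiencyError(
            f"n_components = {n_components} exceeds the centred feature rank {rank}"
        )
    n, p = xr.shape
    w_mat = np.zeros((p, n_components))
    p_mat = np.zeros((p, n_components))
    q_vec = np.zeros(n_components)
    tiny = np.finfo(float).eps * max(n, p)
    for a in range(n_components):
        w = xr.T @ yr
        norm_w = np.linalg.norm(w)
        if norm_w <= tiny:
            raise RankDeficiencyError(
                f"response residual exhausted after {a} components"
            )
        w /= norm_w
        t = xr @ w
        tt = float(t @ t)
        if tt <= tiny:
            raise RankDeficiencyError(f"degenerate score vector at component {a + 1}")
        p_a = xr.T @ t / tt
        q_a = float(yr @ t) / tt
        xr = xr - np.outer(t, p_a)
        yr = yr - q_a * t
        w_mat[:, a] = w
        p_mat[:, a] = p_a
        q_vec[a] = q_a
    coefficients = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PLSDAModel(
        n_components=int(n_components),
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        coefficients=coefficients,
        threshold=0.5,
        classes=classes,
    )


def plsda_response(model: PLSDAModel, queries: np.ndarray) -> np.ndarray:
    """Continuous predicted response of the dummy-coded regression."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.x_mean.size:
        raise InvalidArgumentError(
            f"query dimension {queries.shape[1]} does not match training "
            f"dimension {model.x_mean.size}"
        )
    return (queries - model.x_mean) @ model.coefficients + model.y_mean


def plsda_predict(model: PLSDAModel, queries: np.ndarray) -> np.ndarray:
    """Class assignment: class 1 iff response > threshold (ties -> class 0)."""
    response = plsda_response(model, queries)
    return np.where(response > model.threshold, model.classes[1], model.classes[0])


def _stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Round-robin stratified fold assignment with a seeded shuffle."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % n_folds
    return [np.nonzero(fold_of == f)[0] for f in range(n_folds)]


def select_n_components(
    features: np.ndarray,
    labels: np.ndarray,
    max_components: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the PLS-DA component count by stratified cross-validation.

    Component counts 1..max_components (capped at the feature rank)
    are scored by CV accuracy; the smallest count achieving the best
    accuracy wins, which keeps the model as parsimonious as possible.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    cap = min(max_components, np.linalg.matrix_rank(x - x.mean(axis=0)), x.shape[0] - 1)
    if cap < 1:
        raise RankDeficiencyError("no usable latent components")
    folds = _stratified_folds(labels, n_folds, seed)
    best_a, best_acc = 1, -1.0
    for a in range(1, cap + 1):
        correct = 0
        total = 0
        usable = True
        for test_idx in folds:
            if test_idx.size == 0:
                continue
            train_mask = np.ones(labels.size, dtype=bool)
            train_mask[test_idx] = False
            try:
                model = plsda_fit(x[train_mask], labels[train_mask], a)
            except RankDeficiencyError:
                usable = False
                break
            pred = plsda_predict(model, x[test_idx])
            correct += int(np.sum(pred == labels[test_idx]))
            total += test_idx.size
        if not usable or total == 0:
            continue
        acc = correct / total
        if acc > best_acc + 1e-12:
            best_a, best_acc = a, acc
    return best_a


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def accuracy_percent(n_misclassified: int, n: int) -> float:
    """100 * (1 - misclassified/n), rounded half-up to two decimals."""
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    if not 0 <= n_misclassified <= n:
        raise InvalidArgumentError("misclassified count must lie in [0, n]")
    exact = Decimal(100) * Decimal(n - n_misclassified) / Decimal(n)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Detection-table style accounting for one model on one dataset."""

    n_misclassified_calibration: int
    accuracy_calibration: float
    n_misclassified_prediction: int
    accuracy_prediction: float
    confusion_calibration: np.ndarray
    confusion_prediction: np.ndarray


def _predict(model, features: np.ndarray) -> np.ndarray:
    if isinstance(model, KNNModel):
        return knn_predict(model, features)
    if isinstance(model, PLSDAModel):
        return plsda_predict(model, features)
    raise InvalidArgumentError(f"unsupported model type {type(model).__name__}")


def _confusion(truth: np.ndarray, pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    table = np.zeros((classes.size, classes.size), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            table[i, j] = int(np.sum((truth == ci) & (pred == cj)))
    return table


def evaluate(model, data: LabeledSpectralSet) -> EvaluationReport:
    """Misclassification counts and rounded accuracies per split.

    The model predicts both the calibration and the held-out
    prediction population of ``data``; each split must be non-empty.
    """
    classes = np.unique(data.labels)
    results = {}
    for name, mask in (
        ("calibration", data.calibration_mask),
        ("prediction", data.prediction_mask),
    ):
        if not np.any(mask):
            raise InvalidArgumentError(f"{name} split is empty")
        truth = data.labels[mask]
        pred = _predict(model, data.features[mask])
        n_mis = int(np.sum(pred != truth))
        results[name] = (
            n_mis,
            accuracy_percent(n_mis, int(mask.sum())),
            _confusion(truth, pred, classes),
        )
    return EvaluationReport(
        n_misclassified_calibration=results["calibration"][0],
        accuracy_calibration=results["calibration"][1],
        n_misclassified_prediction=results["prediction"][0],
        accuracy_prediction=results["prediction"][1],
        confusion_calibration=results["calibration"][2],
        confusion_prediction=results["prediction"][2],
    )
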