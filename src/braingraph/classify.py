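"""Stage classification from normalized topological-index features.

Feature vectors are the six WS-normalized indices (Sz, ABC, PI, MO, NGG, W)
per image; labels are the four ordered stages 0-3 (Non-, Very Mild, Mild,
Moderate Demented). The pipeline is: SMOTE oversampling of minority classes
(training data only), a stratified 80-20 split or stratified K-fold
cross-validation, one of five classifier families, and a metric suite of
accuracy, support-weighted precision/recall/F1, one-vs-rest macro AUC and
per-fold confusion matrices.

SMOTE synthesizes minority samples by interpolating between a sample and
one of its k nearest same-class neighbors: ``x + lam * (x_nn - x)`` with
``lam ~ U(0, 1)``, so every synthetic point lies on a segment between two
originals. It is applied inside each cross-validation training fold only,
never to validation or test data, to avoid leakage.

Model families: ``tree`` (CART), ``logistic``, ``svm_rbf`` (RBF kernel with
width sigma = 1, i.e. kernel coefficient 1/(2 sigma^2) = 0.5), and two
multilayer perceptrons -- ``nn2`` with hidden layers (64, 32) and ``nn4``
with hidden layers (128, 64, 32, 16) -- trained by an explicit minibatch
loop minimizing categorical cross-entropy, with per-epoch validation-loss
tracking and an L2 penalty as the overfitting control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.model_selection import train_test_split as _sk_split
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "STAGE_NAMES",
    "MODEL_KINDS",
    "EvalReport",
    "CVReport",
    "smote_oversample",
    "train_test_split",
    "rbf_kernel",
    "categorical_cross_entropy",
    "fit_predict",
    "evaluate",
    "cross_validate",
]

FEATURE_NAMES = ("Sz", "ABC", "PI", "MO", "NGG", "W")
STAGE_NAMES = ("NonDemented", "VeryMildDemented", "MildDemented", "ModerateDemented")
MODEL_KINDS = ("tree", "logistic", "svm_rbf", "nn2", "nn4")

_NN_HIDDEN = {"nn2": (64, 32), "nn4": (128, 64, 32, 16)}


@dataclass
class EvalReport:
    """Metrics of one evaluation (one fold or one test set)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    confusion: np.ndarray
    loss_curve: list | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
        }
        if self.loss_curve is not None:
            d["loss_curve"] = list(self.loss_curve)
        return d


@dataclass
class CVReport:
    """Per-fold reports plus their metric means."""

    folds: list
    mean: dict

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds], "mean": self.mean}


def smote_oversample(X, y, k_neighbors: int = 5, rng=None):
    """Balance classes by synthetic-minority oversampling.

    Every class below the majority count is augmented with interpolated
    samples until all counts match the majority; originals are retained and
    appear first in the output. Already-balanced input is returned
    unchanged. A minority class with a single member cannot be interpolated
    and raises an error naming the class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return X.copy(), y.copy()
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = target - cnt
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has a single member; SMOTE needs at least 2"
            )
        Xc = X[y == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(cnt, size=need)
        pick = rng.integers(1, k + 1, size=need)
        lam = rng.random(need)
        x0 = Xc[base]
        x1 = Xc[idx[base, pick]]
        new_X.append(x0 + lam[:, None] * (x1 - x0))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def train_test_split(X, y, test_fraction: float = 0.2, rng=None):
    """Stratified, seeded train/test split (default 80-20).

    The test partition is meant to stay untouched by oversampling. Every
    class needs at least 5 records so stratification is well defined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 records to split")
    seed = int(np.random.default_rng(rng).integers(2**31)) if not isinstance(rng, int) else rng
    Xtr, Xte, ytr, yte = _sk_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    return (Xtr, ytr), (Xte, yte)


def rbf_kernel(x, x2, sigma: float = 1.0) -> float:
    """Gaussian similarity ``exp(-||x - x'||^2 / (2 sigma^2))``, in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValueError("feature vectors must have equal length")
    return float(np.exp(-np.sum((x - x2) ** 2) / (2.0 * sigma**2)))


def categorical_cross_entropy(y_onehot, y_pred, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy ``-sum_i y_i log(y'_i)`` over rows.

    ``y_onehot`` is a one-hot matrix (or a single vector); ``y_pred`` rows
    must be probability vectors. Zero predicted probability for the true
    class is clipped at ``eps`` and logged rather than propagating -inf.
    """
    Y = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    P = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if Y.shape != P.shape:
        raise ValueError("shapes of targets and predictions must match")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("predictions must be row-stochastic")
    true_p = (Y * P).sum(axis=1)
    if np.any(true_p < eps):
        logger.warning("clipping %d zero probabilities in cross-entropy", int((true_p < eps).sum()))
        true_p = np.clip(true_p, eps, None)
    return float(-np.log(true_p).mean())


def _one_hot(y, classes) -> np.ndarray:
    pos = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((len(y), len(classes)))
    for i, c in enumerate(y):
        Y[i, pos[c]] = 1.0
    return Y


def _fit_nn(X, y, hidden, epochs, batch_size, seed, X_val=None, y_val=None,
            learning_rate=1e-3, alpha=1e-3):
    """Minibatch training loop for an MLP with per-epoch loss tracking.

    Returns (model, loss_curve); the curve is the categorical cross-entropy
    on the validation set when one is given, else on the training set.
    """
    classes = np.unique(y)
    model = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        alpha=alpha,
        batch_size=batch_size,
        learning_rate_init=learning_rate,
        max_iter=1,
        shuffle=False,
        random_state=seed,
        warm_start=False,
    )
    rng = np.random.default_rng(seed)
    n = len(y)
    losses = []
    Xe, ye = (X_val, y_val) if X_val is not None else (X, y)
    Ye = _one_hot(ye, classes)
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            model.partial_fit(X[sel], y[sel], classes=classes)
        proba = model.predict_proba(Xe)
        losses.append(categorical_cross_entropy(Ye, proba))
    return model, losses


def _standardize(Xtr, Xte):
    """Zero-mean unit-sd scaling fit on the training partition only.

    The indices span orders of magnitude (Wiener vs NGG), so the
    scale-sensitive families (logistic, RBF-kernel SVM with sigma = 1, the
    neural nets) operate on standardized features; trees are scale-invariant
    and skip this.
    """
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _make_model(model_kind: str, seed: int, hyper: dict):
    if model_kind == "tree":
        return DecisionTreeClassifier(random_state=seed, **hyper)
    if model_kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **hyper)
    if model_kind == "svm_rbf":
        sigma = hyper.pop("sigma", 1.0)
        return SVC(
            kernel="rbf",
            gamma=1.0 / (2.0 * sigma**2),
            probability=True,
            random_state=seed,
            **hyper,
        )
    raise ValueError(f"unknown model_kind {model_kind!r}; choose from {MODEL_KINDS}")


def fit_predict(model_kind: str, train, test, hyper: dict | None = None, seed: int = 0):
    """Train one model and predict the test set.

    ``train``/``test`` are ``(X, y)`` pairs (test ``y`` may be None).
    Returns ``(predictions, probabilities, loss_curve)``; the loss curve is
    per-epoch categorical cross-entropy for the neural nets and None for the
    other families. All families are deterministic given ``seed``.
    """
    hyper = dict(hyper or {})
    Xtr, ytr = np.asarray(train[0], dtype=float), np.asarray(train[1])
    Xte = np.asarray(test[0], dtype=float)
    yte = test[1]
    if len(ytr) == 0:
        raise ValueError("empty training set")
    classes = np.unique(ytr)
    if len(classes) == 1:
        # degenerate fit: constant predictor
        pred = np.full(len(Xte), classes[0])
        proba = np.ones((len(Xte), 1))
        return pred, proba, None
    if model_kind in _NN_HIDDEN:
        epochs = int(hyper.pop("epochs", 150))
        batch_size = int(hyper.pop("batch_size", 32))
        Xtr_s, Xte_s = _standardize(Xtr, Xte)
        y_val = np.asarray(yte) if yte is not None else None
        model, losses = _fit_nn(
            Xtr_s, ytr, _NN_HIDDEN[model_kind], epochs,
            min(batch_size, len(ytr)), seed,
            Xte_s if y_val is not None else None, y_val, **hyper,
        )
        return model.predict(Xte_s), model.predict_proba(Xte_s), losses
    model = _make_model(model_kind, seed, hyper)
    if model_kind in ("logistic", "svm_rbf"):
        Xtr, Xte = _standardize(Xtr, Xte)
    model.fit(Xtr, ytr)
    return model.predict(Xte), model.predict_proba(Xte), None


def evaluate(y_true, y_pred, proba=None, labels=(0, 1, 2, 3), loss_curve=None) -> EvalReport:
    """Metric suite for one prediction set.

    Accuracy is correct/total; precision, recall and F1 are support-weighted
    over classes; AUC is one-vs-rest, macro-averaged over the classes
    present in the truth (absent classes are excluded and logged). The
    confusion matrix has one row per stage label, rows indexed by truth.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = list(labels)
    acc = float((y_true == y_pred).mean())
    prec = float(precision_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0))
    rec = float(recall_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0))
    f1 = float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0))
    auc = float("nan")
    if proba is not None:
        proba = np.asarray(proba, dtype=float)
        present = [c for c in labels if np.any(y_true == c)]
        if len(present) < len(labels):
            logger.warning("classes %s absent from truth; excluded from AUC",
                           sorted(set(labels) - set(present)))
        if len(present) == 2:
            col = labels.index(present[1])
            auc = float(roc_auc_score((y_true == present[1]).astype(int), proba[:, col]))
        elif len(present) > 2:
            cols = [labels.index(c) for c in present]
            sub = proba[:, cols]
            sub = sub / sub.sum(axis=1, keepdims=True)
            auc = float(
                roc_auc_score(y_true, sub, multi_class="ovr", average="macro", labels=present)
            )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return EvalReport(accuracy=acc, precision=prec, recall=rec, f1=f1, auc=auc,
                      confusion=cm, loss_curve=loss_curve)


def cross_validate(
    X,
    y,
    model_kind: str = "nn4",
    folds: int = 5,
    hyper: dict | None = None,
    seed: int = 0,
    smote_k: int = 5,
    labels=(0, 1, 2, 3),
) -> CVReport:
    """Stratified K-fold cross-validation with leakage-safe SMOTE.

    Oversampling runs inside each fold on the training partition only; the
    held-out fold is evaluated untouched. Fold assignment, SMOTE and model
    fits are all deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class must have at least as many records as folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for k, (tr, te) in enumerate(skf.split(X, y)):
        fold_rng = np.random.default_rng([seed, k])
        Xb, yb = smote_oversample(X[tr], y[tr], k_neighbors=smote_k, rng=fold_rng)
        pred, proba, losses = fit_predict(
            model_kind, (Xb, yb), (X[te], y[te]), hyper=dict(hyper or {}), seed=seed + k
        )
        reports.append(evaluate(y[te], pred, proba, labels=labels, loss_curve=losses))
    mean = {
        m: float(np.mean([getattr(r, m) for r in reports]))
        for m in ("accuracy", "precision", "recall", "f1", "auc")
    }
    return CVReport(folds=reports, mean=mean)
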