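"""Supervised model comparison and semisupervised self-training.

Labels are category indices 0–7 (see :data:`chatmood.annotation.CATEGORIES`).
Five classifier families are supported (SVM, random forest, Gaussian naive
Bayes, gradient-boosted trees, multilayer perceptron), all exposing class
probabilities over the full 8-category inventory.

The self-training loop is the classic pseudo-labeling scheme: train on the
labeled set, move unlabeled items whose maximum predicted probability
exceeds a confidence threshold (default 0.9, strict) into the training set
with their predicted labels frozen, retrain from scratch, repeat until no
new labels, the pool empties, or an iteration cap.  Evaluation can
optionally be restricted to high-confidence test items (default ≥ 0.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import train_test_split

from .annotation import CATEGORIES

N_CLASSES = len(CATEGORIES)

MODEL_FAMILIES = ("svm", "random_forest", "naive_bayes",
                  "gradient_boosted_trees", "mlp")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class EvalMetrics:
    accuracy: float
    auroc: float
    f1: float
    precision: float
    recall: float
    n_eval: int
    skipped_auroc_classes: tuple[int, ...] = ()


@dataclass
class SelfTrainState:
    iteration: int
    threshold: float
    pseudo_labeled: dict[int, tuple[int, float]]  # pool index → (label, confidence)
    pool_remaining: int
    stop_reason: str | None = None  # no_new_labels | max_iters | pool_empty


class TrainedModel:
    """A fitted estimator plus the label encoding used at fit time; always
    exposes probabilities over all 8 categories."""

    def __init__(self, estimator, fit_classes: np.ndarray) -> None:
        self.estimator = estimator
        self.fit_classes = fit_classes  # original labels, sorted

    def predict_proba(self, X) -> np.ndarray:
        """Per-item probability rows over all 8 categories (rows sum to 1)."""
        raw = self.estimator.predict_proba(X)
        out = np.zeros((raw.shape[0], N_CLASSES), dtype=float)
        out[:, self.fit_classes] = raw
        return out

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "svm":
        from sklearn.svm import SVC
        return SVC(probability=True, random_state=spec.seed,
                   **{"kernel": "rbf", "C": 1.0, **hp})
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=spec.seed,
                                      **{"n_estimators": 200, **hp})
    if spec.family == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB
        return GaussianNB(**hp)
    if spec.family == "gradient_boosted_trees":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=spec.seed, verbosity=0,
                             **{"n_estimators": 100, "max_depth": 4, **hp})
    if spec.family == "mlp":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(random_state=spec.seed,
                             **{"hidden_layer_sizes": (100,), "max_iter": 300, **hp})
    raise ValueError(spec.family)


def fit_model(spec: ModelSpec, X, y) -> TrainedModel:
    """Fit a family's estimator; labels are re-encoded to consecutive ints
    internally so a training set missing some categories still fits."""
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    encoded = np.searchsorted(classes, y)
    est = make_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter is not an error
        est.fit(np.asarray(X), encoded)
    return TrainedModel(est, classes)


def split_train_test(X, y, test_fraction: float = 0.2, seed: int = 0,
                     stratified: bool = True):
    """Disjoint, exhaustive train/test split (stratified by category by
    default); deterministic per seed."""
    y = np.asarray(y, dtype=int)
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("stratified split needs >=2 items per category")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=y if stratified else None)
    return np.sort(tr), np.sort(te)


def evaluate(y_true, proba) -> EvalMetrics:
    """Accuracy, macro one-vs-rest AUROC, macro F1/precision/recall.

    AUROC is averaged over classes present in the evaluation set with both
    positives and negatives; others are skipped and reported.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    y_pred = np.argmax(proba, axis=1)
    aucs, skipped = [], []
    for c in range(N_CLASSES):
        pos = y_true == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos.astype(int), proba[:, c]))
        else:
            skipped.append(c)
    labels = sorted(set(y_true) | set(y_pred))
    return EvalMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        auroc=float(np.mean(aucs)) if aucs else float("nan"),
        f1=float(f1_score(y_true, y_pred, labels=labels, average="macro",
                          zero_division=0)),
        precision=float(precision_score(y_true, y_pred, labels=labels,
                                        average="macro", zero_division=0)),
        recall=float(recall_score(y_true, y_pred, labels=labels,
                                  average="macro", zero_division=0)),
        n_eval=int(y_true.size),
        skipped_auroc_classes=tuple(skipped),
    )


def train_and_evaluate(models, X_train, y_train, X_test, y_test):
    """One metrics row per model spec, computed on the test split only.
    A model that fails to fit is flagged (metrics=None) and the run continues."""
    rows: list[tuple[ModelSpec, EvalMetrics | None, str | None]] = []
    for spec in models:
        try:
            model = fit_model(spec, X_train, y_train)
            rows.append((spec, evaluate(y_test, model.predict_proba(X_test)), None))
        except Exception as exc:  # noqa: BLE001 — per-row failure isolation
            rows.append((spec, None, str(exc)))
    return rows


def predict_proba(model: TrainedModel, X) -> np.ndarray:
    if not isinstance(model, TrainedModel):
        raise TypeError("expected a TrainedModel produced by fit_model/self_train")
    return model.predict_proba(X)


def self_train(model_spec: ModelSpec, X_labeled, y_labeled, X_pool,
               threshold: float = 0.9, max_iters: int = 10):
    """Pseudo-labeling loop (train → label pool above threshold → retrain).

    Returns ``(model, history)`` where history holds one
    :class:`SelfTrainState` per completed iteration.  Pseudo labels are
    frozen once assigned; each retraining starts from scratch.  Selection is
    strict (max probability > threshold).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    X_labeled = np.asarray(X_labeled)
    y_labeled = np.asarray(y_labeled, dtype=int)
    X_pool = np.asarray(X_pool)
    if len(y_labeled) == 0:
        raise ValueError("labeled set must be non-empty")

    remaining = np.arange(len(X_pool))
    pseudo_X: list[np.ndarray] = []
    pseudo_y: list[int] = []
    history: list[SelfTrainState] = []
    model = fit_model(model_spec, X_labeled, y_labeled)

    for it in range(max_iters):
        if remaining.size == 0:
            if history:
                history[-1].stop_reason = "pool_empty"
            break
        proba = model.predict_proba(X_pool[remaining])
        conf = proba.max(axis=1)
        take = conf > threshold
        if not take.any():
            history.append(SelfTrainState(
                iteration=it, threshold=threshold, pseudo_labeled={},
                pool_remaining=int(remaining.size), stop_reason="no_new_labels"))
            break
        labels = np.argmax(proba[take], axis=1)
        taken_idx = remaining[take]
        new = {int(i): (int(l), float(c))
               for i, l, c in zip(taken_idx, labels, conf[take])}
        pseudo_X.append(X_pool[taken_idx])
        pseudo_y.extend(labels.tolist())
        remaining = remaining[~take]
        X_aug = np.vstack([X_labeled] + pseudo_X)
        y_aug = np.concatenate([y_labeled, np.asarray(pseudo_y, dtype=int)])
        model = fit_model(model_spec, X_aug, y_aug)
        history.append(SelfTrainState(
            iteration=it, threshold=threshold, pseudo_labeled=new,
            pool_remaining=int(remaining.size),
            stop_reason="max_iters" if it == max_iters - 1 else None))
    return model, history


def high_confidence_eval(model: TrainedModel, X_test, y_test,
                         threshold: float = 0.9) -> EvalMetrics | None:
    """Metrics over test items whose max predicted probability ≥ threshold
    (inclusive).  Returns ``None`` when no item is retained — an explicit
    empty-result signal, never NaN metrics."""
    proba = model.predict_proba(X_test)
    keep = proba.max(axis=1) >= threshold
    if not keep.any():
        return None
    return evaluate(np.asarray(y_test, dtype=int)[keep], proba[keep])
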