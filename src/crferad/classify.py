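"""Pathological typing: label encoding, SMOTE balancing, grid-searched
classifiers, and confusion-matrix / ROC evaluation.

The pathology label is the 3-bit code category = 4*cell_size +
2*keratinization + histology (small/large cell, keratinizing/non-,
squamous/adenocarcinoma).  Training data are balanced by SMOTE (synthetic
minority over-sampling: convex combinations of same-class nearest-
neighbor pairs) on the training folds only; four classifier families
(random forest, gradient boosting, SVM, logistic regression) are tuned by
exhaustive grid search under stratified 5-fold cross-validation on
macro-F1; evaluation reports the confusion matrix, accuracy, macro and
per-class precision/recall/F1, and one-vs-rest ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "encode_pathology",
    "smote_balance",
    "fit_with_grid",
    "evaluate",
    "roc_curves",
    "DEFAULT_GRIDS",
]

DEFAULT_GRIDS = {
    "random_forest": {
        "n_estimators": [50, 100, 200, 300],
        "max_depth": [None, 10, 20, 30],
        "min_samples_split": [2, 5, 10],
    },
    "gradient_boosting": {
        "n_estimators": [50, 100, 200],
        "max_depth": [3, 6],
        "learning_rate": [0.1, 0.3],
    },
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", "auto"]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "random_forest"
    grid: dict | None = None
    cv_folds: int = 5
    scoring: str = "f1_macro"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class EvaluationReport:
    classes: list
    confusion_matrix: np.ndarray  # true x predicted
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: dict  # class -> dict(precision, recall, f1, support)
    roc_auc: dict = field(default_factory=dict)


def encode_pathology(cell_size: int, keratinization: int, histology: int) -> int:
    """3-bit category = 4*cell_size + 2*keratinization + histology."""
    for name, v in (("cell_size", cell_size), ("keratinization", keratinization),
                    ("histology", histology)):
        if v not in (0, 1):
            raise ValueError(f"{name} must be binary, got {v!r}")
    return 4 * cell_size + 2 * keratinization + histology


def smote_balance(matrix: np.ndarray, labels, seed: int = 0, k_neighbors: int = 5):
    """Oversample every minority class up to the majority count.

    Synthetic rows are x_i + u * (x_nn - x_i) for a random same-class
    neighbor x_nn and u ~ U(0, 1); original rows are preserved verbatim.
    Classes with a single member cannot be interpolated and raise.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    out_x, out_y = [matrix], [labels]
    for cls, cnt in zip(classes, counts):
        deficit = int(target - cnt)
        if deficit == 0:
            continue
        if cnt < 2:
            raise ValueError(f"class {cls!r} has a single member; SMOTE undefined")
        pts = matrix[labels == cls]
        k = min(k_neighbors, cnt - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
        _, idx = nn.kneighbors(pts)
        base = rng.integers(0, cnt, size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)  # skip self at column 0
        u = rng.random(size=(deficit, 1))
        synth = pts[base] + u * (pts[idx[base, pick]] - pts[base])
        out_x.append(synth)
        out_y.append(np.full(deficit, cls, dtype=labels.dtype))
    return np.vstack(out_x), np.concatenate(out_y)


def _make_estimator(family: str, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "gradient_boosting":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             use_label_encoder=False, eval_metric="mlogloss")
    if family == "svm":
        return SVC(probability=True, random_state=seed)
    return LogisticRegression(max_iter=2000, random_state=seed)


def fit_with_grid(matrix: np.ndarray, labels, spec: ClassifierSpec):
    """Exhaustive grid search by stratified CV; refit best on all data.

    Returns (fitted estimator, best parameter dict, cv results table).
    For gradient boosting the labels are re-indexed to 0..K-1 internally;
    the returned estimator exposes the original labels via ``classes_``.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    grid = spec.grid if spec.grid is not None else DEFAULT_GRIDS[spec.family]
    y = labels
    if spec.family == "gradient_boosting":
        lut = {c: i for i, c in enumerate(classes)}
        y = np.array([lut[v] for v in labels])
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec.family, spec.seed), grid, cv=cv,
        scoring=spec.scoring, refit=True, n_jobs=1,
    )
    search.fit(matrix, y)
    model = search.best_estimator_
    if spec.family == "gradient_boosting":
        model = _XGBWrapper(model, classes)
    return model, search.best_params_, search.cv_results_


class _XGBWrapper:
    """Maps XGBoost's 0..K-1 class indices back to the original labels."""

    def __init__(self, model, classes):
        self._model = model
        self.classes_ = np.asarray(classes)

    def predict(self, x):
        return self.classes_[self._model.predict(np.asarray(x, dtype=float))]

    def predict_proba(self, x):
        return self._model.predict_proba(np.asarray(x, dtype=float))


def _f1(precision: float, recall: float) -> float:
    return 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)


def evaluate(model, test_matrix: np.ndarray, test_labels) -> EvaluationReport:
    """Confusion matrix plus accuracy / precision / recall / F1.

    Metrics are computed per class one-vs-rest from the confusion counts
    (accuracy = (TP+TN)/total over all predictions; per-class F1 is the
    harmonic mean of precision and recall); macro averages run over
    classes with nonzero test support.  Classes absent from training are
    never predicted, so their recall is 0 — the behavior expected when a
    category has no training representation.
    """
    test_labels = np.asarray(test_labels)
    if len(test_labels) == 0:
        raise ValueError("empty test set")
    pred = np.asarray(model.predict(np.asarray(test_matrix, dtype=float)))
    classes = sorted(set(np.unique(test_labels)) | set(np.asarray(model.classes_)))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(test_labels, pred):
        cm[index[t], index[p]] += 1

    per_class = {}
    for c in classes:
        i = index[c]
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        support = int(cm[i, :].sum())
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        per_class[c] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(_f1(precision, recall)),
            "support": support,
        }
    present = [c for c in classes if per_class[c]["support"] > 0]
    return EvaluationReport(
        classes=classes,
        confusion_matrix=cm,
        accuracy=float(np.trace(cm) / cm.sum()),
        macro_precision=float(np.mean([per_class[c]["precision"] for c in present])),
        macro_recall=float(np.mean([per_class[c]["recall"] for c in present])),
        macro_f1=float(np.mean([per_class[c]["f1"] for c in present])),
        per_class=per_class,
    )


def roc_curves(model, test_matrix: np.ndarray, test_labels) -> dict:
    """One-vs-rest ROC per class present in the test set.

    Returns class -> (fpr, tpr, auc); classes with single-valued truth in
    the test set get auc = None (undefined, not fabricated).
    """
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve as sk_roc

    test_labels = np.asarray(test_labels)
    scores = model.predict_proba(np.asarray(test_matrix, dtype=float))
    model_classes = list(np.asarray(model.classes_))
    out = {}
    for c in sorted(set(test_labels)):
        truth = (test_labels == c).astype(int)
        if c not in model_classes or truth.min() == truth.max():
            out[c] = (None, None, None)
            continue
        s = scores[:, model_classes.index(c)]
        fpr, tpr, _ = sk_roc(truth, s)
        out[c] = (fpr, tpr, float(sk_auc(fpr, tpr)))
    return out
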