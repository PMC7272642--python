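"""AD-vs-NC discrimination with a polynomial-kernel SVM.

A soft-margin SVM with a second-order polynomial kernel, evaluated by
stratified subject-level 6-fold cross-validation: each subject is
predicted exactly once by a model never trained on it, feature
standardization is estimated on the training folds only, and the pooled
out-of-fold decision scores define the ROC curve and its trapezoidal
AUC.  AD is the positive class, so sensitivity is the correct-detection
rate for AD and specificity that for NC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE_LABEL = "AD"
NEGATIVE_LABEL = "NC"


@dataclass(frozen=True)
class ClassifierSpec:
    """Polynomial-kernel SVM and cross-validation settings.

    Kernel (offset + (x.y)/s^2)^degree with box constraint C and
    per-feature z-score standardization fitted on training folds.  The
    default kernel scale ``s = sqrt(n_features)`` ("auto") makes the
    kernel argument a correlation-like O(1) quantity for standardized
    features regardless of dimensionality; a fixed numeric scale can be
    given instead.
    """

    degree: int = 2
    box_constraint: float = 1.0
    kernel_scale: float | str = "auto"
    kernel_offset: float = 1.0
    standardize: bool = True
    n_folds: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.box_constraint <= 0:
            raise ValueError("box constraint must be positive")
        if self.kernel_scale != "auto" and not float(self.kernel_scale) > 0:
            raise ValueError("kernel scale must be positive or 'auto'")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class FittedSVM:
    """A trained decision function: standardization + polynomial SVM."""

    scaler: StandardScaler | None
    svc: SVC

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, POSITIVE_LABEL, NEGATIVE_LABEL)


@dataclass
class CrossValidationReport:
    """Out-of-fold predictions and the derived discrimination metrics."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold: np.ndarray
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    roc_fpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    auc: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_subjects": len(self.subject_ids),
            "confusion_matrix": {
                "TP": self.tp,
                "FP": self.fp,
                "TN": self.tn,
                "FN": self.fn,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "roc": [
                {"fpr": float(f), "tpr": float(t)}
                for f, t in zip(self.roc_fpr, self.roc_tpr)
            ],
            "per_subject": [
                {
                    "subject_id": sid,
                    "true": str(t),
                    "predicted": str(p),
                    "score": float(s),
                    "fold": int(k),
                }
                for sid, t, p, s, k in zip(
                    self.subject_ids, self.y_true, self.y_pred, self.scores, self.fold
                )
            ],
        }


def _validate_labels(y: np.ndarray) -> None:
    labels = set(np.unique(y))
    if not labels <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ValueError(f"labels must be {POSITIVE_LABEL}/{NEGATIVE_LABEL}, got {labels}")
    if len(labels) < 2:
        raise ValueError("training data contains a single class")


def fit_svm(X: np.ndarray, y, spec: ClassifierSpec = ClassifierSpec()) -> FittedSVM:
    """Train the polynomial-kernel SVM on (subjects x features) data."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    _validate_labels(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    if spec.kernel_scale == "auto":
        scale = float(np.sqrt(X.shape[1]))
    else:
        scale = float(spec.kernel_scale)
    svc = SVC(
        kernel="poly",
        degree=spec.degree,
        gamma=1.0 / scale**2,
        coef0=spec.kernel_offset,
        C=spec.box_constraint,
    )
    # Map labels so the decision function is positive for AD.
    svc.fit(X, (y == POSITIVE_LABEL).astype(int))
    return FittedSVM(scaler=scaler, svc=svc)


def roc_points(y_true: np.ndarray, scores: np.ndarray):
    """ROC curve of pooled decision scores; AUC by the trapezoidal rule."""
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=POSITIVE_LABEL)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def cross_validate(
    X: np.ndarray,
    y,
    spec: ClassifierSpec = ClassifierSpec(),
    subject_ids: list[str] | None = None,
) -> CrossValidationReport:
    """Stratified subject-level k-fold cross-validation.

    Every subject is predicted once, by a model fitted (including its
    standardization) without that subject's data; metrics and ROC come
    from the pooled out-of-fold predictions.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    _validate_labels(y)
    counts = pd.Series(y).value_counts()
    if counts.min() < spec.n_folds:
        raise ValueError(
            f"{spec.n_folds}-fold CV infeasible: smallest class has "
            f"{counts.min()} subjects"
        )
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(len(y))]

    skf = StratifiedKFold(
        n_splits=spec.n_folds, shuffle=True, random_state=spec.seed
    )
    scores = np.empty(len(y))
    pred = np.empty(len(y), dtype=object)
    fold_of = np.empty(len(y), dtype=int)
    for k, (train, test) in enumerate(skf.split(X, y)):
        model = fit_svm(X[train], y[train], spec)
        scores[test] = model.decision_function(X[test])
        pred[test] = model.predict(X[test])
        fold_of[test] = k

    tp = int(np.sum((y == POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
    fn = int(np.sum((y == POSITIVE_LABEL) & (pred == NEGATIVE_LABEL)))
    tn = int(np.sum((y == NEGATIVE_LABEL) & (pred == NEGATIVE_LABEL)))
    fp = int(np.sum((y == NEGATIVE_LABEL) & (pred == POSITIVE_LABEL)))
    fpr, tpr, auc = roc_points(y, scores)
    return CrossValidationReport(
        subject_ids=list(subject_ids),
        y_true=y,
        y_pred=pred.astype(str),
        scores=scores,
        fold=fold_of,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
    )


def classify_feature_table(
    features: pd.DataFrame, spec: ClassifierSpec = ClassifierSpec()
) -> CrossValidationReport:
    """Cross-validate on an assembled cohort feature table."""
    cells = [c for c in features.columns if c not in ("subject_id", "group")]
    return cross_validate(
        features[cells].to_numpy(float),
        features["group"].to_numpy(),
        spec,
        subject_ids=list(features["subject_id"]),
    )
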