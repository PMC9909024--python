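"""Classifier head and the imbalanced-binary metric panel.

Six classifier kinds are supported: logistic regression (LR), random forest
(RF), Gaussian naive Bayes (NB), k-nearest neighbours (KNN), AdaBoost and
XGBOOST. XGBOOST consumes missing values natively; for every other kind
missing cells are filled with the constant -1 before fitting (the standard
out-of-band sentinel after min-max scaling to [0, 1]).

The panel reports, at a 0.5 decision threshold: P_Accuracy (positive
predictive value TP/(TP+FP)), N_Accuracy (negative predictive value
TN/(TN+FN)), Sensitivity (TP/(TP+FN)), Specificity (TN/(TN+FP)) and ROC-AUC
from the continuous scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("LR", "RF", "NB", "KNN", "AdaBoost", "XGBOOST")

#: pinned baseline hyperparameters, so runs stay reproducible as library
#: defaults drift; overridable per spec via ``ClassifierSpec.params``
DEFAULT_PARAMS: dict[str, dict] = {
    "LR": {"max_iter": 2000, "solver": "lbfgs", "C": 1.0},
    "RF": {"n_estimators": 200, "n_jobs": 1},
    "NB": {},
    "KNN": {"n_neighbors": 5, "n_jobs": 1},
    "AdaBoost": {"n_estimators": 50, "learning_rate": 1.0},
    "XGBOOST": {
        "n_estimators": 100,
        "max_depth": 6,
        "learning_rate": 0.3,
        "tree_method": "hist",
        "n_jobs": 1,
        "eval_metric": "logloss",
    },
}

MISSING_FILL = -1.0


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier kind with hyperparameters, missing policy and seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")

    @property
    def handles_missing_natively(self) -> bool:
        return self.kind == "XGBOOST"


def _build(spec: ClassifierSpec):
    params = {**DEFAULT_PARAMS[spec.kind], **spec.params}
    if spec.kind == "LR":
        return LogisticRegression(random_state=spec.seed, **params)
    if spec.kind == "RF":
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.kind == "NB":
        return GaussianNB(**params)
    if spec.kind == "KNN":
        return KNeighborsClassifier(**params)
    if spec.kind == "AdaBoost":
        return AdaBoostClassifier(random_state=spec.seed, **params)
    return XGBClassifier(random_state=spec.seed, **params)


@dataclass
class FittedClassifier:
    """A fitted estimator plus the design-matrix policy actually applied.

    ``design_matrix_`` keeps the (possibly -1-filled) matrix the estimator
    saw during fitting, as an introspection hook for the missing-value
    contract.
    """

    spec: ClassifierSpec
    estimator: object
    design_matrix_: np.ndarray

    def _prepare(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
        if not self.spec.handles_missing_natively:
            X = np.where(np.isnan(X), MISSING_FILL, X)
        return X

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(self._prepare(X))[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.spec.threshold).astype(int)


def fit_classifier(spec: ClassifierSpec, features, labels) -> FittedClassifier:
    """Fit one classifier; -1-fill missing cells unless the kind handles NaN.

    Raises on single-class labels or on non-finite values that are not
    missing (inf is always an error).
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_classifier requires both classes present")
    if np.isinf(X).any():
        raise ValueError("feature matrix contains non-finite (inf) values")
    if not spec.handles_missing_natively:
        X = np.where(np.isnan(X), MISSING_FILL, X)
    est = _build(spec)
    est.fit(X, y)
    return FittedClassifier(spec=spec, estimator=est, design_matrix_=X)


#: sentinel AUC when ground truth has a single class (AUC undefined)
AUC_UNDEFINED = None


@dataclass
class MetricPanel:
    """Confusion counts and the derived panel for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    p_accuracy: float
    n_accuracy: float
    sensitivity: float
    specificity: float
    roc_auc: float | None

    def as_dict(self) -> dict:
        return {
            "P_Accuracy": self.p_accuracy,
            "N_Accuracy": self.n_accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "ROC": self.roc_auc,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
        }


def panel_from_counts(tp: int, fp: int, tn: int, fn: int, roc_auc: float | None = None) -> MetricPanel:
    """Closed-form panel from a confusion matrix (PPV/NPV default to 0 on empty denominators)."""
    if tp + fp == 0:
        logger.warning("no predicted positives; P_Accuracy reported as 0")
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return MetricPanel(
        tp=tp, fp=fp, tn=tn, fn=fn,
        p_accuracy=ppv, n_accuracy=npv, sensitivity=sens, specificity=spec, roc_auc=roc_auc,
    )


def panel_from_scores(scores, labels, threshold: float = 0.5) -> MetricPanel:
    """Panel from continuous scores: confusion at the threshold, trapezoidal AUC.

    One-class ground truth yields the explicit ``None`` sentinel for AUC (with
    a warning), never a silent NaN.
    """
    y = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if len(np.unique(y)) < 2:
        logger.warning("single-class ground truth: ROC-AUC is undefined")
        auc = AUC_UNDEFINED
    else:
        auc = float(roc_auc_score(y, scores))
    return panel_from_counts(tp, fp, tn, fn, auc)


def evaluate(model: FittedClassifier, features, labels, threshold: float | None = None) -> MetricPanel:
    """Score a fitted classifier on a feature matrix (see :func:`panel_from_scores`)."""
    thr = model.spec.threshold if threshold is None else threshold
    return panel_from_scores(model.predict_proba(features), labels, thr)
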