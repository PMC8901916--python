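"""Classification of subject feature vectors.

Bootstrap-aggregated decision trees (BADT) and Gaussian naive Bayes
(GNB), evaluated with stratified k-fold cross validation repeated over
many replications; accuracy, sensitivity and specificity are reported as
means with standard errors over replications, with MDD as the positive
class.  An optional margin-based "Mixed" latent-label augmentation
relabels low-confidence training instances for a second pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CVConfig",
    "ClassifierReport",
    "train_badt",
    "train_gnb",
    "mixed_label_augmentation",
    "MixedLabelBadt",
    "evaluate_cv",
]

POSITIVE_LABEL = "MDD"


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol: k folds, reshuffled over replications."""

    folds: int = 10
    replications: int = 100
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


def train_badt(features, labels, n_estimators: int = 200, seed: int = 0) -> BaggingClassifier:
    """Fit bootstrap-aggregated decision trees (plain bagging, full-depth
    trees, no feature subsampling) with majority-vote prediction."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (impute upstream)")
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_estimators,
        random_state=seed,
    )
    return model.fit(X, y)


def train_gnb(features, labels, var_floor: float = 1e-9) -> GaussianNB:
    """Fit Gaussian naive Bayes (per-class per-feature normal likelihoods)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    for c in np.unique(y):
        if np.any(X[y == c].var(axis=0) <= 0):
            warnings.warn(
                f"zero-variance feature in class {c!r}; variance floored at {var_floor}"
            )
    return GaussianNB(var_smoothing=var_floor).fit(X, y)


def mixed_label_augmentation(
    features, labels, threshold: float = 0.1, n_estimators: int = 200, seed: int = 0
) -> np.ndarray:
    """Relabel low-margin instances with the latent class "Mixed".

    An out-of-bag bagged-tree model scores every training instance; those
    whose class-probability margin |p(MDD) - p(H)| falls below
    ``threshold`` are relabeled "Mixed" for a second training pass.  This
    is a heuristic interpretation of a latent sub-type label and is off by
    default in the evaluation pipeline.
    """
    y = np.asarray(labels, dtype=object).copy()
    if threshold <= 0:
        return y
    X = np.asarray(features, dtype=float)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_estimators,
        oob_score=False,
        bootstrap=True,
        random_state=seed,
    ).fit(X, y)
    # out-of-bag class probabilities, tree by tree
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes_)))
    counts = np.zeros(n)
    rng_states = model.estimators_samples_
    for est, samples in zip(model.estimators_, rng_states):
        oob = np.setdiff1d(np.arange(n), samples)
        if oob.size == 0:
            continue
        # inner estimators predict label-encoded class indices
        pred = np.asarray(est.predict(X[oob]), dtype=int)
        for ci in range(len(model.classes_)):
            votes[oob[pred == ci], ci] += 1
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        proba = votes / np.maximum(counts, 1)[:, None]
    margin = np.abs(np.diff(proba, axis=1)).ravel() if proba.shape[1] == 2 else np.ptp(proba, axis=1)
    y[(counts > 0) & (margin < threshold)] = "Mixed"
    return y


class MixedLabelBadt:
    """BADT trained with the latent "Mixed" class; predicts binary labels.

    A "Mixed" prediction is resolved to the majority binary vote among the
    ensemble's trees (falling back to the larger of the two binary class
    probabilities).
    """

    def __init__(self, threshold: float = 0.1, n_estimators: int = 200, seed: int = 0):
        self.threshold = threshold
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        y_aug = mixed_label_augmentation(
            X, y, threshold=self.threshold, n_estimators=self.n_estimators, seed=self.seed
        )
        if np.unique(y_aug).size < 2:
            y_aug = np.asarray(y, dtype=object)
        self.binary_classes_ = np.unique(np.asarray(y, dtype=object))
        self.model_ = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=self.seed),
            n_estimators=self.n_estimators,
            random_state=self.seed,
        ).fit(np.asarray(X, dtype=float), y_aug)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        pred = self.model_.predict(X).astype(object)
        mixed = pred == "Mixed"
        if np.any(mixed):
            proba = self.model_.predict_proba(X[mixed])
            cols = [i for i, c in enumerate(self.model_.classes_) if c in self.binary_classes_]
            sub = proba[:, cols]
            pred[mixed] = np.asarray(self.model_.classes_)[cols][np.argmax(sub, axis=1)]
        return pred


@dataclass
class ClassifierReport:
    """Cross-validated metrics: means and standard errors over replications."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_se: float
    sensitivity_se: float
    specificity_se: float
    per_replication: pd.DataFrame
    confusion_matrices: list

    def summary(self) -> str:
        return (
            f"accuracy    {self.accuracy:.3f} +- {self.accuracy_se:.3f}\n"
            f"sensitivity {self.sensitivity:.3f} +- {self.sensitivity_se:.3f}\n"
            f"specificity {self.specificity:.3f} +- {self.specificity_se:.3f}"
        )


def _make_model(model_spec, seed):
    if callable(model_spec):
        return model_spec(seed)
    if model_spec == "badt":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=200,
            random_state=seed,
        )
    if model_spec == "badt_mixed":
        return MixedLabelBadt(seed=seed)
    if model_spec == "gnb":
        return GaussianNB(var_smoothing=1e-9)
    raise ValueError(f"unknown model spec {model_spec!r}")


def evaluate_cv(
    model_spec,
    features,
    labels,
    cv: CVConfig = CVConfig(),
    positive_label: str = POSITIVE_LABEL,
) -> ClassifierReport:
    """Repeated stratified k-fold cross validation with the study's metrics.

    Per replication the data are reshuffled (seeded), split into stratified
    folds, and a fresh model is trained per fold; fold confusion matrices
    are aggregated and accuracy, sensitivity (positive class
    ``positive_label``) and specificity computed.  NaN feature entries are
    imputed with the *training-fold* per-feature median (no leakage).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("evaluate_cv expects exactly two classes")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    if X.shape[0] < cv.folds:
        raise ValueError("need at least as many subjects as folds")

    rows, confusions = [], []
    for rep in range(cv.replications):
        rep_seed = cv.seed + rep
        splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=rep_seed)
        tp = tn = fp = fn = 0
        for tr, te in splitter.split(X, y.astype(str)):
            if np.unique(y[tr]).size < 2:
                warnings.warn("fold without both classes; reshuffling")
                splitter = StratifiedKFold(
                    n_splits=cv.folds, shuffle=True, random_state=rep_seed + 10_000
                )
                continue
            med = np.nanmedian(X[tr], axis=0)
            med = np.where(np.isfinite(med), med, 0.0)
            Xtr = np.where(np.isnan(X[tr]), med, X[tr])
            Xte = np.where(np.isnan(X[te]), med, X[te])
            model = _make_model(model_spec, rep_seed)
            model.fit(Xtr, y[tr])
            pred = np.asarray(model.predict(Xte), dtype=object)
            truth = y[te]
            tp += int(np.sum((truth == positive_label) & (pred == positive_label)))
            fn += int(np.sum((truth == positive_label) & (pred != positive_label)))
            tn += int(np.sum((truth != positive_label) & (pred != positive_label)))
            fp += int(np.sum((truth != positive_label) & (pred == positive_label)))
        total = tp + tn + fp + fn
        rows.append(
            {
                "replication": rep,
                "accuracy": (tp + tn) / total,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
        confusions.append(np.array([[tp, fn], [fp, tn]]))
    per_rep = pd.DataFrame(rows).set_index("replication")
    means = per_rep.mean()
    ses = per_rep.std(ddof=1) / np.sqrt(cv.replications) if cv.replications > 1 else per_rep.iloc[0] * 0
    return ClassifierReport(
        accuracy=float(means["accuracy"]),
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        accuracy_se=float(ses["accuracy"]),
        sensitivity_se=float(ses["sensitivity"]),
        specificity_se=float(ses["specificity"]),
        per_replication=per_rep,
        confusion_matrices=confusions,
    )
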