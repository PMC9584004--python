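"""Random Forest classification of segmented objects with the accuracy
protocol used in remote-sensing accuracy assessment.

The confusion matrix convention is rows = reference, columns = predicted,
so user's accuracy (precision) is a column ratio and producer's accuracy
(recall) a row ratio.  Cross-validation is stratified k-fold; metrics are
computed per fold and averaged, and the pooled confusion matrix across the
test folds is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassificationReport",
    "train_classifier",
    "cross_validate",
    "accuracy_metrics",
]


@dataclass
class ClassificationReport:
    classes: list
    confusion: np.ndarray                 # pooled over test folds
    overall_accuracy: float               # mean over folds
    users_accuracy: dict                  # class -> mean over folds
    producers_accuracy: dict
    kappa: float                          # mean over folds
    fold_overall: list[float] = field(default_factory=list)
    fold_kappa: list[float] = field(default_factory=list)
    pooled_overall: float = np.nan
    pooled_kappa: float = np.nan

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "users_accuracy": {str(k): v for k, v in self.users_accuracy.items()},
            "producers_accuracy": {str(k): v for k, v in self.producers_accuracy.items()},
            "kappa": self.kappa,
            "fold_overall": self.fold_overall,
            "fold_kappa": self.fold_kappa,
            "pooled_overall": self.pooled_overall,
            "pooled_kappa": self.pooled_kappa,
        }


def _as_xy(features, labels):
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are not aligned")
    if np.isnan(X).any():
        raise ValueError("missing feature values; impute before training")
    return X, y


def train_classifier(features, labels, n_trees: int = 500, seed: int = 0):
    """Fit a Random Forest (bootstrap aggregation, sqrt(p) features per split).

    Deterministic under a fixed seed; exposes class probabilities via
    ``predict_proba``.
    """
    X, y = _as_xy(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least two examples")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return model


def confusion_matrix(reference, predicted, classes) -> np.ndarray:
    """Confusion counts with rows = reference, columns = predicted."""
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for r, p in zip(reference, predicted):
        cm[idx[r], idx[p]] += 1
    return cm


def accuracy_metrics(confusion) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(overall, user's per class, producer's per class, Cohen's kappa).

    overall = trace / N; user's = diagonal / column sum; producer's =
    diagonal / row sum; kappa = (p_o - p_e) / (1 - p_e) with p_e the chance
    agreement from the marginals.  A zero marginal makes that class's
    accuracy missing (NaN).
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain observations")
    diag = np.diag(cm)
    rows = cm.sum(axis=1)
    cols = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(cols > 0, diag / cols, np.nan)
        producers = np.where(rows > 0, diag / rows, np.nan)
    p_o = diag.sum() / total
    p_e = float(np.sum(rows * cols)) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return float(p_o), users, producers, float(kappa)


def cross_validate(
    features, labels, k: int = 5, n_trees: int = 500, seed: int = 0
) -> ClassificationReport:
    """Stratified k-fold cross-validation with per-fold metric averaging."""
    if k < 2:
        raise ValueError("k must be at least 2")
    X, y = _as_xy(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("each class must have at least k examples")
    classes = list(classes)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    fold_overall, fold_kappa = [], []
    fold_users = np.zeros((k, len(classes)))
    fold_producers = np.zeros((k, len(classes)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed + f, n_jobs=1
        )
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        cm = confusion_matrix(y[te], pred, classes)
        pooled += cm
        oa, users, producers, kap = accuracy_metrics(cm)
        fold_overall.append(oa)
        fold_kappa.append(kap)
        fold_users[f] = users
        fold_producers[f] = producers
    pooled_oa, _, _, pooled_kappa = accuracy_metrics(pooled)
    with np.errstate(invalid="ignore"):
        mean_users = np.nanmean(fold_users, axis=0)
        mean_producers = np.nanmean(fold_producers, axis=0)
    return ClassificationReport(
        classes=classes,
        confusion=pooled,
        overall_accuracy=float(np.mean(fold_overall)),
        users_accuracy=dict(zip(classes, mean_users)),
        producers_accuracy=dict(zip(classes, mean_producers)),
        kappa=float(np.mean(fold_kappa)),
        fold_overall=[float(v) for v in fold_overall],
        fold_kappa=[float(v) for v in fold_kappa],
        pooled_overall=float(pooled_oa),
        pooled_kappa=float(pooled_kappa),
    )
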