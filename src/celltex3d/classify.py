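"""Multiclass classification with leave-one-out cross-validation and the
one-vs-rest performance metrics.

Three small-sample classifiers are supported: a CART decision tree with the
Gini split criterion (``"DT"``), Gaussian naïve Bayes (``"NB"``) and the
1-nearest-neighbour rule with Euclidean distance (``"NN"``). Validation is
leave-one-out: by default the whole feature-preparation chain (z-score →
ANOVA filter → PCA) is refit inside each fold on the training samples only,
so selection never sees the held-out sample; ``refit_selection=False``
("paper mode") fits the chain once on all samples for comparability with
protocols that select features before cross-validating.

Per-class metrics come from the one-vs-rest reduction of the confusion
matrix: for class c, TP = diagonal entry, FN = rest of row c, FP = rest of
column c, and TN = everything else (off-class samples not predicted as c).
Percentages are displayed truncated to 2 decimals, the convention of the
tabulated reference values (e.g. 18/19 → 94.73); raw fractions are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractError, ParameterError
from .haralick import FeatureMatrix
from .selection import select_features

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix",
    "OneVsRestCounts",
    "ClassifierReport",
    "onevsrest_counts",
    "report_metrics",
    "loocv_run",
    "percent",
]

#: Canonical class order: benign hyperplasia, intraepithelial neoplasia, carcinoma.
CLASS_ORDER = ("BH", "IN", "Ca")

CLASSIFIER_IDS = ("DT", "NB", "NN")


def percent(fraction: float) -> float:
    """A fraction as a percentage truncated to 2 decimals (table convention)."""
    return np.floor(fraction * 10000.0 + 1e-9) / 100.0


@dataclass
class ConfusionMatrix:
    """Square contingency table; rows = true class, columns = predicted."""

    table: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        k = len(self.classes)
        if t.shape != (k, k):
            raise ParameterError(f"table: expected ({k}, {k}), got {t.shape}")
        if not np.issubdtype(t.dtype, np.integer) or (t < 0).any():
            raise ParameterError("table: entries must be non-negative integers")
        self.table = t.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.table.sum())

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=CLASS_ORDER) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        t = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for yt, yp in zip(y_true, y_pred):
            t[index[yt], index[yp]] += 1
        return cls(t, tuple(classes))


class OneVsRestCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int


def onevsrest_counts(cm: ConfusionMatrix, cls: str) -> OneVsRestCounts:
    """TP/TN/FP/FN for one class treated as positive against the rest."""
    if cls not in cm.classes:
        raise ParameterError(f"class {cls!r} not in {cm.classes}")
    c = cm.classes.index(cls)
    tp = int(cm.table[c, c])
    fn = int(cm.table[c].sum()) - tp
    fp = int(cm.table[:, c].sum()) - tp
    tn = cm.total - tp - fn - fp
    return OneVsRestCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class ClassifierReport:
    """Confusion matrix plus derived metrics for one classifier run.

    ``accuracy`` and the per-class entries are raw fractions in [0, 1];
    ``summary()`` renders them as truncated percentages.
    """

    confusion: ConfusionMatrix
    classifier_id: str
    accuracy: float = field(init=False)
    per_class: dict[str, dict[str, float]] = field(init=False)
    pairwise_auc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cm = self.confusion
        if cm.total == 0:
            raise ContractError("empty confusion matrix")
        self.accuracy = float(np.trace(cm.table)) / cm.total
        self.per_class = {}
        for cls in cm.classes:
            tp, tn, fp, fn = onevsrest_counts(cm, cls)
            self.per_class[cls] = {
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                "f_score": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
                "accuracy": (tp + tn) / cm.total,
            }

    def summary(self) -> str:
        cm = self.confusion
        lines = [f"Classifier: {self.classifier_id}"]
        header = "true\\pred " + " ".join(f"{c:>5}" for c in cm.classes)
        lines.append(header)
        for i, c in enumerate(cm.classes):
            lines.append(f"{c:>9} " + " ".join(f"{v:>5d}" for v in cm.table[i]))
        lines.append(f"overall accuracy: {percent(self.accuracy):.2f}%")
        for cls in cm.classes:
            m = self.per_class[cls]
            lines.append(
                f"{cls}: sensitivity {percent(m['sensitivity']):.2f}%  "
                f"specificity {percent(m['specificity']):.2f}%  "
                f"F-score {percent(m['f_score']):.2f}%"
            )
        for pair, auc in self.pairwise_auc.items():
            lines.append(f"AUC {pair}: {percent(auc):.2f}%")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_id,
            "classes": list(self.confusion.classes),
            "confusion_matrix": self.confusion.table.tolist(),
            "accuracy": self.accuracy,
            "accuracy_percent": percent(self.accuracy),
            "per_class": {
                cls: {
                    **{k: v for k, v in m.items()},
                    **{f"{k}_percent": percent(v) for k, v in m.items()},
                }
                for cls, m in self.per_class.items()
            },
            "pairwise_auc": self.pairwise_auc,
        }


def report_metrics(cm: ConfusionMatrix, classifier_id: str = "DT") -> ClassifierReport:
    """Derive overall accuracy and per-class sensitivity/specificity/F-score."""
    return ClassifierReport(cm, classifier_id)


def _make_classifier(classifier_id: str):
    key = classifier_id.upper()
    if key == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=0)
    if key == "NB":
        return GaussianNB()
    if key == "NN":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    raise ParameterError(f"classifier: expected one of {CLASSIFIER_IDS}, got {classifier_id!r}")


def _class_scores(model, x, classes, xtr, ytr) -> np.ndarray:
    """A continuous per-class score for one sample (for ROC ranking).

    DT and NB expose class probabilities; the 1-NN rule uses the negative
    distance to the nearest training sample of each class.
    """
    if isinstance(model, KNeighborsClassifier):
        scores = np.full(len(classes), -np.inf)
        d = np.sqrt(((xtr - x) ** 2).sum(axis=1))
        for i, c in enumerate(classes):
            mask = ytr == c
            if mask.any():
                scores[i] = -d[mask].min()
        return scores
    proba = model.predict_proba(x[None, :])[0]
    scores = np.zeros(len(classes))
    for cls, p in zip(model.classes_, proba):
        scores[classes.index(cls)] = p
    return scores


def loocv_run(
    features: FeatureMatrix,
    labels=None,
    classifier: str = "DT",
    refit_selection: bool = True,
    alpha: float = 0.01,
    variance_target: float = 0.97,
    max_components: int | None = None,
    classes: tuple[str, ...] = CLASS_ORDER,
) -> ClassifierReport:
    """Leave-one-out cross-validation on texture features.

    Each sample is predicted by a classifier trained on all others; the
    confusion matrix is assembled over the folds and pairwise ROC AUCs are
    computed from the held-out class scores. Deterministic for fixed inputs.
    """
    labels = features.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ContractError("loocv_run requires labels")
    labels = np.asarray(labels)
    classes = tuple(c for c in classes if c in labels) or tuple(pd.unique(labels))
    for c in classes:
        if (labels == c).sum() < 2:
            raise ContractError(f"class {c!r} has < 2 samples")
    _make_classifier(classifier)  # validate id before any work

    n = features.n_samples
    df = features.data
    shared_sel = None
    if not refit_selection:
        shared_sel = select_features(
            features, labels, alpha=alpha,
            variance_target=variance_target, max_components=max_components,
        )

    y_pred = []
    score_rows = np.zeros((n, len(classes)))
    for i in range(n):
        train_idx = np.ones(n, dtype=bool)
        train_idx[i] = False
        train_df = df.iloc[train_idx]
        train_labels = labels[train_idx]
        if refit_selection:
            sel = select_features(
                FeatureMatrix(train_df, labels=train_labels),
                alpha=alpha, variance_target=variance_target,
                max_components=max_components,
            )
        else:
            sel = shared_sel
        xtr = sel.transform(train_df)
        xte = sel.transform(df.iloc[[i]])[0]
        model = _make_classifier(classifier)
        model.fit(xtr, train_labels)
        y_pred.append(model.predict(xte[None, :])[0])
        score_rows[i] = _class_scores(model, xte, classes, xtr, train_labels)

    cm = ConfusionMatrix.from_predictions(labels, y_pred, classes)
    report = ClassifierReport(cm, classifier.upper())
    report.pairwise_auc = _pairwise_auc(labels, score_rows, classes)
    return report


def _pairwise_auc(labels: np.ndarray, scores: np.ndarray, classes) -> dict[str, float]:
    """ROC AUC for every class pair from held-out class scores.

    The ranking score for pair (A, B) is score_A - score_B with A positive;
    tied scores get mid-rank treatment (the trapezoidal ROC convention).
    """
    aucs = {}
    for a_idx in range(len(classes)):
        for b_idx in range(a_idx + 1, len(classes)):
            a, b = classes[a_idx], classes[b_idx]
            pick = (labels == a) | (labels == b)
            if len(np.unique(labels[pick])) < 2:
                continue
            diff = scores[pick, a_idx] - scores[pick, b_idx]
            diff = np.where(np.isfinite(diff), diff, 0.0)
            aucs[f"{a}_vs_{b}"] = float(
                roc_auc_score((labels[pick] == a).astype(int), diff)
            )
    return aucs
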