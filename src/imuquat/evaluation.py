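"""Evaluation metrics and the quaternion-vs-raw comparison pipeline.

Per-class metrics follow the usual confusion-matrix definitions:

* precision ``P = tp / (tp + fp)``
* recall ``R = tp / (tp + fn)``
* F-score ``F = 2 P R / (P + R)``

with the convention that a 0/0 quotient is 0 (warned). The score of a
classifier is the unweighted macro average over the six classes; under
k-fold cross-validation the per-class and macro scores are averaged
across folds (an unweighted mean over folds; pooling the fold confusion
matrices first is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, default_specs, train_classifier
from .exceptions import InvalidInputError
from .features import FeatureMatrix, FoldSplit, build_features, kfold_split
from .simulate import LabeledDataset

__all__ = [
    "EvalReport",
    "ComparisonReport",
    "confusion_counts",
    "score",
    "cross_validate",
    "compare_views",
]


@dataclass
class EvalReport:
    """Per-class and macro precision/recall/F plus the confusion matrix.

    ``fold`` identifies what was scored: a fold index, ``"aggregate"``
    for a single evaluation, or ``"cv-mean"`` for a cross-fold average
    (whose confusion matrix is the sum over folds and whose
    ``per_fold`` attribute holds the individual fold reports).
    """

    classes: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fscore: np.ndarray
    confusion: np.ndarray
    fold: object = "aggregate"
    per_fold: Optional[List["EvalReport"]] = None

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_fscore(self) -> float:
        return float(self.fscore.mean())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def class_metric(self, cls, metric: str = "fscore") -> float:
        idx = int(np.nonzero(self.classes == cls)[0][0])
        return float(getattr(self, metric)[idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "class": list(self.classes) + ["macro"],
                "precision": list(self.precision) + [self.macro_precision],
                "recall": list(self.recall) + [self.macro_recall],
                "fscore": list(self.fscore) + [self.macro_fscore],
            }
        )
        frame["fold"] = str(self.fold)
        return frame

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Class × class count grid, rows = true class, columns = predicted."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def _safe_divide(num: np.ndarray, den: np.ndarray, what: str, classes) -> np.ndarray:
    out = np.zeros(len(num))
    nonzero = den > 0
    out[nonzero] = num[nonzero] / den[nonzero]
    for c in np.asarray(classes)[~nonzero]:
        warnings.warn(f"{what} undefined for class {c!r} (0/0); using 0", stacklevel=3)
    return out


def score(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: Optional[Sequence] = None,
    fold: object = "aggregate",
) -> EvalReport:
    """Per-class precision, recall and F-score of one prediction run.

    ``classes`` fixes the class set and order (needed when a fold might
    miss a class); by default it is the sorted union of labels seen.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise InvalidInputError("true and predicted label sequences differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    cm = confusion_counts(y_true, y_pred, classes)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision = _safe_divide(tp, tp + fp, "precision", classes)
    recall = _safe_divide(tp, tp + fn, "recall", classes)
    fscore = _safe_divide(2 * precision * recall, precision + recall, "F-score", classes)
    return EvalReport(
        classes=classes,
        precision=precision,
        recall=recall,
        fscore=fscore,
        confusion=cm,
        fold=fold,
    )


def cross_validate(
    spec: ClassifierSpec,
    features: FeatureMatrix,
    folds: FoldSplit,
    seed: int = 0,
    pooled: bool = False,
) -> EvalReport:
    """k-fold cross-validation of one classifier on one feature view.

    Each fold is held out once while the classifier trains on the other
    k−1 folds. By default per-class metrics are averaged over folds
    (unweighted) and the confusion matrix is the sum over folds; with
    ``pooled=True`` the summed confusion matrix is scored directly
    instead.
    """
    if len(folds.assignments) != len(features):
        raise InvalidInputError("fold assignment length does not match feature rows")
    classes = np.unique(features.y)
    reports: List[EvalReport] = []
    for fold in range(folds.k):
        train_mask, test_mask = folds.train_test(fold)
        model = train_classifier(spec, features.X[train_mask], features.y[train_mask], seed=seed)
        y_pred = model.predict(features.X[test_mask])
        reports.append(score(features.y[test_mask], y_pred, classes=classes, fold=fold))
    confusion = np.sum([r.confusion for r in reports], axis=0)
    if pooled:
        tp = np.diag(confusion).astype(float)
        fp = confusion.sum(axis=0) - tp
        fn = confusion.sum(axis=1) - tp
        precision = _safe_divide(tp, tp + fp, "precision", classes)
        recall = _safe_divide(tp, tp + fn, "recall", classes)
        fscore = _safe_divide(2 * precision * recall, precision + recall, "F-score", classes)
    else:
        precision = np.mean([r.precision for r in reports], axis=0)
        recall = np.mean([r.recall for r in reports], axis=0)
        fscore = np.mean([r.fscore for r in reports], axis=0)
    return EvalReport(
        classes=classes,
        precision=precision,
        recall=recall,
        fscore=fscore,
        confusion=confusion,
        fold="cv-mean",
        per_fold=reports,
    )


@dataclass
class ComparisonReport:
    """Cross-validated reports per (classifier kind, view) plus deltas.

    ``deltas[kind]`` is the macro F-score gain of the quaternion view
    over the raw view for that classifier. Both views share one fold
    assignment, so the comparison is paired.
    """

    reports: Dict[Tuple[str, str], EvalReport]
    deltas: Dict[str, float]
    k: int
    seed: int

    def macro_fscore(self, kind: str, view: str) -> float:
        return self.reports[(kind, view)].macro_fscore

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (kind, view), report in self.reports.items():
            row = {"classifier": kind, "view": view}
            for c, p, r, f in zip(
                report.classes, report.precision, report.recall, report.fscore
            ):
                row[f"precision_{c}"] = p
                row[f"recall_{c}"] = r
                row[f"fscore_{c}"] = f
            row["macro_precision"] = report.macro_precision
            row["macro_recall"] = report.macro_recall
            row["macro_fscore"] = report.macro_fscore
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Plain-text grid: per-class P/R/F for each classifier × view."""
        lines = []
        kinds = sorted({kind for kind, _ in self.reports})
        views = sorted({view for _, view in self.reports})
        for kind in kinds:
            lines.append(f"{kind} performance")
            header = f"{'class':<10}" + "".join(
                f"{v + ' P':>10}{v + ' R':>10}{v + ' F':>10}" for v in views
            )
            lines.append(header)
            classes = next(iter(self.reports.values())).classes
            for i, c in enumerate(classes):
                cells = ""
                for v in views:
                    r = self.reports[(kind, v)]
                    cells += f"{r.precision[i]:>10.2f}{r.recall[i]:>10.2f}{r.fscore[i]:>10.2f}"
                lines.append(f"{c:<10}" + cells)
            cells = ""
            for v in views:
                r = self.reports[(kind, v)]
                cells += (
                    f"{r.macro_precision:>10.2f}{r.macro_recall:>10.2f}{r.macro_fscore:>10.2f}"
                )
            lines.append(f"{'average':<10}" + cells)
            lines.append("")
        return "\n".join(lines)


def compare_views(
    dataset: LabeledDataset,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    k: int = 10,
    seed: int = 0,
    views: Sequence[str] = ("quat4", "raw6"),
) -> ComparisonReport:
    """Run the central experiment: every classifier on every view.

    Builds the requested feature views over the same dataset, draws one
    stratified fold assignment shared by all views (rows line up across
    views), cross-validates every classifier spec on each view, and
    tabulates the per-class and macro F-scores plus quaternion-vs-raw
    deltas.
    """
    if specs is None:
        specs = default_specs()
    matrices = {view: build_features(dataset, view) for view in views}
    first = next(iter(matrices.values()))
    folds = kfold_split(first, k=k, seed=seed)
    reports: Dict[Tuple[str, str], EvalReport] = {}
    for spec in specs:
        for view, fm in matrices.items():
            reports[(spec.kind, view)] = cross_validate(spec, fm, folds, seed=seed)
    deltas = {}
    if "quat4" in views and "raw6" in views:
        for spec in specs:
            deltas[spec.kind] = (
                reports[(spec.kind, "quat4")].macro_fscore
                - reports[(spec.kind, "raw6")].macro_fscore
            )
    return ComparisonReport(reports=reports, deltas=deltas, k=k, seed=seed)
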