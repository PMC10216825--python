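"""One-vs-all KNN/SVM evaluation of the scalar quantifier feature.

Each of the four emotion classes is evaluated as a binary problem (class c
versus the rest) with stratified k-fold cross-validation.  Confusion
counts are pooled over the folds (micro-averaging; per-fold macro
averaging is available) and converted to the three reported metrics:

    AC = (TP + TN) / (TP + TN + FP + FN) · 100
    SE = TP / (TP + FN) · 100
    F1 = 2·TP / (2·TP + FP + FN) · 100

:func:`sweep` runs the full grid the reporting mirrors: K = 1..20 for KNN
and k-fold = 2..20 for both classifiers, and summarizes each class by the
configuration attaining the highest accuracy.

Classifier details the underlying method leaves open and that are fixed
here: KNN uses Euclidean distance on the 1-D normalized feature with
voting ties broken toward the positive class; the SVM uses an RBF kernel
with scikit-learn defaults (a linear kernel is selectable).  Folds are
stratified on the four-class labels with a fixed seed so every one-vs-all
task sees both classes in every training fold whenever each class has at
least k members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .quantifier import FeatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PerformanceTable",
    "StratificationError",
    "evaluate_ova",
    "metrics",
    "sweep",
]


class StratificationError(ValueError):
    """Raised when a training fold contains a single class."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Accuracy, sensitivity and F1 score in percent.

    Undefined ratios (no positives for SE, no predicted-or-actual
    positives for F1) are reported as NaN with a warning.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    ac = 100.0 * (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fn == 0:
        warnings.warn("SE undefined: no positive samples (TP + FN = 0)")
        se = float("nan")
    else:
        se = 100.0 * counts.tp / (counts.tp + counts.fn)
    if 2 * counts.tp + counts.fp + counts.fn == 0:
        warnings.warn("F1 undefined: 2·TP + FP + FN = 0")
        f1 = float("nan")
    else:
        f1 = 100.0 * 2 * counts.tp / (2 * counts.tp + counts.fp + counts.fn)
    return ac, se, f1


def _make_classifier(classifier: str, K: int | None, kernel: str):
    if classifier == "knn":
        if K is None or K < 1:
            raise ValueError(f"KNN requires a neighbor count K >= 1, got {K}")
        return KNeighborsClassifier(n_neighbors=K, metric="euclidean")
    if classifier == "svm":
        return SVC(kernel=kernel)
    raise ValueError(f"classifier must be 'knn' or 'svm', got {classifier!r}")


def _predict(model, X: np.ndarray) -> np.ndarray:
    # KNN voting ties (possible at even K) are broken toward the positive
    # class: predict positive whenever at least half the neighbors are.
    if isinstance(model, KNeighborsClassifier) and len(model.classes_) == 2:
        proba = model.predict_proba(X)
        return model.classes_[(proba[:, 1] >= 0.5).astype(int)]
    return model.predict(X)


def _fold_indices(
    class_ids: np.ndarray, k_fold: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    splitter = StratifiedKFold(n_splits=k_fold, shuffle=True, random_state=seed)
    try:
        return list(splitter.split(np.zeros((len(class_ids), 1)), class_ids))
    except ValueError as exc:
        raise StratificationError(
            f"cannot build {k_fold} stratified folds: {exc}"
        ) from exc


def evaluate_ova(
    features: FeatureVector,
    classifier: str = "knn",
    K: int | None = 5,
    k_fold: int = 10,
    seed: int = 0,
    kernel: str = "rbf",
    pooling: str = "micro",
    classes: Sequence[int] | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Cross-validated one-vs-all evaluation at one (classifier, K, k).

    Returns one row per class with pooled AC/SE/F1.  Deterministic given
    the seed (which fixes the stratified fold assignment).
    """
    X = features.normalized.reshape(-1, 1)
    class_ids = features.class_ids
    present = sorted(np.unique(class_ids))
    if len(present) < 2:
        raise StratificationError("need at least 2 classes present to evaluate")
    if classes is None:
        classes = present
    if folds is None:
        folds = _fold_indices(class_ids, k_fold, seed)

    rows = []
    for c in classes:
        y = (class_ids == c).astype(int)
        pooled = ConfusionCounts(0, 0, 0, 0)
        per_fold_metrics = []
        for fold_no, (train, test) in enumerate(folds, start=1):
            y_train = y[train]
            if len(np.unique(y_train)) < 2:
                missing = "positive" if y_train.sum() == 0 else "negative"
                raise StratificationError(
                    f"training fold {fold_no}/{k_fold} has no {missing} "
                    f"samples for class {c}"
                )
            model = _make_classifier(classifier, K, kernel)
            model.fit(X[train], y_train)
            pred = _predict(model, X[test])
            y_test = y[test]
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (y_test == 1))),
                tn=int(np.sum((pred == 0) & (y_test == 0))),
                fp=int(np.sum((pred == 1) & (y_test == 0))),
                fn=int(np.sum((pred == 0) & (y_test == 1))),
            )
            pooled = pooled + counts
            if pooling == "macro":
                per_fold_metrics.append(metrics(counts))
        if pooling == "micro":
            ac, se, f1 = metrics(pooled)
        elif pooling == "macro":
            ac, se, f1 = (float(np.nanmean(m)) for m in zip(*per_fold_metrics))
        else:
            raise ValueError(f"pooling must be 'micro' or 'macro', got {pooling!r}")
        rows.append(
            {
                "class_id": c,
                "classifier": classifier,
                "K": K if classifier == "knn" else np.nan,
                "k_fold": k_fold,
                "AC": ac,
                "SE": se,
                "F1": f1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PerformanceTable:
    """Full sweep records plus the per-class best-accuracy summary."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Best accuracy per (classifier, class) with its K, k-fold, SE, F1.

        Ties are resolved toward the smallest k-fold, then the smallest K,
        so the summary is deterministic.
        """
        rec = self.records.sort_values(
            ["classifier", "class_id", "k_fold", "K"], na_position="first"
        )
        idx = rec.groupby(["classifier", "class_id"])["AC"].idxmax()
        cols = ["classifier", "class_id", "AC", "SE", "F1", "K", "k_fold"]
        return rec.loc[idx, cols].reset_index(drop=True)

    def to_csv_dir(self, out_dir: str | Path, prefix: str = "") -> list[Path]:
        """Write one records file per classifier plus a summary file."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for clf, group in self.records.groupby("classifier"):
            path = out_dir / f"{prefix}performance_{clf}.csv"
            group.to_csv(path, index=False)
            written.append(path)
        path = out_dir / f"{prefix}performance_summary.csv"
        self.summary().to_csv(path, index=False)
        written.append(path)
        return written


def sweep(
    features: FeatureVector,
    classifiers: Sequence[str] = ("knn", "svm"),
    K_range: Iterable[int] = range(1, 21),
    kfold_range: Iterable[int] = range(2, 21),
    seed: int = 0,
    kernel: str = "rbf",
    pooling: str = "micro",
) -> PerformanceTable:
    """Full Cartesian performance sweep.

    KNN is evaluated at every (K, k-fold) pair and the SVM at every
    k-fold; fold assignments are shared across K at a given k so KNN
    results differ only through the classifier.
    """
    K_range = list(K_range)
    kfold_range = list(kfold_range)
    if not kfold_range or (("knn" in classifiers) and not K_range):
        raise ValueError("parameter ranges must be non-empty")
    frames = []
    class_ids = features.class_ids
    for k in kfold_range:
        folds = _fold_indices(class_ids, k, seed)
        for clf in classifiers:
            if clf == "knn":
                for K in K_range:
                    frames.append(
                        evaluate_ova(
                            features, clf, K=K, k_fold=k, seed=seed,
                            pooling=pooling, folds=folds,
                        )
                    )
            else:
                frames.append(
                    evaluate_ova(
                        features, clf, K=None, k_fold=k, seed=seed,
                        kernel=kernel, pooling=pooling, folds=folds,
                    )
                )
    records = pd.concat(frames, ignore_index=True)
    return PerformanceTable(records=records)
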