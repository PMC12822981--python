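"""Fixed-hyperparameter classifiers, metrics, and patient-grouped CV.

Three classifiers with frozen hyperparameters are compared:

* kNN — k = 7, Euclidean distance, uniform weights;
* SVM — RBF kernel, C = 100, gamma = 1e-4, tol = 1e-3;
* LR  — L2 penalty, C = 1.0, tol = 1e-4, BFGS-family (lbfgs) solver.

Evaluation uses 5-fold cross-validation that is *stratified at the
patient level and grouped by patient*: all images of one patient land
in the same fold, and fold class proportions are balanced over
patients. This prevents the within-patient correlation of ROI images
from leaking between training and test folds. Per-fold accuracy,
precision, recall, F1, specificity and AUC are aggregated as
mean ± SD over folds. The positive class is the irregular (SCC-like)
texture class by default.

In the default ``safe`` mode, standardization and feature selection
are refitted inside each training fold; ``paper`` mode fits them once
on the full table before splitting, reproducing the order of
operations in which selection precedes cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FEATURE_SETS, feature_columns, feature_table
from .filters import apply_filter, FilterSpec
from .selection import ImportanceSelector, TableStandardizer

__all__ = [
    "CLASSIFIER_KINDS",
    "make_classifier",
    "ConfusionCounts",
    "confusion_metrics",
    "roc_auc",
    "fit_predict",
    "grouped_stratified_cv",
    "run_experiment",
    "CvReport",
]

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("knn", "svm", "lr")
METRICS = ("accuracy", "precision", "recall", "f1", "auc", "specificity")


def make_classifier(kind: str):
    """Instantiate one of the three frozen-hyperparameter classifiers."""
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=7, metric="euclidean", weights="uniform")
    if kind == "svm":
        return SVC(C=100.0, kernel="rbf", gamma=1e-4, tol=1e-3)
    if kind == "lr":
        # L2 penalty (the sklearn default; the explicit kwarg is deprecated)
        return LogisticRegression(tol=1e-4, C=1.0, solver="lbfgs", max_iter=2000)
    raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}, got {kind!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1, specificity and FPR from counts.

    Zero-denominator cases return 0 (with a logged warning), never raise.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    return {
        "accuracy": (tp + tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "f1": _safe_ratio(2 * precision * recall, precision + recall, "f1"),
        "specificity": _safe_ratio(tn, tn + fp, "specificity"),
        "fpr": _safe_ratio(fp, fp + tn, "fpr"),
    }


def roc_auc(labels, scores, positive=1) -> float:
    """Area under the ROC curve by pair-counting (ties get half credit).

    Equivalent to the normalized Mann–Whitney U statistic: the fraction
    of (positive, negative) pairs ranked correctly by ``scores``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def positive_scores(estimator, X, positive):
    """Continuous score for the positive class from a fitted classifier.

    Probability of the positive class for kNN/LR (neighbor-vote fraction
    and model probability, respectively); signed decision-function value
    for the SVM.
    """
    classes = list(estimator.classes_)
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} absent from training data")
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, classes.index(positive)]
    scores = estimator.decision_function(X)
    return scores if classes.index(positive) == 1 else -scores


def fit_predict(kind_or_estimator, X_train, y_train, X_test, positive):
    """Fit a classifier and return (predicted labels, positive-class scores)."""
    est = (
        make_classifier(kind_or_estimator)
        if isinstance(kind_or_estimator, str)
        else kind_or_estimator
    )
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    est.fit(np.asarray(X_train, dtype=float), y_train)
    X_test = np.asarray(X_test, dtype=float)
    return est.predict(X_test), positive_scores(est, X_test, positive)


@dataclass
class CvReport:
    """Per-fold metrics of one cross-validated experiment."""

    fold_metrics: pd.DataFrame  # one row per fold, columns = METRICS
    fold_assignment: pd.Series  # image index -> fold number
    mode: str
    classifier: str
    n_splits: int
    selected_features: tuple[tuple[str, ...], ...] = ()

    def mean(self, metric: str) -> float:
        return float(self.fold_metrics[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.fold_metrics[metric].std(ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in self.fold_metrics.columns}

    def __str__(self) -> str:
        parts = [
            f"{m} {mean:.2f} +/- {sd:.2f}" for m, (mean, sd) in self.summary().items()
        ]
        return f"CvReport[{self.classifier}, {self.mode}]: " + ", ".join(parts)


def _resolve_splits(y, groups, n_splits: int) -> int:
    frame = pd.DataFrame({"y": np.asarray(y), "g": np.asarray(groups)})
    per_class = frame.drop_duplicates("g").groupby("y").size()
    smallest = int(per_class.min())
    if smallest < 2:
        raise ValueError("need at least 2 patients per class for cross-validation")
    if smallest < n_splits:
        warnings.warn(
            f"only {smallest} patients in the smallest class; "
            f"reducing folds from {n_splits} to {smallest}",
            stacklevel=3,
        )
        return smallest
    return n_splits


def grouped_stratified_cv(
    X: pd.DataFrame,
    y,
    groups,
    classifier: str = "lr",
    n_splits: int = 5,
    seed: int = 42,
    mode: str = "safe",
    positive: str | int = "irregular",
    select_k: int | None = 25,
    n_trees: int = 100,
    selection_seed: int = 42,
    grouped: bool = True,
) -> CvReport:
    """Patient-grouped, patient-stratified k-fold evaluation.

    Parameters
    ----------
    X : DataFrame of shape (n_images, n_features)
        Raw (un-standardized) feature table.
    y : array-like
        Class label per image; all images of one patient share it.
    groups : array-like
        Patient identifier per image; no patient appears in two folds.
    mode : {"safe", "paper"}
        ``safe`` refits standardization and selection inside each
        training fold; ``paper`` fits them once on the full table first.
    select_k : int or None
        Top-k features to keep (None disables selection).
    grouped : bool
        If False, uses a plain image-level stratified split — only
        useful as a leakage demonstration control.
    """
    if mode not in ("safe", "paper"):
        raise ValueError("mode must be 'safe' or 'paper'")
    if classifier not in CLASSIFIER_KINDS:
        raise ValueError(f"classifier must be one of {CLASSIFIER_KINDS}")
    X = X.reset_index(drop=True) if isinstance(X, pd.DataFrame) else _require_frame(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    n_splits = _resolve_splits(y, groups, n_splits)
    if grouped:
        splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)

    if mode == "paper":
        full_std = TableStandardizer().fit(X)
        Xs_full = full_std.transform(X)
        if select_k is not None:
            full_sel = ImportanceSelector(
                k=select_k, n_trees=n_trees, seed=selection_seed
            ).fit(Xs_full, y)

    rows = []
    assignment = np.full(len(X), -1, dtype=int)
    selected_per_fold: list[tuple[str, ...]] = []
    for fold, (train_idx, test_idx) in enumerate(split_iter):
        assignment[test_idx] = fold
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        if mode == "safe":
            std = TableStandardizer().fit(X_tr)
            X_tr_s, X_te_s = std.transform(X_tr), std.transform(X_te)
            if select_k is not None:
                sel = ImportanceSelector(
                    k=select_k, n_trees=n_trees, seed=selection_seed
                ).fit(X_tr_s, y_tr)
                X_tr_s, X_te_s = sel.transform(X_tr_s), sel.transform(X_te_s)
                selected_per_fold.append(sel.selected_)
        else:
            X_tr_s, X_te_s = Xs_full.iloc[train_idx], Xs_full.iloc[test_idx]
            if select_k is not None:
                X_tr_s, X_te_s = full_sel.transform(X_tr_s), full_sel.transform(X_te_s)
                selected_per_fold.append(full_sel.selected_)
        pred, scores = fit_predict(classifier, X_tr_s, y_tr, X_te_s, positive)
        counts = ConfusionCounts.from_predictions(y_te, pred, positive)
        metrics = confusion_metrics(counts)
        metrics["auc"] = roc_auc(y_te, scores, positive)
        metrics["fold"] = fold
        rows.append(metrics)
    fold_metrics = pd.DataFrame(rows).set_index("fold")[list(METRICS)]
    return CvReport(
        fold_metrics=fold_metrics,
        fold_assignment=pd.Series(assignment, name="fold"),
        mode=mode,
        classifier=classifier,
        n_splits=n_splits,
        selected_features=tuple(selected_per_fold),
    )


def _require_frame(X) -> pd.DataFrame:
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def run_experiment(
    images: Sequence,
    image_types: Sequence[str] = ("raw", "normalize", "median"),
    feature_sets: Sequence[str] = FEATURE_SETS,
    classifiers: Sequence[str] = CLASSIFIER_KINDS,
    entropy_params=None,
    n_levels: int = 32,
    median_radius: int = 1,
    n_splits: int = 5,
    seed: int = 42,
    mode: str = "safe",
    positive: str = "irregular",
    select_k: int = 25,
    n_trees: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial grid: image types x feature sets x classifiers.

    Returns ``(grid, per_fold)``: the grid has one row per cell with
    mean and SD of every metric (27 rows for the full 3 x 3 x 3
    factorial) plus a ``best`` flag marking, per classifier/feature
    set/metric, the image type with the highest mean; ``per_fold``
    holds the raw fold-level metric values behind each cell.
    """
    images = list(images)
    labels = np.asarray([img.class_label for img in images])
    patients = np.asarray([img.patient_id for img in images])
    spec_by_type = {
        "raw": FilterSpec("none"),
        "normalize": FilterSpec("normalize"),
        "median": FilterSpec("median", median_radius=median_radius),
    }
    grid_rows = []
    fold_rows = []
    for image_type in image_types:
        if image_type not in spec_by_type:
            raise ValueError(f"unknown image type {image_type!r}")
        filtered = [apply_filter(img, spec_by_type[image_type]) for img in images]
        combined = feature_table(
            filtered, "combined", entropy_params=entropy_params, n_levels=n_levels
        )
        entropy_cols = [c for c in combined.columns if "_s" in c and c.split("_s")[0]
                        in ("SampEn2D", "FuzzEn2D", "PermEn2D", "DispEn2D", "DistEn2D")]
        stat_cols = [c for c in feature_columns(combined) if c not in entropy_cols]
        set_columns = {
            "statistical": stat_cols,
            "entropy": entropy_cols,
            "combined": stat_cols + entropy_cols,
        }
        for feature_set in feature_sets:
            X = combined[set_columns[feature_set]]
            for clf in classifiers:
                report = grouped_stratified_cv(
                    X,
                    labels,
                    patients,
                    classifier=clf,
                    n_splits=n_splits,
                    seed=seed,
                    mode=mode,
                    positive=positive,
                    select_k=min(select_k, X.shape[1]),
                    n_trees=n_trees,
                )
                row = {
                    "image_type": image_type,
                    "feature_set": feature_set,
                    "classifier": clf,
                }
                for metric in METRICS:
                    row[f"{metric}_mean"] = report.mean(metric)
                    row[f"{metric}_sd"] = report.sd(metric)
                grid_rows.append(row)
                per_fold = report.fold_metrics.reset_index()
                per_fold.insert(0, "image_type", image_type)
                per_fold.insert(1, "feature_set", feature_set)
                per_fold.insert(2, "classifier", clf)
                fold_rows.append(per_fold)
    grid = pd.DataFrame(grid_rows)
    per_fold = pd.concat(fold_rows, ignore_index=True)
    # per classifier/feature set/metric, flag the best image type (bold-max analog)
    for metric in METRICS:
        flag = np.zeros(len(grid), dtype=bool)
        for (_, _), sub in grid.groupby(["feature_set", "classifier"]):
            flag[sub[f"{metric}_mean"].idxmax()] = True
        grid[f"{metric}_best"] = flag
    return grid, per_fold


def format_grid(grid: pd.DataFrame) -> str:
    """Human-readable mean +/- SD table, one block per feature set."""
    lines = []
    for feature_set, sub in grid.groupby("feature_set", sort=False):
        lines.append(f"=== feature set: {feature_set} ===")
        for _, row in sub.iterrows():
            cells = [
                f"{m}={row[f'{m}_mean']:.2f}+/-{row[f'{m}_sd']:.2f}"
                + ("*" if row[f"{m}_best"] else "")
                for m in METRICS
            ]
            lines.append(
                f"  {row['classifier']:>4s} | {row['image_type']:<9s} | "
                + " ".join(cells)
            )
    return "\n".join(lines)
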