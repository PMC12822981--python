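"""Standardization and random-forest importance-based feature selection.

Feature selection follows the select-from-model protocol: a random
forest (100 trees, fixed seed) is fitted to the standardized feature
table and the ``k`` features with the highest mean impurity decrease
(Gini importance) are retained — by default the top 25. Ties at the
k-th rank are broken by a seeded shuffle of the column order, recorded
in the result, so the selection is deterministic and reproducible.

Both stages are sklearn-style transformers so they can be refitted
inside each cross-validation training fold (the leakage-safe default)
or fitted once on the full table (``paper`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionResult",
    "TableStandardizer",
    "ImportanceSelector",
    "select_top_k",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one importance-based selection."""

    selected: tuple[str, ...]  # descending importance
    importances: dict[str, float]
    k: int
    seed: int
    n_trees: int


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class TableStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise zero-mean / unit-SD standardization of a feature table.

    Thin wrapper over :class:`sklearn.preprocessing.StandardScaler`
    (population SD) that additionally records which columns were
    constant in the fitting table (``constant_columns_``; they transform
    to zeros) and validates the column schema on apply.
    """

    def fit(self, X, y=None) -> "TableStandardizer":
        frame = _as_frame(X)
        if frame.empty:
            raise ValueError("cannot standardize an empty table")
        self.columns_ = list(frame.columns)
        self.scaler_ = StandardScaler().fit(frame.to_numpy(dtype=float))
        self.constant_columns_ = [
            c for c, v in zip(self.columns_, self.scaler_.var_) if v == 0.0
        ]
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = _as_frame(X)
        if list(frame.columns) != self.columns_:
            raise ValueError("column schema does not match the fitted table")
        out = self.scaler_.transform(frame.to_numpy(dtype=float))
        return pd.DataFrame(out, columns=self.columns_, index=frame.index)


class ImportanceSelector(TransformerMixin, BaseEstimator):
    """Select the top-k features by random-forest importance.

    Parameters
    ----------
    k : int
        Number of features to keep (default 25); if ``k`` exceeds the
        number of columns, all features are kept.
    n_trees : int
        Forest size (default 100).
    seed : int
        Random state of the forest and of the tie-breaking shuffle
        (default 42).
    importance : {"impurity", "permutation"}
        Ranking criterion; mean impurity decrease by default.
    """

    def __init__(self, k: int = 25, n_trees: int = 100, seed: int = 42,
                 importance: str = "impurity") -> None:
        self.k = k
        self.n_trees = n_trees
        self.seed = seed
        self.importance = importance

    def fit(self, X, y) -> "ImportanceSelector":
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")
        frame = _as_frame(X)
        # canonical column order: forests are column-order sensitive, so the
        # selection is made order-invariant by always fitting in sorted order
        frame = frame.reindex(columns=sorted(frame.columns, key=str))
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("selection needs at least 2 classes in y")
        if not np.all(np.isfinite(frame.to_numpy(dtype=float))):
            raise ValueError("feature table contains non-finite values")
        forest = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.seed
        )
        forest.fit(frame.to_numpy(dtype=float), y)
        if self.importance == "impurity":
            imp = forest.feature_importances_
        else:
            imp = permutation_importance(
                forest, frame.to_numpy(dtype=float), y, random_state=self.seed
            ).importances_mean
        columns = list(frame.columns)
        # seeded shuffle recorded as the tie-break order at equal importance
        rng = np.random.default_rng(self.seed)
        tie_rank = np.empty(len(columns), dtype=int)
        tie_rank[rng.permutation(len(columns))] = np.arange(len(columns))
        order = sorted(range(len(columns)), key=lambda i: (-imp[i], tie_rank[i]))
        k = min(self.k, len(columns))
        self.forest_ = forest
        self.importances_ = {c: float(v) for c, v in zip(columns, imp)}
        self.selected_ = tuple(columns[i] for i in order[:k])
        self.tie_break_order_ = tuple(int(t) for t in tie_rank)
        return self

    def transform(self, X):
        frame = _as_frame(X)
        missing = [c for c in self.selected_ if c not in frame.columns]
        if missing:
            raise ValueError(f"columns missing from table: {missing}")
        return frame[list(self.selected_)]

    def result(self) -> SelectionResult:
        return SelectionResult(
            selected=self.selected_,
            importances=self.importances_,
            k=self.k,
            seed=self.seed,
            n_trees=self.n_trees,
        )


def select_top_k(X, y, k: int = 25, n_trees: int = 100, seed: int = 42) -> SelectionResult:
    """Functional wrapper: fit an :class:`ImportanceSelector` and return its result."""
    return ImportanceSelector(k=k, n_trees=n_trees, seed=seed).fit(X, y).result()
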