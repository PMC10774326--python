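"""Random-forest screening of indicator influence on nesting.

One classifier per species separates nesting (1) from non-nesting (0)
cells on the 22 indicators; the normalized feature importances rank the
indicators. Performance (precision/recall/F1) is deliberately evaluated
on the training rows themselves — the forest is used as a pattern
detector on a fixed dataset, not as a predictive model — so the reported
scores are optimistic by construction and labelled as such. Robustness
is checked by a 4-fold cross-validation comparing fold importances
against the full-model ranking, and a greedy, collinearity-aware rule
picks the per-species indicator subset carried into clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .registry import INDICATOR_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Forest hyperparameters (defaults sized for ~7% nesting prevalence)."""

    n_trees: int = 500
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    class_weight: str | None = "balanced"
    importance: str = "impurity"     # or "permutation"
    seed: int = 0
    indicator_columns: tuple = INDICATOR_COLUMNS


@dataclass
class ImportanceResult:
    species: str
    importance: pd.Series            # indicator -> relative importance (sums to 1)
    ranks: pd.Series                 # indicator -> 1..n (1 = most important)
    n_rows: int
    n_dropped: int
    importance_type: str


@dataclass
class PerformanceScores:
    precision: float
    recall: float
    f1: float
    evaluated_on: str = "training data (optimistic)"


@dataclass
class CVReport:
    species: str
    fold_importances: list           # 4 ImportanceResult
    consistency: list                # Spearman rank corr. of each fold vs full model
    fold_indices: list = field(default_factory=list)


def _design(table: pd.DataFrame, species: str, columns) -> tuple:
    label_col = f"nesting_{species}"
    if label_col not in table.columns:
        raise ValueError(f"table has no nesting flags for species {species!r}")
    cols = [c for c in columns if c in table.columns]
    sub = table[cols + [label_col]].dropna()
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.info("dropped %d rows with missing indicators for species %s", n_dropped, species)
    X = sub[cols].to_numpy(dtype=float)
    y = sub[label_col].to_numpy(dtype=int)
    return X, y, cols, sub.index, n_dropped


def _fit_forest(X, y, config: RFConfig, seed_offset: int = 0) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        max_depth=config.max_depth,
        class_weight=config.class_weight,
        random_state=config.seed + seed_offset,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _importances(rf, X, y, cols, config: RFConfig) -> pd.Series:
    if config.importance == "impurity":
        imp = rf.feature_importances_
    elif config.importance == "permutation":
        res = permutation_importance(rf, X, y, n_repeats=10, random_state=config.seed)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance type {config.importance!r}")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=cols, name="importance")


def _ranks(imp: pd.Series) -> pd.Series:
    order = np.lexsort((np.arange(len(imp)), -imp.to_numpy()))
    ranks = np.empty(len(imp), dtype=int)
    ranks[order] = np.arange(1, len(imp) + 1)
    return pd.Series(ranks, index=imp.index, name="rank")


def fit_importance(table: pd.DataFrame, species: str,
                   config: RFConfig | None = None):
    """Fit the per-species forest on all rows; returns
    (:class:`ImportanceResult`, :class:`PerformanceScores`)."""
    config = config or RFConfig()
    X, y, cols, _, n_dropped = _design(table, species, config.indicator_columns)
    if (y == 1).sum() == 0:
        raise ValueError(f"species {species!r} has zero nesting rows")
    if (y == 0).sum() == 0:
        raise ValueError(f"species {species!r} has zero non-nesting rows")
    rf = _fit_forest(X, y, config)
    imp = _importances(rf, X, y, cols, config)
    pred = rf.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    result = ImportanceResult(species=species, importance=imp, ranks=_ranks(imp),
                              n_rows=len(y), n_dropped=n_dropped,
                              importance_type=config.importance)
    return result, scores_from_confusion(tp, fp, fn)


def scores_from_confusion(tp: int, fp: int, fn: int) -> PerformanceScores:
    """Precision, recall and F1 from confusion counts.

    Zero denominators yield a 0 score with a warning rather than an
    error, so degenerate predictions stay reportable.
    """
    if tp + fp == 0:
        warnings.warn("no positive predictions: precision defined as 0", RuntimeWarning, stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive labels: recall defined as 0", RuntimeWarning, stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2.0 * precision * recall / (precision + recall)
    return PerformanceScores(precision=precision, recall=recall, f1=f1)


def cross_validate(table: pd.DataFrame, species: str,
                   config: RFConfig | None = None) -> CVReport:
    """Robustness check: four sub-models, each trained on three of four
    seeded disjoint partitions (75% of rows), compared to the full model
    by Spearman rank correlation of importances."""
    config = config or RFConfig()
    X, y, cols, idx, _ = _design(table, species, config.indicator_columns)
    n = len(y)
    if n < 8:
        raise ValueError(f"need at least 8 complete rows for 4-fold CV, got {n}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    folds = [np.sort(perm[i::4]) for i in range(4)]
    full_rf = _fit_forest(X, y, config)
    full_imp = _importances(full_rf, X, y, cols, config)
    fold_results, consistency = [], []
    for i, held in enumerate(folds):
        train = np.setdiff1d(np.arange(n), held)
        rf = _fit_forest(X[train], y[train], config, seed_offset=i + 1)
        imp = _importances(rf, X[train], y[train], cols, config)
        fold_results.append(ImportanceResult(species=species, importance=imp,
                                             ranks=_ranks(imp), n_rows=len(train),
                                             n_dropped=0, importance_type=config.importance))
        rho = spearmanr(imp.to_numpy(), full_imp.to_numpy()).statistic
        consistency.append(float(rho))
    return CVReport(species=species, fold_importances=fold_results,
                    consistency=consistency,
                    fold_indices=[idx[h].tolist() for h in folds])


def select_indicators(result: ImportanceResult, corr: pd.DataFrame,
                      n: int = 6, collinearity_cut: float = 0.9,
                      override: list | None = None) -> list:
    """Greedy influential-subset selection.

    Walk indicators by descending importance, skipping any whose
    absolute Spearman correlation with an already-selected indicator
    reaches ``collinearity_cut`` (importance spread over collinear pairs
    reflects one underlying process), stopping at ``n``. An explicit
    ``override`` list short-circuits the rule — the hook for choices
    made on expert judgment — and is returned verbatim.
    """
    if override is not None:
        return list(override)
    order = result.ranks.sort_values().index
    chosen: list = []
    for ind in order:
        if len(chosen) == n:
            break
        if any(abs(corr.loc[ind, c]) >= collinearity_cut for c in chosen
               if np.isfinite(corr.loc[ind, c])):
            continue
        chosen.append(ind)
    if len(chosen) < n:
        warnings.warn(
            f"only {len(chosen)} indicators available after collinearity pruning (requested {n})",
            RuntimeWarning, stacklevel=2)
    return chosen


def indicator_correlations(table: pd.DataFrame, columns=INDICATOR_COLUMNS) -> pd.DataFrame:
    """Spearman correlation matrix of indicators over cells (pairwise-complete)."""
    cols = [c for c in columns if c in table.columns]
    return table[cols].corr(method="spearman")
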