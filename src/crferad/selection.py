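"""Feature engineering: standardization, a three-way selection ensemble
(random-forest importance, ANOVA F-test, recursive feature elimination),
cross-validated search over the retained-feature count, the normalized-
importance cutoff, and a correlation/cluster report.

The three rankings are combined by mean reciprocal rank; the retained
count is chosen by the one-standard-error rule on a cross-validated
score curve over candidate counts (5..100 by default); and a final
cutoff keeps features whose normalized importance stays above a floor
(0.01), capped at 30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "standardize_features",
    "rank_features",
    "ensemble_ranking",
    "choose_feature_count",
    "apply_cutoff",
    "correlation_cluster_report",
    "select_biomarkers",
]

METHODS = ("model_importance", "anova_f", "rfe")


@dataclass(frozen=True)
class SelectionConfig:
    count_grid: tuple = tuple(range(5, 101, 5))
    cv_folds: int = 5
    importance_cutoff: float = 0.01
    max_keep: int = 30
    rfe_step: float = 0.1  # fraction of remaining features dropped per round
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.count_grid:
            raise ValueError("count_grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    selected_names: list
    importance_scores: np.ndarray  # normalized, descending, for selected
    chosen_count: int
    per_method_rankings: dict
    cv_score_by_count: dict = field(default_factory=dict)


def standardize_features(matrix: np.ndarray, feature_names=None):
    """Column-standardize a subjects x features matrix to mean 0, var 1.

    Constant columns cannot be standardized and are dropped with a
    warning.  Returns (standardized matrix, fitted scaler, kept indices);
    the scaler is reusable on held-out data.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    keep = np.where(matrix.std(axis=0) > 0)[0]
    if len(keep) < matrix.shape[1]:
        dropped = matrix.shape[1] - len(keep)
        warnings.warn(f"dropped {dropped} constant feature column(s)")
    scaler = StandardScaler().fit(matrix[:, keep])
    return scaler.transform(matrix[:, keep]), scaler, keep


def _normalize(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    # an infinite score (e.g. ANOVA F on a perfect separator) outranks
    # every finite one; give it a finite cap so normalization is defined
    cap = 10.0 * np.abs(finite).max() if finite.size and np.abs(finite).max() > 0 else 1.0
    scores = np.where(np.isposinf(scores), cap, scores)
    scores = np.where(np.isfinite(scores), scores, 0.0)
    scores = scores - scores.min() if scores.min() < 0 else scores
    total = scores.sum()
    return scores / total if total > 0 else np.full_like(scores, 1.0 / len(scores))


def rank_features(matrix: np.ndarray, labels, method: str, config: SelectionConfig | None = None):
    """Full feature ranking under one method.

    Returns (order, scores): ``order`` is the feature-index permutation by
    decreasing importance; ``scores`` are normalized to sum to 1 over all
    features (in original feature order).
    """
    config = config or SelectionConfig()
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to rank features")
    if method == "model_importance":
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=config.seed, n_jobs=1
        ).fit(matrix, labels)
        scores = forest.feature_importances_
    elif method == "anova_f":
        f_stat, _ = f_classif(matrix, labels)
        scores = f_stat
    elif method == "rfe":
        est = RandomForestClassifier(
            n_estimators=max(25, config.n_estimators // 4),
            random_state=config.seed, n_jobs=1,
        )
        rfe = RFE(est, n_features_to_select=1, step=config.rfe_step).fit(matrix, labels)
        # elimination order: later-eliminated (lower ranking_) = more important
        scores = 1.0 / rfe.ranking_.astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    scores = _normalize(scores)
    order = np.argsort(-scores, kind="stable")
    return order, scores


def ensemble_ranking(matrix, labels, config: SelectionConfig | None = None):
    """Mean-reciprocal-rank fusion of the three methods.

    Returns (order, fused scores normalized to sum 1, per-method orders).
    """
    config = config or SelectionConfig()
    n = np.asarray(matrix).shape[1]
    per_method = {}
    mrr = np.zeros(n)
    for method in METHODS:
        order, _ = rank_features(matrix, labels, method, config)
        per_method[method] = order
        ranks = np.empty(n)
        ranks[order] = np.arange(1, n + 1)
        mrr += 1.0 / ranks
    fused = _normalize(mrr / len(METHODS))
    return np.argsort(-fused, kind="stable"), fused, per_method


def choose_feature_count(matrix, labels, config: SelectionConfig | None = None):
    """Cross-validated search for the retained-feature count.

    For each k in the grid, the top-k ensemble features are scored by
    stratified k-fold CV of a seeded forest; the chosen count is the
    smallest k whose mean score is within one standard error of the best.
    """
    config = config or SelectionConfig()
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    order, fused, _ = ensemble_ranking(matrix, labels, config)
    n_feat = matrix.shape[1]
    curve = {}
    best_mean, best_se = -np.inf, 0.0
    for k in config.count_grid:
        kk = min(int(k), n_feat)
        if kk != k:
            warnings.warn(f"count {k} clipped to {kk} available features")
        cols = order[:kk]
        cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                             random_state=config.seed)
        forest = RandomForestClassifier(
            n_estimators=config.n_estimators // 2, random_state=config.seed, n_jobs=1
        )
        scores = cross_val_score(forest, matrix[:, cols], labels, cv=cv)
        curve[kk] = (float(scores.mean()), float(scores.std() / np.sqrt(len(scores))))
        if scores.mean() > best_mean:
            best_mean, best_se = scores.mean(), scores.std() / np.sqrt(len(scores))
    threshold = best_mean - best_se
    chosen = min(k for k, (m, _) in curve.items() if m >= threshold)
    return chosen, curve


def apply_cutoff(order, scores, names, config: SelectionConfig | None = None) -> SelectionResult:
    """Keep features with normalized importance >= cutoff, capped at max_keep."""
    config = config or SelectionConfig()
    order = np.asarray(order)
    scores = np.asarray(scores, dtype=float)
    kept = [i for i in order if scores[i] >= config.importance_cutoff][: config.max_keep]
    return SelectionResult(
        selected_names=[names[i] for i in kept],
        importance_scores=scores[kept],
        chosen_count=len(kept),
        per_method_rankings={},
    )


def correlation_cluster_report(matrix: np.ndarray, names):
    """Pearson correlations + average-linkage clustering on 1 - |r|.

    Zero-variance features are excluded with a warning.  Returns
    (correlation matrix, kept names, dendrogram leaf order).
    """
    matrix = np.asarray(matrix, dtype=float)
    keep = np.where(matrix.std(axis=0) > 0)[0]
    if len(keep) < matrix.shape[1]:
        warnings.warn("excluded zero-variance feature(s) from correlation report")
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant features")
    sub = matrix[:, keep]
    corr = np.corrcoef(sub, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard tiny asymmetries
    link = hierarchy.average(squareform(dist, checks=False))
    order = list(hierarchy.leaves_list(link))
    kept_names = [names[i] for i in keep]
    return corr, kept_names, order


def select_biomarkers(matrix, labels, names, config: SelectionConfig | None = None) -> SelectionResult:
    """End-to-end selection: ensemble rank, count search, cutoff."""
    config = config or SelectionConfig()
    order, fused, per_method = ensemble_ranking(matrix, labels, config)
    chosen_k, curve = choose_feature_count(matrix, labels, config)
    result = apply_cutoff(order[:chosen_k], fused, names, config)
    result.per_method_rankings = per_method
    result.cv_score_by_count = curve
    return result
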