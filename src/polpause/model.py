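"""Random-forest classification of pausing vs non-pausing sites.

The model distinguishes pause sites from distance-matched controls from
their genomic features. About 20% of the sites (stratified) are set aside
to tune the forest's hyperparameters (number of trees, maximum depth,
minimum samples to split, minimum samples per leaf); the remaining 80% are
scored by stratified k-fold cross-validation (default k = 10). Performance
is the area under the precision-recall curve (PR-AUC). Feature relevance is
permutation importance — the PR-AUC drop after shuffling one feature column
on held-out data — with a one-sided significance test (BH-corrected across
features) separating informative features from noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import FeatureMatrix
from .pda import bh_adjust

DEFAULT_GRID: Dict[str, List] = {
    "n_estimators": [100, 300, 500],
    "max_depth": [None, 10, 20],
    "min_samples_split": [2, 10],
    "min_samples_leaf": [1, 5],
}


@dataclass
class ModelConfig:
    tune_fraction: float = 0.2
    k_folds: int = 10
    grid: Dict[str, List] = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 0
    importance_repeats: int = 10
    alpha_importance: float = 0.05
    tune_cv: int = 3  # internal CV folds during grid search

    def __post_init__(self) -> None:
        if not 0 < self.tune_fraction < 1:
            raise ValueError("tune_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class ImportanceRecord:
    feature: str
    mean: float
    std: float
    p: float
    q: float = 1.0
    significant: bool = False


@dataclass
class ModelReport:
    hyperparameters: Dict[str, object]
    fold_pr_auc: List[float]
    importances: List[ImportanceRecord]
    n: int
    p: int

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_auc))

    def significant_features(self) -> List[str]:
        return [r.feature for r in self.importances if r.significant]

    def to_json(self, path: str) -> None:
        payload = {
            "hyperparameters": {k: v for k, v in self.hyperparameters.items()},
            "fold_pr_auc": self.fold_pr_auc,
            "mean_pr_auc": self.mean_pr_auc,
            "n": self.n,
            "p": self.p,
            "importances": [
                {"feature": r.feature, "mean": r.mean, "std": r.std,
                 "p": r.p, "q": r.q, "significant": r.significant}
                for r in self.importances],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# PR-AUC
# ---------------------------------------------------------------------------

def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise summation over
    score thresholds (ties grouped); equals average precision."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("PR-AUC needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Splitting, tuning, evaluation
# ---------------------------------------------------------------------------

def split_tune_rest(matrix: FeatureMatrix, config: ModelConfig
                    ) -> Tuple[pd.Index, pd.Index]:
    """Stratified, seeded split of site ids into (tune, evaluation) sets."""
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    tune_idx, rest_idx = train_test_split(
        matrix.data.index, test_size=1.0 - config.tune_fraction,
        stratify=y, random_state=config.seed)
    return pd.Index(tune_idx), pd.Index(rest_idx)


def _forest(params: Mapping[str, object], seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def _grid_candidates(grid: Mapping[str, List]) -> List[Dict[str, object]]:
    keys = sorted(grid)
    combos = []
    import itertools
    for values in itertools.product(*(grid[k] for k in keys)):
        combos.append(dict(zip(keys, values)))
    return combos


def _model_size_key(params: Mapping[str, object]) -> Tuple:
    """Tie-break ordering: prefer fewer trees, then shallower."""
    depth = params.get("max_depth")
    return (params.get("n_estimators", 0),
            np.inf if depth is None else depth)


def tune_hyperparameters(X: pd.DataFrame, y: pd.Series,
                         config: ModelConfig) -> Dict[str, object]:
    """Grid search scored by cross-validated PR-AUC on the tune set; ties
    broken toward the smaller model."""
    candidates = _grid_candidates(config.grid)
    if not candidates:
        raise ValueError("hyperparameter grid is empty")
    if len(candidates) == 1:
        return candidates[0]
    n_per_class = int(y.value_counts().min())
    n_splits = min(config.tune_cv, n_per_class)
    if n_splits < 2:  # tune set too small for internal CV
        return min(candidates, key=_model_size_key)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                         random_state=config.seed)
    results = []
    for params in candidates:
        scores = []
        for train, test in cv.split(X, y):
            clf = _forest(params, config.seed)
            clf.fit(X.iloc[train], y.iloc[train])
            s = clf.predict_proba(X.iloc[test])[:, 1]
            scores.append(pr_auc(s, y.iloc[test].to_numpy()))
        results.append((float(np.mean(scores)), params))
    best_score = max(r[0] for r in results)
    # tolerate float jitter when declaring ties
    tied = [p for s, p in results if s >= best_score - 1e-12]
    return min(tied, key=_model_size_key)


def cv_evaluate(X: pd.DataFrame, y: pd.Series, params: Mapping[str, object],
                k: int, seed: int) -> List[float]:
    """Per-fold PR-AUC under stratified k-fold cross-validation."""
    if k < 2:
        raise ValueError("k must be >= 2")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for train, test in cv.split(X, y):
        y_test = y.iloc[test].to_numpy()
        if len(np.unique(y_test)) < 2:
            raise ValueError("a fold lost one of the classes")
        clf = _forest(params, seed)
        clf.fit(X.iloc[train], y.iloc[train])
        out.append(pr_auc(clf.predict_proba(X.iloc[test])[:, 1], y_test))
    return out


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importances(X: pd.DataFrame, y: pd.Series,
                            params: Mapping[str, object],
                            config: ModelConfig) -> List[ImportanceRecord]:
    """Held-out permutation importance with significance filtering.

    For every cross-validation fold, the model is fit on the training part;
    on the held-out part each feature column is shuffled
    ``importance_repeats`` times and the importance is the baseline PR-AUC
    minus the permuted PR-AUC. Repeats within a fold share one fitted model
    and are therefore averaged before testing; across the per-fold means a
    one-sided one-sample t-test (mean > 0) is BH-corrected across features;
    q < ``alpha_importance`` with a positive mean marks a feature
    significant.
    """
    cv = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                         random_state=config.seed)
    rng = np.random.default_rng(config.seed)
    per_feature: Dict[str, List[float]] = {f: [] for f in X.columns}
    for train, test in cv.split(X, y):
        clf = _forest(params, config.seed)
        clf.fit(X.iloc[train], y.iloc[train])
        X_test = X.iloc[test].reset_index(drop=True)
        y_test = y.iloc[test].to_numpy()
        baseline = pr_auc(clf.predict_proba(X_test)[:, 1], y_test)
        for feature in X.columns:
            col = X_test[feature].to_numpy()
            drops = []
            for _ in range(config.importance_repeats):
                Xp = X_test.copy()
                Xp[feature] = rng.permutation(col)
                permuted = pr_auc(clf.predict_proba(Xp)[:, 1], y_test)
                drops.append(baseline - permuted)
            # one value per fold: repeats share the fold's fitted model
            per_feature[feature].append(float(np.mean(drops)))

    records = []
    for feature in X.columns:
        drops = np.asarray(per_feature[feature])
        mean = float(drops.mean())
        std = float(drops.std(ddof=1)) if len(drops) > 1 else 0.0
        if std == 0.0:
            p = 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
        else:
            p = float(scipy_stats.ttest_1samp(
                drops, 0.0, alternative="greater").pvalue)
        records.append(ImportanceRecord(feature, mean, std, p))
    q = bh_adjust([r.p for r in records])
    for r, qi in zip(records, q):
        r.q = float(qi)
        r.significant = bool(qi < config.alpha_importance and r.mean > 0)
    return records


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def fit_report(matrix: FeatureMatrix, config: Optional[ModelConfig] = None
               ) -> ModelReport:
    """Tune on ~20% of sites, cross-validate on the rest, and score feature
    importances; deterministic for a fixed config seed."""
    config = config or ModelConfig()
    tune_idx, rest_idx = split_tune_rest(matrix, config)
    X, y = matrix.data, matrix.labels
    params = tune_hyperparameters(X.loc[tune_idx], y.loc[tune_idx], config)
    folds = cv_evaluate(X.loc[rest_idx], y.loc[rest_idx], params,
                        config.k_folds, config.seed)
    importances = permutation_importances(X.loc[rest_idx], y.loc[rest_idx],
                                          params, config)
    return ModelReport(dict(params), folds, importances,
                       n=matrix.n, p=X.shape[1])
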