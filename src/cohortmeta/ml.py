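"""Random-forest classification harness for cross-cohort benchmarking.

Three evaluation regimes mirror standard multi-cohort practice:
within-dataset stratified cross-validation (the matrix diagonal),
dataset-to-dataset transfer (off-diagonals) and leave-one-dataset-out
(LODO, the extra bottom row), all scored by the area under the ROC
curve. Feature importance ranks are averaged over the LODO training
models only, so the ranking never sees a test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RfConfig",
    "CVResult",
    "PredictionMatrix",
    "select_eligible",
    "align_features",
    "run_cv",
    "run_transfer",
    "run_lodo",
    "cross_prediction_matrix",
]


@dataclass(frozen=True)
class RfConfig:
    """Randomised-tree ensemble and evaluation settings.

    Defaults follow the benchmarking convention for microbiome
    classifiers: 1000 trees, minimum leaf size 5, unlimited depth,
    sqrt(features) per split, Shannon-entropy impurity, 10-fold CV with
    10 random repetitions.
    """

    n_trees: int = 1000
    min_samples_leaf: int = 5
    max_depth: int | None = None
    max_features: str = "sqrt"
    criterion: str = "entropy"
    n_repeats: int = 10
    cv_folds: int = 10
    seed: int = 0
    #: df for AUC confidence intervals; None uses (number of AUCs - 1).
    #: The multi-cohort reporting convention sets df = D * 20 - 1 with D
    #: the number of datasets, applied literally by the matrix assembler.
    ci_df: int | None = None


@dataclass
class CVResult:
    mean_auc: float
    ci_low: float
    ci_high: float
    aucs: np.ndarray = field(repr=False)
    #: LODO only: average feature rank over the models trained while this
    #: dataset was held out (training data only, never the test set)
    ranking: "pd.Series | None" = field(default=None, repr=False)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _make_rf(config: RfConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_samples_leaf,
        max_depth=config.max_depth,
        max_features=config.max_features,
        criterion=config.criterion,
        random_state=seed,
        n_jobs=1,
    )


def _auc_ci(aucs: np.ndarray, df: int | None) -> tuple[float, float, float]:
    mean = float(np.mean(aucs))
    if df is None:
        df = len(aucs) - 1
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(len(aucs)) if df >= 1 else np.nan
    return mean, mean - half, mean + half


def select_eligible(
    meta: pd.DataFrame,
    exclude_antibiotics: bool = True,
    min_per_class: int = 20,
    per_class: bool = True,
) -> pd.DataFrame:
    """Samples and datasets usable for the classification experiments.

    Keeps the baseline (earliest) timepoint per mouse, optionally drops
    antibiotic-treated samples, and keeps only datasets with at least
    *min_per_class* samples in each diet class (``per_class=False``
    interprets the threshold as a total over both classes).
    """
    sub = meta.copy()
    if "timepoint" in sub.columns and sub["timepoint"].notna().any():
        tp = sub["timepoint"].fillna(-np.inf)
        baseline = tp.groupby(sub["mouse_id"]).transform("min")
        sub = sub[tp == baseline]
    if exclude_antibiotics and "antibiotics" in sub.columns:
        sub = sub[~sub["antibiotics"].fillna(False).astype(bool)]
    counts = (
        sub.groupby(["dataset_id", "diet_class"], observed=True).size().unstack(fill_value=0)
    )
    for cls in ("high_fat", "low_fat"):
        if cls not in counts.columns:
            counts[cls] = 0
    if per_class:
        ok = counts.index[(counts["high_fat"] >= min_per_class) & (counts["low_fat"] >= min_per_class)]
    else:
        both = (counts["high_fat"] > 0) & (counts["low_fat"] > 0)
        ok = counts.index[both & (counts.sum(axis=1) >= min_per_class)]
    return sub[sub["dataset_id"].isin(ok)]


def align_features(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union feature space; features absent from one table are zero-filled
    (absence in a relative-abundance profile is a true zero)."""
    union = train.columns.union(test.columns)
    return (
        train.reindex(columns=union, fill_value=0.0),
        test.reindex(columns=union, fill_value=0.0),
    )


def run_cv(X: pd.DataFrame, y, config: RfConfig) -> CVResult:
    """Stratified k-fold CV repeated n_repeats times; AUC per held-out fold."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes")
    n_min = int(min(np.bincount(pd.factorize(y)[0])))
    folds = config.cv_folds
    if n_min < folds:
        warnings.warn(
            f"smallest class has {n_min} samples; reducing folds to {n_min}",
            stacklevel=2,
        )
        folds = max(2, n_min)
    seeds = _child_seeds(config.seed, 2 * config.n_repeats)
    aucs = []
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seeds[2 * rep])
        for train_idx, test_idx in skf.split(Xv, y):
            clf = _make_rf(config, seeds[2 * rep + 1])
            clf.fit(Xv[train_idx], y[train_idx])
            score = clf.predict_proba(Xv[test_idx])[:, list(clf.classes_).index(1)]
            aucs.append(roc_auc_score(y[test_idx], score))
    mean, lo, hi = _auc_ci(np.asarray(aucs), config.ci_df)
    return CVResult(mean, lo, hi, np.asarray(aucs))


def run_transfer(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    config: RfConfig,
) -> CVResult:
    """Train on one cohort, test on another; mean AUC over n_repeats."""
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set has a single class; AUC undefined")
    Xtr, Xte = align_features(X_train, X_test)
    seeds = _child_seeds(config.seed, config.n_repeats)
    aucs = []
    for rep in range(config.n_repeats):
        clf = _make_rf(config, seeds[rep])
        clf.fit(Xtr.to_numpy(dtype=float), np.asarray(y_train))
        score = clf.predict_proba(Xte.to_numpy(dtype=float))[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc_score(y_test, score))
    mean, lo, hi = _auc_ci(np.asarray(aucs), config.ci_df)
    return CVResult(mean, lo, hi, np.asarray(aucs))


def run_lodo(
    datasets: Mapping[str, tuple[pd.DataFrame, Sequence]],
    config: RfConfig,
) -> tuple[dict[str, CVResult], pd.Series]:
    """Leave-one-dataset-out AUC per cohort plus averaged feature ranking.

    *datasets* maps dataset id -> (samples x features table, labels).
    The ranking averages, over every LODO training model, the rank of
    each feature by impurity importance (rank 1 = most important); it is
    computed from training data only.
    """
    if len(datasets) < 2:
        raise ValueError("LODO needs at least two datasets")
    ids = list(datasets)
    union = None
    for X, _ in datasets.values():
        union = X.columns if union is None else union.union(X.columns)
    seeds = _child_seeds(config.seed, len(ids) * config.n_repeats)
    results: dict[str, CVResult] = {}
    rank_sum = np.zeros(len(union))
    n_models = 0
    for i, held_out in enumerate(ids):
        X_test, y_test = datasets[held_out]
        X_test = X_test.reindex(columns=union, fill_value=0.0)
        train_parts = [
            datasets[d][0].reindex(columns=union, fill_value=0.0) for d in ids if d != held_out
        ]
        y_train = np.concatenate(
            [np.asarray(datasets[d][1]) for d in ids if d != held_out]
        )
        X_train = pd.concat(train_parts, axis=0).to_numpy(dtype=float)
        y_test = np.asarray(y_test)
        if len(np.unique(y_test)) < 2:
            warnings.warn(f"dataset {held_out!r} single-class; skipped", stacklevel=2)
            continue
        aucs = []
        local_rank = np.zeros(len(union))
        for rep in range(config.n_repeats):
            clf = _make_rf(config, seeds[i * config.n_repeats + rep])
            clf.fit(X_train, y_train)
            score = clf.predict_proba(X_test.to_numpy(dtype=float))[
                :, list(clf.classes_).index(1)
            ]
            aucs.append(roc_auc_score(y_test, score))
            local_rank += stats.rankdata(-clf.feature_importances_)
            n_models += 1
        rank_sum += local_rank
        mean, lo, hi = _auc_ci(np.asarray(aucs), config.ci_df)
        results[held_out] = CVResult(
            mean,
            lo,
            hi,
            np.asarray(aucs),
            ranking=pd.Series(local_rank / config.n_repeats, index=union),
        )
    ranking = pd.Series(rank_sum / max(n_models, 1), index=union, name="avg_rank")
    return results, ranking


@dataclass
class PredictionMatrix:
    """Train x test AUC grid: CV diagonal, transfer off-diagonals, LODO row."""

    auc: pd.DataFrame  # (D + 1) x D, last row "LODO"
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    ranking: pd.Series

    @property
    def lodo_mean(self) -> float:
        return float(self.auc.loc["LODO"].mean())

    def to_long(self) -> pd.DataFrame:
        rows = []
        for train_id in self.auc.index:
            for test_id in self.auc.columns:
                rows.append(
                    {
                        "train": train_id,
                        "test": test_id,
                        "auc": self.auc.loc[train_id, test_id],
                        "ci_low": self.ci_low.loc[train_id, test_id],
                        "ci_high": self.ci_high.loc[train_id, test_id],
                    }
                )
        return pd.DataFrame(rows)


def cross_prediction_matrix(
    datasets: Mapping[str, tuple[pd.DataFrame, Sequence]],
    config: RfConfig,
) -> PredictionMatrix:
    """Assemble the full cross-prediction grid for the given cohorts."""
    ids = list(datasets)
    if len(ids) < 2:
        raise ValueError("need at least two datasets")
    if config.ci_df is None:
        config = replace(config, ci_df=len(ids) * 20 - 1)
    auc = pd.DataFrame(np.nan, index=ids + ["LODO"], columns=ids)
    lo = auc.copy()
    hi = auc.copy()
    for train_id in ids:
        X_tr, y_tr = datasets[train_id]
        for test_id in ids:
            if train_id == test_id:
                res = run_cv(X_tr, y_tr, config)
            else:
                res = run_transfer(X_tr, y_tr, *datasets[test_id], config)
            auc.loc[train_id, test_id] = res.mean_auc
            lo.loc[train_id, test_id] = res.ci_low
            hi.loc[train_id, test_id] = res.ci_high
    lodo, ranking = run_lodo(datasets, config)
    for test_id, res in lodo.items():
        auc.loc["LODO", test_id] = res.mean_auc
        lo.loc["LODO", test_id] = res.ci_low
        hi.loc["LODO", test_id] = res.ci_high
    return PredictionMatrix(auc, lo, hi, ranking)
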