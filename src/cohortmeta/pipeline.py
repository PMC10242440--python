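"""End-to-end cross-cohort analyses.

Each entry point chains the specified stages: prevalence filtering ->
arcsine-square-root transform -> per-dataset covariate-adjusted models
-> meta-analytic pooling -> Benjamini-Yekutieli FDR, with the filter
applied *before* the correction so the FDR family equals the reported
feature set. Results are plain DataFrames ready to be written as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import (
    DEFAULT_COVARIATES,
    fit_dataset_lm,
    partial_spearman_matrix,
)
from .meta import (
    CorrelationRecord,
    by_fdr,
    lfc_meta,
    pool_correlations,
    random_effects_pool,
)
from .ml import PredictionMatrix, RfConfig, cross_prediction_matrix, select_eligible
from .profiles import (
    ProfileMatrix,
    arcsin_sqrt_transform,
    compute_prevalence,
    filter_features,
)
from .simulate import SyntheticSpec, generate

logger = logging.getLogger("cohortmeta")

__all__ = [
    "AnalysisConfig",
    "run_binary_meta",
    "run_correlation_meta",
    "run_ml",
    "select_top_features",
    "evaluate_trajectories",
    "binary_meta_replicate",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and options shared by the pipeline entry points.

    The detection filters mirror the reporting conventions of the
    cross-cohort analyses: features must exceed 20% average prevalence
    and be detected in at least 5 datasets for the binary meta-analysis,
    4 for the fat-percentage correlations and 3 for the diet-duration
    correlations; significance is called at BY-FDR < 0.2.
    """

    prevalence_threshold: float = 0.20
    min_datasets_binary: int = 5
    min_datasets_fat: int = 4
    min_datasets_duration: int = 3
    fdr_alpha: float = 0.2
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    detection_threshold: float = 0.0
    rf: RfConfig = field(default_factory=RfConfig)
    seed: int = 0


def _meta_frame(results) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results])
    if df.empty:
        return df
    df["q"] = by_fdr(df["p"].to_numpy())
    return df.reindex(
        df["pooled"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def run_binary_meta(
    profiles: ProfileMatrix,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    include_lfc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """High-fat vs low-fat random-effects SMD meta-analysis.

    Returns (pooled table, per-dataset effect table, fold-change table),
    the pooled table sorted by |pooled effect| descending with BY q
    computed across the retained features only.
    """
    config = config or AnalysisConfig()
    prev = compute_prevalence(profiles, meta, config.detection_threshold)
    keep = filter_features(
        prev, config.prevalence_threshold, config.min_datasets_binary
    )
    logger.info("binary meta: %d/%d features pass filters", len(keep), len(prev.overall))
    if not keep:
        logger.warning("no feature passes the binary-analysis filters")
        empty = pd.DataFrame()
        return empty, empty, empty
    sub = profiles.subset_features(keep)
    feats_t = arcsin_sqrt_transform(sub)

    effect_rows = []
    for ds in pd.unique(meta["dataset_id"]):
        effect_rows.extend(
            fit_dataset_lm(feats_t, meta, ds, covariates=config.covariates)
        )
    effects = pd.DataFrame([asdict(e) for e in effect_rows])
    if effects.empty:
        logger.warning("no dataset produced usable effect estimates")
        return pd.DataFrame(), effects, pd.DataFrame()

    pooled = []
    for fid, grp in effects.groupby("feature_id", sort=False):
        if len(grp) < 2:
            logger.info("feature %s pooled in <2 datasets; dropped", fid)
            continue
        pooled.append(
            random_effects_pool(
                grp["d"].to_numpy(), grp["se_d"].to_numpy() ** 2, feature_id=fid
            )
        )
    smd = _meta_frame(pooled)

    lfc = pd.DataFrame()
    if include_lfc and not smd.empty:
        ab = sub.abundances
        diet = meta.loc[ab.columns, "diet_class"]
        ds_all = meta.loc[ab.columns, "dataset_id"]
        lfc_rows = []
        for _, row in smd.iterrows():
            fid = row["feature_id"]
            used = effects.loc[effects["feature_id"] == fid, "dataset_id"]
            per_dataset = {}
            for ds in used:
                in_ds = ds_all == ds
                per_dataset[ds] = (
                    ab.loc[fid, in_ds & (diet == "high_fat")].to_numpy(),
                    ab.loc[fid, in_ds & (diet == "low_fat")].to_numpy(),
                )
            res = lfc_meta(
                per_dataset, smd_sign=1 if row["pooled"] >= 0 else -1, feature_id=fid
            )
            lfc_rows.append(asdict(res))
        lfc = pd.DataFrame(lfc_rows)
    return smd, effects, lfc


def _covariate_matrix(
    sub_meta: pd.DataFrame, covariates: Sequence[str]
) -> np.ndarray | None:
    """Numeric covariate block for partial correlations (dummies for
    categoricals, constants dropped)."""
    cols = []
    for cov in covariates:
        values = sub_meta[cov]
        if values.nunique(dropna=False) <= 1:
            continue
        if values.dtype.kind in "fiu":
            cols.append(values.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(values.astype("category"), drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
    if not cols:
        return None
    return np.column_stack(cols)


def run_correlation_meta(
    profiles: ProfileMatrix,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    exposure: str = "fat_pct",
) -> pd.DataFrame:
    """Meta-analysis of partial Spearman correlations with an exposure.

    The exposure is ``fat_pct`` (controlling for the full covariate set
    plus diet duration) or ``duration_days`` (controlling for the full
    set plus fat percentage). Pooling happens on the Fisher-Z scale.
    """
    config = config or AnalysisConfig()
    if exposure == "fat_pct":
        min_ds = config.min_datasets_fat
        covariates = tuple(config.covariates) + ("duration_days",)
    elif exposure == "duration_days":
        min_ds = config.min_datasets_duration
        covariates = tuple(config.covariates) + ("fat_pct",)
    else:
        raise ValueError(f"unknown exposure {exposure!r}")

    prev = compute_prevalence(profiles, meta, config.detection_threshold)
    keep = filter_features(prev, config.prevalence_threshold, min_ds)
    if not keep:
        logger.warning("no feature passes the correlation-analysis filters")
        return pd.DataFrame()
    sub = profiles.subset_features(keep)
    feats_t = arcsin_sqrt_transform(sub)

    records: dict[str, list[CorrelationRecord]] = {fid: [] for fid in keep}
    for ds in pd.unique(meta["dataset_id"]):
        sub_meta = meta[meta["dataset_id"] == ds]
        samples = [s for s in sub_meta.index if s in feats_t.columns]
        sub_meta = sub_meta.loc[samples]
        x = sub_meta[exposure].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("dataset %s: exposure %s constant; skipped", ds, exposure)
            continue
        cov = _covariate_matrix(sub_meta, covariates)
        k = 0 if cov is None else cov.shape[1]
        if len(samples) - k - 2 < 1:
            logger.warning("dataset %s: too few samples for partials; skipped", ds)
            continue
        y = feats_t[samples].to_numpy(dtype=float).T
        rho, p = partial_spearman_matrix(y, x, cov)
        for fid, r_i, p_i in zip(keep, rho, p):
            if np.isfinite(r_i):
                records[fid].append(
                    CorrelationRecord(fid, ds, float(r_i), len(samples), k, float(p_i))
                )

    pooled = []
    for fid, recs in records.items():
        if len(recs) < 2:
            continue
        pooled.append(pool_correlations(recs, feature_id=fid))
    return _meta_frame(pooled)


def run_ml(
    profiles: ProfileMatrix,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    feature_sets: Sequence[str] = ("all", "known_only"),
    exclude_antibiotics: bool = True,
    min_per_class: int = 20,
) -> dict[str, PredictionMatrix]:
    """Cross-prediction matrices per feature set (all SGBs vs kSGBs only)."""
    config = config or AnalysisConfig()
    eligible = select_eligible(
        meta, exclude_antibiotics=exclude_antibiotics, min_per_class=min_per_class
    )
    if eligible["dataset_id"].nunique() < 2:
        raise ValueError("fewer than two eligible datasets for the ML experiments")
    feats_t = arcsin_sqrt_transform(profiles)
    out = {}
    for fs in feature_sets:
        if fs == "all":
            table = feats_t
        elif fs == "known_only":
            table = feats_t.loc[profiles.features["known"].to_numpy(dtype=bool)]
        else:
            raise ValueError(f"unknown feature set {fs!r}")
        datasets = {}
        for ds, grp in eligible.groupby("dataset_id", observed=True):
            samples = [s for s in grp.index if s in table.columns]
            X = table[samples].T  # samples x features
            y = (grp.loc[samples, "diet_class"] == "high_fat").to_numpy(dtype=int)
            datasets[ds] = (X, y)
        out[fs] = cross_prediction_matrix(datasets, config.rf)
    return out


def select_top_features(
    smd_table: pd.DataFrame,
    ranking: pd.Series,
    k: int = 8,
    fdr_alpha: float = 0.2,
    features: pd.DataFrame | None = None,
    unknown_only: bool = False,
) -> list[str]:
    """Top-k features by average LODO rank among significant pooled effects."""
    sig = smd_table[smd_table["q"] < fdr_alpha]["feature_id"]
    candidates = [f for f in sig if f in ranking.index]
    if unknown_only and features is not None:
        candidates = [f for f in candidates if not features.loc[f, "known"]]
    ordered = sorted(candidates, key=lambda f: ranking[f])
    return ordered[:k]


def evaluate_trajectories(
    profiles: ProfileMatrix,
    meta: pd.DataFrame,
    feature_ids: Sequence[str],
    phase_col: str = "phase",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse phase summaries and paired shift tests.

    For every mouse and phase, the mean square-root-scale abundance of
    the selected features; consecutive phases (in timepoint order) are
    compared with a two-sided Wilcoxon signed-rank test paired by mouse.
    Phases with no samples are skipped; an all-zero difference vector is
    reported as a missing p-value.
    """
    if meta[phase_col].nunique() < 2:
        raise ValueError("need at least two phases")
    sqrt_ab = np.sqrt(profiles.abundances.loc[list(feature_ids)])
    per_sample = sqrt_ab.mean(axis=0)
    df = meta.copy()
    df["signal"] = per_sample.reindex(df.index)

    # contiguous runs of one phase are distinct segments so a schedule may
    # revisit the same diet (e.g. LFD -> HFD -> LFD)
    tp_phase = (
        df[["timepoint", phase_col]]
        .drop_duplicates("timepoint")
        .sort_values("timepoint")
    )
    seg_of_tp: dict = {}
    seg_phase: list[str] = []
    for _, (tp, ph) in tp_phase.iterrows():
        if not seg_phase or seg_phase[-1] != ph:
            seg_phase.append(ph)
        seg_of_tp[tp] = len(seg_phase) - 1
    df["segment"] = df["timepoint"].map(seg_of_tp)

    summary = (
        df.groupby(["mouse_id", "segment"], observed=True)["signal"]
        .mean()
        .reset_index()
    )
    summary[phase_col] = summary["segment"].map(dict(enumerate(seg_phase)))
    wide = summary.pivot(index="mouse_id", columns="segment", values="signal")

    tests = []
    for a, b in zip(range(len(seg_phase) - 1), range(1, len(seg_phase))):
        if a not in wide.columns or b not in wide.columns:
            logger.warning("segment pair (%d, %d) has no samples; skipped", a, b)
            continue
        paired = wide[[a, b]].dropna()
        if paired.empty:
            logger.warning("segment pair (%d, %d): no paired mice; skipped", a, b)
            continue
        diff = paired[b] - paired[a]
        if np.allclose(diff, 0):
            p = np.nan
        else:
            p = float(stats.wilcoxon(paired[a], paired[b]).pvalue)
        tests.append(
            {
                "phase_from": seg_phase[a],
                "phase_to": seg_phase[b],
                "n_mice": len(paired),
                "median_shift": float(diff.median()),
                "p_wilcoxon": p,
            }
        )
    return summary, pd.DataFrame(tests)


def binary_meta_replicate(
    spec: SyntheticSpec,
    seed: int,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One generate -> binary-meta run with the truth merged back in.

    The workhorse of the parameter-recovery and error-control studies:
    returns the pooled table joined with each feature's true SMD and
    biomarker flag.
    """
    profiles, meta, truth = generate(replace(spec, seed=seed))
    smd, _, _ = run_binary_meta(profiles, meta, config, include_lfc=False)
    truth_df = pd.DataFrame(
        {
            "feature_id": truth.feature_ids,
            "true_smd": truth.true_smd,
            "biomarker": truth.biomarker,
        }
    )
    if smd.empty:
        return smd
    return smd.merge(truth_df, on="feature_id", how="left")
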