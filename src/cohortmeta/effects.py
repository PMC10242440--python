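"""Per-dataset, per-feature effect models.

Each dataset is analysed on its own: for every SGB an ordinary
least-squares model of the arcsine-square-root-transformed abundance on
the diet indicator plus curated covariates yields a t statistic for the
diet term, which is converted into a standardised mean difference
(Cohen's d scale) with its standard error. Continuous exposures (dietary
fat percentage, diet duration) are handled with partial Spearman
correlations: Pearson correlation of the rank-transformed response and
exposure after residualising both on the rank-transformed covariates.

All features of one dataset share a single design matrix, so the OLS
fits are computed as one multi-response least-squares solve; the t and p
values are identical to fitting each feature separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DatasetEffect",
    "CorrelationRecord",
    "DEFAULT_COVARIATES",
    "build_design",
    "fit_dataset_lm",
    "t_to_smd",
    "partial_spearman",
    "partial_spearman_matrix",
]

#: covariates adjusted for in the per-dataset models. Sex is included by
#: default (it can be dropped via the `covariates` argument); covariates
#: constant within a dataset are removed automatically before fitting.
DEFAULT_COVARIATES = ("age_days", "sex", "strain", "body_site", "antibiotics")

_CATEGORICAL = {"sex", "strain", "body_site", "antibiotics"}


@dataclass
class DatasetEffect:
    """Diet-term effect of one feature in one dataset."""

    feature_id: str
    dataset_id: str
    t: float
    df: int
    n1: int  # high-fat group size
    n2: int  # low-fat group size
    d: float
    se_d: float
    p_wald: float


@dataclass
class CorrelationRecord:
    """Partial Spearman correlation of one feature with an exposure."""

    feature_id: str
    dataset_id: str
    rho: float
    n: int
    n_covariates: int
    p: float


def build_design(
    meta: pd.DataFrame,
    covariates: Sequence[str],
    diet_col: str = "diet_class",
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, diet, covariates...] for one dataset.

    The diet indicator codes high_fat = 1. Categorical covariates are
    one-hot encoded against a first-level reference; covariates constant
    within the dataset are dropped with a warning.
    """
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    diet = (meta[diet_col] == "high_fat").to_numpy(dtype=float)
    cols.append(diet)
    names.append("diet")
    for cov in covariates:
        values = meta[cov]
        if values.nunique(dropna=False) <= 1:
            warnings.warn(
                f"covariate {cov!r} constant within dataset; dropped", stacklevel=2
            )
            continue
        if cov in _CATEGORICAL or values.dtype == object or values.dtype == bool:
            dummies = pd.get_dummies(values.astype("category"), drop_first=True)
            for level in dummies.columns:
                cols.append(dummies[level].to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(values.to_numpy(dtype=float))
            names.append(cov)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns by greedy QR-based elimination
        _, r = np.linalg.qr(x)
        bad = [names[i] for i in range(x.shape[1]) if abs(r[i, i]) < 1e-8]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear term(s): {bad or names}"
        )
    return x, names


def fit_dataset_lm(
    features_t: pd.DataFrame,
    meta: pd.DataFrame,
    dataset_id: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    diet_col: str = "diet_class",
) -> list[DatasetEffect]:
    """OLS of every (transformed) feature on diet + covariates in one dataset.

    Parameters
    ----------
    features_t:
        Feature x sample matrix of arcsine-square-root-transformed
        abundances (all samples, or only this dataset's).
    meta:
        Sample metadata indexed by sample_id.
    dataset_id:
        Dataset to fit; its samples are selected from *meta*.

    Returns one :class:`DatasetEffect` per feature with non-degenerate
    variance. Features constant within the dataset are skipped with a
    warning (a missing record, not t = 0).
    """
    sub = meta[meta["dataset_id"] == dataset_id]
    samples = [s for s in sub.index if s in features_t.columns]
    sub = sub.loc[samples]
    n1 = int((sub[diet_col] == "high_fat").sum())
    n2 = int((sub[diet_col] == "low_fat").sum())
    if n1 < 2 or n2 < 2:
        warnings.warn(
            f"dataset {dataset_id!r} lacks two samples in each diet class; skipped",
            stacklevel=2,
        )
        return []

    x, names = build_design(sub, covariates, diet_col)
    y = features_t[samples].to_numpy(dtype=float).T  # n x F
    n, p = x.shape
    df = n - p
    if df < 1:
        warnings.warn(f"dataset {dataset_id!r}: no residual df; skipped", stacklevel=2)
        return []

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # p x F
    resid = y - x @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    j = names.index("diet")
    var_scale = xtx_inv[j, j]

    results: list[DatasetEffect] = []
    feature_ids = list(features_t.index)
    y_range = y.max(axis=0) - y.min(axis=0)
    for f_idx, fid in enumerate(feature_ids):
        if y_range[f_idx] == 0:
            warnings.warn(
                f"feature {fid!r} constant in dataset {dataset_id!r}; skipped",
                stacklevel=2,
            )
            continue
        se = np.sqrt(sigma2[f_idx] * var_scale)
        t = beta[j, f_idx] / se if se > 0 else np.nan
        if not np.isfinite(t):
            continue
        p_wald = 2 * stats.t.sf(abs(t), df)
        d, se_d = t_to_smd(t, n1, n2, df)
        results.append(
            DatasetEffect(
                feature_id=fid,
                dataset_id=dataset_id,
                t=float(t),
                df=int(df),
                n1=n1,
                n2=n2,
                d=float(d),
                se_d=float(se_d),
                p_wald=float(p_wald),
            )
        )
    return results


def t_to_smd(t, n1: int, n2: int, df: int):
    """Standardised mean difference (Cohen's d scale) from a model t value.

    d    = t (n1 + n2) / (sqrt(n1 n2) sqrt(df))
    se_d = sqrt( ((n1 + n2 - 1) / (n1 + n2 - 3)) * (4 / (n1 + n2)) * (1 + d^2 / 8) )

    The se uses the adjusted small-sample form; it is centralised here so
    an alternative variant can be swapped in one place.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    if df < 1:
        raise ValueError("df must be >= 1")
    m = n1 + n2
    if m <= 3:
        raise ValueError("SE undefined for n1 + n2 <= 3")
    t = np.asarray(t, dtype=float)
    d = t * m / (np.sqrt(n1 * n2) * np.sqrt(df))
    se_d = np.sqrt(((m - 1) / (m - 3)) * (4.0 / m) * (1.0 + d**2 / 8.0))
    if d.ndim == 0:
        return float(d), float(se_d)
    return d, se_d


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def partial_spearman_matrix(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Spearman rho and p of each column of *y* with *x*.

    All variables are rank-transformed (average ranks on ties); ranked y
    and ranked x are residualised on an intercept plus the ranked
    covariates, and rho is the Pearson correlation of the residuals. p
    comes from the t transform with n - n_covariates - 2 df. Columns of y
    (or an x) with zero variance yield NaN.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    n = y.shape[0]
    k = 0 if covariates is None or covariates.size == 0 else covariates.shape[1]
    df = n - k - 2
    if df < 1:
        raise ValueError("insufficient samples for partial correlation")

    ry = _rank(y, axis=0)
    rx = _rank(np.asarray(x, dtype=float))
    z = np.ones((n, 1))
    if k:
        z = np.hstack([z, _rank(np.asarray(covariates, dtype=float), axis=0)])
    q, _ = np.linalg.qr(z)
    proj = lambda a: a - q @ (q.T @ a)  # noqa: E731
    ey = proj(ry)
    ex = proj(rx[:, None])[:, 0]

    sy = np.sqrt((ey**2).sum(axis=0))
    sx = np.sqrt((ex**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ey.T @ ex) / (sy * sx)
    rho = np.where((sy <= 1e-12) | (sx <= 1e-12), np.nan, rho)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = rho * np.sqrt(df / (1.0 - rho**2))
    p = np.where(
        np.isnan(rho), np.nan, np.where(np.abs(rho) >= 1, 0.0, 2 * stats.t.sf(np.abs(tval), df))
    )
    return rho, p


def partial_spearman(
    y,
    x,
    covariates=None,
    feature_id: str = "",
    dataset_id: str = "",
) -> CorrelationRecord:
    """Partial Spearman correlation of one feature with one exposure."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cov = None
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        k = cov.shape[1]
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        warnings.warn("constant variable: partial Spearman undefined", stacklevel=2)
        return CorrelationRecord(feature_id, dataset_id, np.nan, len(y), k, np.nan)
    rho, p = partial_spearman_matrix(y[:, None], x, cov)
    return CorrelationRecord(
        feature_id, dataset_id, float(rho[0]), len(y), k, float(p[0])
    )
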