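"""Meta-analytic pooling of per-dataset effects.

Standardised mean differences are pooled with a random-effects model:
between-study variance tau^2 by the iterative Paule-Mandel moment
estimator, weights 1/(v_i + tau^2), normal-theory 95% confidence
intervals. Log2 fold changes are pooled with a fixed-effect model whose
reporting conventions (meta SE divided by sqrt(k), t-quantile CI) follow
the originating analysis exactly; a flag restores the standard
fixed-effect SE. Correlations are pooled on the Fisher-Z scale with
variance 1/(n - n_covariates - 3) and back-transformed. Multiple testing
uses the Benjamini-Yekutieli step-up procedure, which is valid under
arbitrary dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .effects import CorrelationRecord

__all__ = [
    "MetaResult",
    "LfcMetaResult",
    "paule_mandel_tau2",
    "dersimonian_laird_tau2",
    "random_effects_pool",
    "fixed_effects_pool",
    "lfc_meta",
    "fisher_z",
    "inverse_fisher_z",
    "pool_correlations",
    "by_fdr",
]

_Z975 = 1.959963984540054


@dataclass
class MetaResult:
    """Pooled effect for one feature."""

    feature_id: str
    k: int
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    Q_het: float
    q: float = field(default=np.nan)  # BY-adjusted p, filled in later


@dataclass
class LfcMetaResult:
    """Pooled log2 fold change for one feature, linear scale included."""

    feature_id: str
    k: int
    pooled_log2fc: float
    se: float
    ci_low: float
    ci_high: float
    fold_change: float
    fc_ci_low: float
    fc_ci_high: float
    direction_sign: int


def dersimonian_laird_tau2(effects: np.ndarray, variances: np.ndarray) -> float:
    w = 1.0 / variances
    mu = (w * effects).sum() / w.sum()
    q = (w * (effects - mu) ** 2).sum()
    k = len(effects)
    c = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0


def paule_mandel_tau2(
    effects,
    variances,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """Between-study variance by the Paule-Mandel moment estimator.

    Iteratively solves sum_i w_i(tau2) (y_i - mu(tau2))^2 = k - 1 with
    w_i = 1/(v_i + tau2), truncating at 0. Falls back to the
    DerSimonian-Laird estimate with a warning if the iteration does not
    converge.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("Paule-Mandel needs at least two studies")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")

    def gen_q(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return (w * (y - mu) ** 2).sum()

    if gen_q(0.0) <= k - 1:
        return 0.0
    tau2 = dersimonian_laird_tau2(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        q = (w * (y - mu) ** 2).sum()
        denom = (w**2 * (y - mu) ** 2).sum()
        if denom <= 0:
            break
        step = (q - (k - 1)) / denom
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    warnings.warn(
        "Paule-Mandel did not converge; using DerSimonian-Laird", stacklevel=2
    )
    return dersimonian_laird_tau2(y, v)


def fixed_effects_pool(effects, variances) -> tuple[float, float]:
    """Inverse-variance weighted mean and its standard error."""
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) == 0:
        raise ValueError("no studies to pool")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    pooled = (w * y).sum() / w.sum()
    se = 1.0 / np.sqrt(w.sum())
    return float(pooled), float(se)


def random_effects_pool(
    effects,
    variances,
    feature_id: str = "",
    tau2: float | None = None,
) -> MetaResult:
    """Random-effects pooled effect with Paule-Mandel heterogeneity.

    With *tau2* given (e.g. forced to 0) the estimator is bypassed; with
    tau2 = 0 the result equals the fixed-effect pool exactly. Cochran's Q
    is computed with fixed-effect weights regardless.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = len(y)
    if k == 0:
        raise ValueError("no studies to pool")
    if tau2 is None:
        tau2 = paule_mandel_tau2(y, v) if k >= 2 else 0.0
    w_fe = 1.0 / v
    mu_fe = (w_fe * y).sum() / w_fe.sum()
    q_het = float((w_fe * (y - mu_fe) ** 2).sum())
    w = 1.0 / (v + tau2)
    pooled = (w * y).sum() / w.sum()
    se = 1.0 / np.sqrt(w.sum())
    z = pooled / se
    p = 2 * stats.norm.sf(abs(z))
    return MetaResult(
        feature_id=feature_id,
        k=k,
        pooled=float(pooled),
        se=float(se),
        ci_low=float(pooled - _Z975 * se),
        ci_high=float(pooled + _Z975 * se),
        z=float(z),
        p=float(p),
        tau2=float(tau2),
        Q_het=q_het,
    )


def lfc_meta(
    per_dataset: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    smd_sign: int,
    feature_id: str = "",
    eps: float = 1e-4,
    printed_se: bool = True,
) -> LfcMetaResult:
    """Fixed-effect meta-analysis of log2 fold changes for one feature.

    *per_dataset* maps dataset id -> (high-fat abundances, low-fat
    abundances). Zeros are replaced by *eps* (0.0001) before the log2;
    the numerator group of the fold change is the one favoured by the
    SMD sign (high-fat first when the pooled standardised mean
    difference is positive). The per-dataset variance is the sum of the
    two group-mean variances. The meta SE is, as conventionally printed
    here, the fixed-effect SE divided by sqrt(k), and the CI uses the
    t quantile with k - 1 df; set ``printed_se=False`` for the standard
    fixed-effect SE with a normal CI.
    """
    sign = 1 if smd_sign >= 0 else -1
    lfcs, variances = [], []
    for ds, (high, low) in per_dataset.items():
        high = np.asarray(high, dtype=float)
        low = np.asarray(low, dtype=float)
        if high.size == 0 or low.size == 0:
            warnings.warn(f"dataset {ds!r}: empty diet group; excluded", stacklevel=2)
            continue
        first, second = (high, low) if sign > 0 else (low, high)
        lf = np.log2(np.where(first == 0, eps, first))
        ls = np.log2(np.where(second == 0, eps, second))
        lfc = lf.mean() - ls.mean()
        var = lf.var(ddof=1) / len(lf) + ls.var(ddof=1) / len(ls)
        if var <= 0:
            var = 1e-12  # degenerate groups (all values identical)
        lfcs.append(lfc)
        variances.append(var)
    k = len(lfcs)
    if k == 0:
        raise ValueError("no dataset contributed to the fold-change meta-analysis")
    pooled, se_fe = fixed_effects_pool(lfcs, variances)
    if printed_se:
        se = se_fe / np.sqrt(k)
    else:
        se = se_fe
    if k > 1:
        mult = stats.t.ppf(0.975, k - 1) if printed_se else _Z975
    else:
        mult = np.nan
    ci_low = pooled - mult * se
    ci_high = pooled + mult * se
    return LfcMetaResult(
        feature_id=feature_id,
        k=k,
        pooled_log2fc=float(pooled),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        fold_change=float(2.0**pooled),
        fc_ci_low=float(2.0**ci_low),
        fc_ci_high=float(2.0**ci_high),
        direction_sign=sign,
    )


def fisher_z(r):
    """Variance-stabilising transform of a correlation: z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Back-transform: r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def pool_correlations(
    records: Iterable[CorrelationRecord],
    feature_id: str = "",
    tau2: float | None = None,
) -> MetaResult:
    """Random-effects pool of partial correlations on the Fisher-Z scale.

    Each record enters with variance 1/(n - n_covariates - 3) — the
    classic 1/(n - 3) adjusted for the residualised covariates. The
    pooled estimate and its CI are back-transformed to the r scale; se
    and tau2 remain on the z scale.
    """
    zs, vs = [], []
    for rec in records:
        if not np.isfinite(rec.rho):
            continue
        denom = rec.n - rec.n_covariates - 3
        if denom <= 0:
            warnings.warn(
                f"record {rec.feature_id!r}/{rec.dataset_id!r}: too few samples; excluded",
                stacklevel=2,
            )
            continue
        zs.append(fisher_z(min(max(rec.rho, -0.999999), 0.999999)))
        vs.append(1.0 / denom)
    if not zs:
        raise ValueError("no usable correlation records")
    res = random_effects_pool(zs, vs, feature_id=feature_id, tau2=tau2)
    return MetaResult(
        feature_id=feature_id,
        k=res.k,
        pooled=inverse_fisher_z(res.pooled),
        se=res.se,
        ci_low=inverse_fisher_z(res.ci_low),
        ci_high=inverse_fisher_z(res.ci_high),
        z=res.z,
        p=res.p,
        tau2=res.tau2,
        Q_het=res.Q_het,
    )


def by_fdr(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values.

    q_(i) = min_{j >= i} min(1, p_(j) m c(m) / j) with c(m) the harmonic
    sum; the mapping preserves the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = (1.0 / np.arange(1, m + 1)).sum()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q
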