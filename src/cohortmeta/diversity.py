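"""Alpha/beta diversity and permutational variance analysis.

PERMANOVA here is the classic distance-based pseudo-F test: among-group
vs within-group sums of squared dissimilarities, with significance from
label permutation. When the number of distinct label arrangements is no
larger than the requested permutation count the test switches to
complete enumeration and the p-value is exact.

``variance_partition`` performs a sequential (type-I) decomposition of a
distance matrix over an ordered list of covariates via the Gower-centred
inner-product matrix — the variance-fraction part of a distance-based
redundancy analysis, without the ordination axes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "PermanovaResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "permanova",
    "variance_partition",
    "adjusted_r2",
]


def alpha_diversity(abundances, index: str = "shannon") -> float:
    """Alpha diversity of one sample's abundance vector.

    Proportions are renormalised over detected taxa; Shannon entropy uses
    the natural log; ``richness`` counts strictly positive entries.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundance")
    if index == "richness":
        return float(np.count_nonzero(x > 0))
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-sum sample has undefined diversity")
    p = x[x > 0] / total
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "gini_simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown index {index!r}")


def alpha_diversity_table(matrix) -> pd.DataFrame:
    """Shannon, Gini-Simpson and richness for every sample of a profile."""
    ab = matrix.abundances if hasattr(matrix, "abundances") else matrix
    rows = {}
    for sample in ab.columns:
        v = ab[sample].to_numpy()
        rows[sample] = {
            "shannon": alpha_diversity(v, "shannon") if v.sum() > 0 else 0.0,
            "gini_simpson": alpha_diversity(v, "gini_simpson") if v.sum() > 0 else 0.0,
            "richness": alpha_diversity(v, "richness"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(i, j) = sum |x_i - x_j| / sum (x_i + x_j) over features. A pair of
    all-zero samples has an undefined (0/0) dissimilarity; it is set to 0
    with a warning so downstream permutation tests stay finite.
    """
    ab = matrix.abundances if hasattr(matrix, "abundances") else matrix
    X = ab.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis undefined, set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=list(ab.columns))


@dataclass
class PermanovaResult:
    """Pseudo-F, variance fractions and permutation p for one term/test."""

    term: str
    pseudo_F: float
    R2: float
    adjusted_R2: float
    p_perm: float
    n_permutations: int
    exhaustive: bool = False


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2) (n - 1) / (n - k - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _group_codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes, len(uniques)


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """(SS_total, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    return ss_total, ss_within


def _pseudo_f(ss_total: float, ss_within: float, n: int, a: int) -> float:
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _ss_within_batch(d2: np.ndarray, code_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """SS_within for each row of permuted group codes (B x n)."""
    out = np.zeros(code_matrix.shape[0])
    for g in range(n_groups):
        m = (code_matrix == g).astype(float)
        ng = m[0].sum()  # group sizes are permutation-invariant
        out += np.einsum("bi,ij,bj->b", m, d2, m) / (2 * ng)
    return out


def _distinct_assignments(counts: list[int], n: int):
    """Yield every distinct label-code arrangement for a multiset."""
    positions = list(range(n))

    def rec(remaining, group):
        if group == len(counts) - 1:
            arr = np.empty(n, dtype=int)
            for g_prev, pos in enumerate(assigned):
                for p in pos:
                    arr[p] = g_prev
            for p in remaining:
                arr[p] = group
            yield arr
            return
        for combo in itertools.combinations(remaining, counts[group]):
            assigned.append(combo)
            rest = [p for p in remaining if p not in set(combo)]
            yield from rec(rest, group + 1)
            assigned.pop()

    assigned: list[tuple] = []
    yield from rec(positions, 0)


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    term: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels."""
    labels = np.asarray(
        labels.loc[list(dist.ids)] if isinstance(labels, pd.Series) else labels
    )
    codes, a = _group_codes(labels)
    n = len(codes)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        raise ValueError("every group needs at least two samples")

    d2 = dist.data.astype(float) ** 2
    ss_total, ss_within = _permanova_stats(d2, codes, a)
    f_obs = _pseudo_f(ss_total, ss_within, n, a)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    n_distinct = math.factorial(n) // math.prod(math.factorial(int(c)) for c in counts)
    tol = 1e-12
    if n_distinct <= n_permutations:
        fs = []
        for arrangement in _distinct_assignments([int(c) for c in counts], n):
            _, ssw = _permanova_stats(d2, arrangement, a)
            fs.append(_pseudo_f(ss_total, ssw, n, a))
        fs = np.asarray(fs)
        p = float(np.mean(fs >= f_obs - tol))
        n_used, exhaustive = n_distinct, True
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
        ssw = _ss_within_batch(d2, perms, a)
        f_perm = np.where(
            ssw <= 0, np.inf, ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))
        )
        p = float((1 + np.sum(f_perm >= f_obs - tol)) / (1 + n_permutations))
        n_used, exhaustive = n_permutations, False

    return PermanovaResult(
        term=term,
        pseudo_F=float(f_obs),
        R2=float(r2),
        adjusted_R2=adjusted_r2(r2, n, a - 1),
        p_perm=p,
        n_permutations=n_used,
        exhaustive=exhaustive,
    )


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _term_design(values: pd.Series) -> np.ndarray | None:
    """Columns encoding one covariate; None if constant."""
    if values.nunique(dropna=False) <= 1:
        return None
    if values.dtype.kind in "fiu" and values.nunique() > 2:
        v = values.to_numpy(dtype=float)
        return ((v - v.mean()) / v.std())[:, None]
    dummies = pd.get_dummies(values.astype("category"), drop_first=True)
    return dummies.to_numpy(dtype=float)


def variance_partition(
    dist: DistanceMatrix,
    covariates: pd.DataFrame,
    term_order: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> list[PermanovaResult]:
    """Sequential variance decomposition of a distance matrix.

    Terms enter in the given order; each term's R^2 is the increment in
    explained (Gower-centred) sum of squares, its adjusted R^2 uses the
    Ezekiel formula with the cumulative model degrees of freedom, and its
    p-value comes from permuting that covariate while earlier terms stay
    fixed.
    """
    ids = list(dist.ids)
    cov = covariates.loc[ids]
    if cov.isna().any().any():
        raise ValueError("missing values in covariates used for partition")
    n = len(ids)
    d2 = dist.data.astype(float) ** 2
    g = _gower_center(d2)
    ss_total = np.trace(g)
    rng = np.random.default_rng(seed)

    designs: dict[str, np.ndarray] = {}
    for term in term_order:
        block = _term_design(cov[term])
        if block is None:
            warnings.warn(f"covariate {term!r} is constant; skipped", stacklevel=2)
            continue
        designs[term] = block

    def explained(blocks: list[np.ndarray]) -> float:
        x = np.hstack([np.ones((n, 1))] + blocks)
        q, _ = np.linalg.qr(x)
        h = q @ q.T
        return float(np.trace(h @ g))

    results: list[PermanovaResult] = []
    blocks_so_far: list[np.ndarray] = []
    ss_prev = 0.0
    k_cum = 0
    for term, block in designs.items():
        ss_cum = explained(blocks_so_far + [block])
        ss_term = ss_cum - ss_prev
        df_term = block.shape[1]
        k_cum += df_term
        r2 = ss_term / ss_total

        # permutation p: shuffle this covariate's rows, earlier terms fixed
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            ss_p = explained(blocks_so_far + [block[perm]]) - ss_prev
            if ss_p >= ss_term - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)

        resid = ss_total - ss_cum
        denom_df = n - 1 - k_cum
        f = (ss_term / df_term) / (resid / denom_df) if resid > 0 and denom_df > 0 else np.inf
        results.append(
            PermanovaResult(
                term=term,
                pseudo_F=float(f),
                R2=float(r2),
                adjusted_R2=adjusted_r2(r2, n, k_cum),
                p_perm=float(p),
                n_permutations=n_permutations,
            )
        )
        blocks_so_far.append(block)
        ss_prev = ss_cum
    return results
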