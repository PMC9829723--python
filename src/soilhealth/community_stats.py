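"""Permutation and variance-partitioning statistics on community data.

PERMANOVA follows the Gower-centering formulation: with D the distance
matrix, G = -(1/2) J D^2 J (J the centering projector), SS_total = tr(G) =
(1/N) sum_{i<j} d_ij^2, and sequential (Type-I) sums of squares tr(H_f G)
for the hat-matrix increments H_f of each factor added in order. Pseudo-F
compares a factor's mean square to the residual mean square; the null
permutes sample labels. Because sequential SS depends on factor order, R^2
is additionally averaged over random shufflings of the factor order.

LMG relative importance decomposes a linear model's R^2 by averaging each
predictor's sequential contribution over all predictor orderings (computed
via subset-R^2 weighting, exact for any number of predictors).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables_io import ValidationError

logger = logging.getLogger("soilhealth")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValidationError("distance matrix shape must match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], data=df.to_numpy(dtype=float))


@dataclass
class PermanovaResult:
    """Sequential SS partitioning per factor plus order-averaged R^2."""

    table: pd.DataFrame  # factor, ss, df, pseudo_F, r2, p_perm (+ Residual/Total rows)
    r2_order_averaged: dict[str, float]
    n_perm: int
    n_order_shuffles: int
    factor_order: list[str]


def bray_curtis(abund: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j)."""
    x = abund.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    sums = x.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(abund.index, sums) if t <= 0]
        raise ValidationError(f"zero-sum sample(s): {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(ids=[str(s) for s in abund.index], data=d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(design: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(design)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10)
    q = q[:, :rank]
    return q @ q.T


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _sequential_partition(
    g: np.ndarray, factors: dict[str, np.ndarray], order: list[str]
) -> tuple[dict[str, float], dict[str, int], float, int]:
    """Sequential SS and df per factor for one factor order; returns
    (ss_by_factor, df_by_factor, ss_resid, df_resid)."""
    n = g.shape[0]
    design = np.ones((n, 1))
    h_prev = _hat(design)
    ss: dict[str, float] = {}
    df: dict[str, int] = {}
    rank_prev = 1
    for f in order:
        design = np.hstack([design, _dummy(factors[f])])
        h = _hat(design)
        ss[f] = float(np.trace((h - h_prev) @ g))
        rank = int(round(np.trace(h)))
        df[f] = rank - rank_prev
        h_prev, rank_prev = h, rank
    ss_total = float(np.trace(g))
    ss_resid = ss_total - sum(ss.values())
    df_resid = n - rank_prev
    return ss, df, ss_resid, df_resid


def permanova(
    dist: DistanceMatrix,
    factors: dict[str, np.ndarray | list],
    n_perm: int = 999,
    n_order_shuffles: int = 50,
    seed: int | None = None,
    exhaustive_limit: int = 45_000,
) -> PermanovaResult:
    """PERMANOVA with sequential SS, label-permutation p-values and R^2
    averaged over shuffled factor orders.

    ``factors`` maps factor name -> per-sample labels in the distance
    matrix's sample order. p-values are computed for the declared order; R^2
    is also averaged over ``n_order_shuffles`` random orders (a single factor
    needs no shuffling and averages to its own R^2 exactly). When n! is at
    most ``exhaustive_limit`` every sample permutation is enumerated and p is
    the plain proportion of null pseudo-F >= observed.
    """
    rng = np.random.default_rng(seed)
    fac = {k: np.asarray(v) for k, v in factors.items()}
    for name, labels in fac.items():
        if len(labels) != dist.n:
            raise ValidationError(f"factor {name!r} length != n samples")
        levels, counts = np.unique(labels, return_counts=True)
        if len(levels) < 2:
            raise ValidationError(f"factor {name!r} has a single level")
    order = list(fac)
    g = _gower_center(dist.data)
    ss, df, ss_resid, df_resid = _sequential_partition(g, fac, order)
    ss_total = float(np.trace(g))
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    ms_resid = ss_resid / df_resid
    f_obs = {f: (ss[f] / df[f]) / ms_resid for f in order}

    # permutation null: permute sample labels (rows/cols of D jointly)
    if math.factorial(dist.n) <= exhaustive_limit:
        perms = [np.asarray(p) for p in permutations(range(dist.n))]
        ge = {f: 0 for f in order}
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            ss_p, df_p, ss_r_p, df_r_p = _sequential_partition(gp, fac, order)
            ms_r_p = ss_r_p / df_r_p
            for f in order:
                if (ss_p[f] / df_p[f]) / ms_r_p >= f_obs[f] - 1e-12:
                    ge[f] += 1
        p_perm = {f: ge[f] / len(perms) for f in order}
    else:
        ge = {f: 1 for f in order}
        for _ in range(n_perm):
            perm = rng.permutation(dist.n)
            gp = g[np.ix_(perm, perm)]
            ss_p, df_p, ss_r_p, df_r_p = _sequential_partition(gp, fac, order)
            ms_r_p = ss_r_p / df_r_p
            for f in order:
                if (ss_p[f] / df_p[f]) / ms_r_p >= f_obs[f] - 1e-12:
                    ge[f] += 1
        p_perm = {f: ge[f] / (1.0 + n_perm) for f in order}

    # order-averaged R^2
    r2_sums = {f: 0.0 for f in order}
    n_orders = n_order_shuffles if len(order) > 1 else 1
    for _ in range(n_orders):
        shuffled = list(rng.permutation(order)) if len(order) > 1 else order
        ss_o, _, _, _ = _sequential_partition(g, fac, shuffled)
        for f in order:
            r2_sums[f] += ss_o[f] / ss_total
    r2_avg = {f: r2_sums[f] / n_orders for f in order}

    rows = [
        {
            "factor": f,
            "ss": ss[f],
            "df": df[f],
            "pseudo_F": f_obs[f],
            "r2": ss[f] / ss_total,
            "p_perm": p_perm[f],
        }
        for f in order
    ]
    rows.append({"factor": "Residual", "ss": ss_resid, "df": df_resid,
                 "pseudo_F": np.nan, "r2": ss_resid / ss_total, "p_perm": np.nan})
    rows.append({"factor": "Total", "ss": ss_total, "df": dist.n - 1,
                 "pseudo_F": np.nan, "r2": 1.0, "p_perm": np.nan})
    return PermanovaResult(
        table=pd.DataFrame(rows),
        r2_order_averaged=r2_avg,
        n_perm=n_perm,
        n_order_shuffles=n_orders,
        factor_order=order,
    )


def mantel(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive_limit: int = 20_000,
) -> tuple[float, float]:
    """Mantel test: Pearson r over upper-triangle entries; p by joint
    row/column permutation of one matrix (two-sided on |r|). Exact
    enumeration of all n! permutations when feasible."""
    a = np.asarray(mat_a, dtype=float)
    b = np.asarray(mat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("matrices must be square and same shape")
    if not (np.allclose(a, a.T, atol=1e-9) and np.allclose(b, b.T, atol=1e-9)):
        raise ValidationError("matrices must be symmetric")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]

    def corr(perm: np.ndarray) -> float:
        vb = b[np.ix_(perm, perm)][iu]
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(np.arange(n))
    if math.factorial(n) <= exhaustive_limit:
        rs = [corr(np.asarray(p)) for p in permutations(range(n))]
        p = float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        ge = 1
        for _ in range(n_perm):
            if abs(corr(rng.permutation(n))) >= abs(r_obs) - 1e-12:
                ge += 1
        p = ge / (1.0 + n_perm)
    return r_obs, p


def _subset_r2(x: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    design = np.hstack([np.ones((len(y), 1)), x[:, cols]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def lmg_importance(
    predictors: pd.DataFrame, response: pd.Series, max_predictors: int = 10
) -> pd.Series:
    """LMG relative importance: each predictor's average sequential R^2
    increment over all predictor orderings; shares sum to the full-model R^2.

    Computed exactly via the subset-weighting identity
    share_j = sum_S w(|S|) (R^2(S+j) - R^2(S)), w(k) = k!(p-1-k)!/p!.
    """
    p = predictors.shape[1]
    if p > max_predictors:
        raise ValidationError(f"{p} predictors exceed max_predictors={max_predictors}")
    common = predictors.dropna().index.intersection(response.dropna().index)
    x = predictors.loc[common].to_numpy(dtype=float)
    y = response.loc[common].to_numpy(dtype=float)
    n = len(y)
    if n <= p + 1:
        raise ValidationError("need n_samples > n_predictors + 1")
    if np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), x])) < p + 1:
        corr = pd.DataFrame(x, columns=predictors.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValidationError(f"rank-deficient predictors (e.g. {worst[0]} ~ {worst[1]})")

    r2_cache: dict[tuple[int, ...], float] = {(): 0.0}
    for k in range(1, p + 1):
        for cols in combinations(range(p), k):
            r2_cache[cols] = _subset_r2(x, y, cols)

    shares = np.zeros(p)
    fact = math.factorial
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for k in range(p):
            w = fact(k) * fact(p - 1 - k) / fact(p)
            for s in combinations(others, k):
                with_j = tuple(sorted(s + (j,)))
                shares[j] += w * (r2_cache[with_j] - r2_cache[s])
    return pd.Series(shares, index=predictors.columns, name="lmg_share")


def group_tests(
    values: pd.Series, groups: pd.Series, test: str = "t"
) -> tuple[float, float]:
    """Two-sample comparison of a per-sample quantity between two factor
    levels (Welch t or Wilcoxon rank-sum)."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    levels = sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 levels, got {levels}")
    a = df.loc[df["g"] == levels[0], "v"].to_numpy(dtype=float)
    b = df.loc[df["g"] == levels[1], "v"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 samples per level")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValidationError("constant values across both groups")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
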