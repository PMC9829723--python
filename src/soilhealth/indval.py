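"""Indicator-species analysis (IndVal) for categorical factors.

For an OTU o and factor level k the indicator value is stat = sqrt(A * B)
where B (fidelity) is the fraction of level-k samples containing the OTU and
A (specificity) concentrates its abundance in level k. Two variants:

* ``indval``: A = (total abundance of o in k) / (total abundance of o)
* ``indval_g`` (default): A = (mean abundance of o in k) /
  (sum over levels of mean abundance) - the group-size-corrected form.

Significance comes from permuting sample labels; the exact null is enumerated
automatically when the number of distinct label arrangements is small.
Only singleton levels are considered (no level combinations), which is the
interpretable choice for two-level factors such as till vs. no-till.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .bioindicators import benjamini_hochberg
from .tables_io import ValidationError

logger = logging.getLogger("soilhealth")

#: enumerate the exact null when distinct arrangements are at most this many
EXHAUSTIVE_LIMIT = 20_000


@dataclass
class IndValResult:
    """Per-OTU best-level indicator statistics with permutation p-values."""

    records: pd.DataFrame  # otu_id, level, A, B, stat, p_perm, p_adj
    n_permutations: int
    variant: str
    exhaustive: bool = False

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _check_groups(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("need at least 2 factor levels")
    small = levels[counts < 2]
    if len(small):
        raise ValidationError(f"levels with < 2 samples: {list(small)}")
    return levels, counts


def indval_stat(
    abund: pd.DataFrame,
    groups,
    variant: str = "indval_g",
) -> pd.DataFrame:
    """A, B and stat = sqrt(A*B) for every OTU x level.

    Returns a tidy frame (otu_id, level, A, B, stat).
    """
    if variant not in ("indval", "indval_g"):
        raise ValueError(f"unknown variant {variant!r}")
    groups = np.asarray(pd.Series(groups, index=abund.index).loc[abund.index])
    levels, _ = _check_groups(groups)
    x = abund.to_numpy(dtype=float)
    A, B = _indval_components(x, groups, levels, variant)
    frames = []
    for j, level in enumerate(levels):
        frames.append(
            pd.DataFrame(
                {
                    "otu_id": abund.columns,
                    "level": level,
                    "A": A[j],
                    "B": B[j],
                    "stat": np.sqrt(A[j] * B[j]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    absent = out.groupby("otu_id")["stat"].transform("max") == 0
    if absent.any():
        logger.warning(
            "indval_stat: %d OTUs absent everywhere, stat = 0",
            out[absent]["otu_id"].nunique(),
        )
    return out


def _indval_components(
    x: np.ndarray, groups: np.ndarray, levels: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) arrays of shape (n_levels, n_otus); zero-safe."""
    n_levels = len(levels)
    n_otus = x.shape[1]
    mean_in = np.zeros((n_levels, n_otus))
    sum_in = np.zeros((n_levels, n_otus))
    B = np.zeros((n_levels, n_otus))
    for j, level in enumerate(levels):
        member = groups == level
        xg = x[member]
        mean_in[j] = xg.mean(axis=0)
        sum_in[j] = xg.sum(axis=0)
        B[j] = (xg > 0).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "indval_g":
            denom = mean_in.sum(axis=0)
            A = np.where(denom > 0, mean_in / denom, 0.0)
        else:
            denom = sum_in.sum(axis=0)
            A = np.where(denom > 0, sum_in / denom, 0.0)
    return A, B


def _best_stat(x: np.ndarray, groups: np.ndarray, levels: np.ndarray, variant: str):
    """Per-OTU max-over-levels stat and the argmax level index (ties -> first
    level in declared order)."""
    A, B = _indval_components(x, groups, levels, variant)
    stat = np.sqrt(A * B)
    best = stat.argmax(axis=0)
    return stat.max(axis=0), best


def _n_distinct_arrangements(counts: np.ndarray) -> int:
    n = int(counts.sum())
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_label_arrangements(groups: np.ndarray):
    """Yield every distinct arrangement of the multiset of labels
    (multiset-permutation recursion; never materializes duplicate orders)."""
    levels, counts = np.unique(groups, return_counts=True)
    n = len(groups)
    slot = np.empty(n, dtype=groups.dtype)

    def rec(pos: int, remaining: np.ndarray):
        if pos == n:
            yield slot.copy()
            return
        for j in range(len(levels)):
            if remaining[j] > 0:
                slot[pos] = levels[j]
                remaining[j] -= 1
                yield from rec(pos + 1, remaining)
                remaining[j] += 1

    yield from rec(0, counts.copy())


def indval_permutation_test(
    abund: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    variant: str = "indval_g",
    alpha: float | None = None,
) -> IndValResult:
    """Permutation test of each OTU's best-level indicator value.

    The null permutes group labels over samples. Monte-Carlo p uses the
    add-one estimator (1 + #{perm >= obs}) / (1 + n_perm); when the number of
    distinct label arrangements is <= 20,000 the exact null is enumerated and
    p is the plain proportion over all arrangements. BH is applied across
    OTUs. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = np.asarray(pd.Series(groups, index=abund.index).loc[abund.index])
    levels, counts = _check_groups(groups)
    x = abund.to_numpy(dtype=float)
    obs_stat, best_idx = _best_stat(x, groups, levels, variant)

    n_arr = _n_distinct_arrangements(counts)
    exhaustive = n_arr <= EXHAUSTIVE_LIMIT
    if exhaustive:
        ge = np.zeros_like(obs_stat)
        total = 0
        for arrangement in _distinct_label_arrangements(groups):
            perm_stat, _ = _best_stat(x, arrangement, levels, variant)
            ge += perm_stat >= obs_stat - 1e-12
            total += 1
        p_perm = ge / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        ge = np.ones_like(obs_stat)  # add-one
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            perm_stat, _ = _best_stat(x, perm, levels, variant)
            ge += perm_stat >= obs_stat - 1e-12
        p_perm = ge / (1.0 + n_perm)
        n_used = n_perm

    records = pd.DataFrame(
        {
            "otu_id": abund.columns,
            "level": levels[best_idx],
            "stat": obs_stat,
            "p_perm": p_perm,
        }
    )
    A, B = _indval_components(x, groups, levels, variant)
    records["A"] = A[best_idx, np.arange(len(best_idx))]
    records["B"] = B[best_idx, np.arange(len(best_idx))]
    records["p_adj"] = benjamini_hochberg(records["p_perm"].to_numpy())
    records = records[["otu_id", "level", "A", "B", "stat", "p_perm", "p_adj"]]
    if alpha is not None:
        records = records[records["p_adj"] < alpha].reset_index(drop=True)
    return IndValResult(
        records, n_permutations=n_used, variant=variant, exhaustive=exhaustive
    )
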