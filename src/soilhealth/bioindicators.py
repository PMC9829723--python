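"""Bioindicator calling: OTU filtering, counts-per-thousand normalization and
Spearman rank correlation of OTU abundance against soil-health ratings with
Benjamini-Hochberg multiplicity control.

A bioindicator is an OTU whose relative abundance correlates with a rating at
|rho| >= r_min (default 0.3) and BH-adjusted p <= alpha (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import OtuTable, RatingsTable, RATING_NAMES, ValidationError

logger = logging.getLogger("soilhealth")


class EmptyResultError(ValueError):
    """Raised when a filtering step removes everything."""


@dataclass
class BioindicatorSet:
    """OTU x rating associations surviving the thresholds.

    ``records`` columns: otu_id, rating, rho, p_raw, p_adj, direction.
    """

    records: pd.DataFrame
    r_min: float
    alpha: float

    def __post_init__(self) -> None:
        need = {"otu_id", "rating", "rho", "p_raw", "p_adj", "direction"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValidationError(f"records missing columns {sorted(missing)}")
        if len(self.records):
            r = self.records
            if (np.abs(r["rho"]) < self.r_min - 1e-15).any():
                raise ValidationError("record below r_min threshold")
            if (r["p_adj"] > self.alpha + 1e-15).any():
                raise ValidationError("record above alpha threshold")
            if (np.sign(r["rho"]) != r["direction"]).any() or (r["direction"] == 0).any():
                raise ValidationError("direction must equal sign(rho) != 0")

    @property
    def otu_ids(self) -> list[str]:
        return sorted(self.records["otu_id"].unique())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def filter_otus(
    table: OtuTable,
    min_samples: int = 10,
    min_relabund_frac: float = 1e-4,
) -> OtuTable:
    """Drop rare OTUs before correlation analysis.

    An OTU is removed when it occurs (count > 0) in fewer than ``min_samples``
    samples, or when its mean count across samples falls below
    ``min_relabund_frac`` x the mean per-sample read depth (the "<0.01% of
    average read depth" rule, interpreted on mean counts). Survivor order is
    preserved.
    """
    if table.counts.empty:
        raise EmptyResultError("empty OTU table")
    counts = table.counts
    prevalence = (counts > 0).sum(axis=0)
    mean_count = counts.mean(axis=0)
    depth_threshold = min_relabund_frac * table.depths.mean()
    keep = (prevalence >= min_samples) & (mean_count >= depth_threshold)
    kept = [o for o in table.otu_ids if keep[o]]
    n_dropped = len(table.otu_ids) - len(kept)
    if not kept:
        raise EmptyResultError(
            f"all {len(table.otu_ids)} OTUs removed by the frequency/abundance filter"
        )
    if n_dropped:
        logger.info("filter_otus: removed %d of %d OTUs", n_dropped, len(table.otu_ids))
    return table.subset_otus(kept)


def normalize_cpt(table: OtuTable) -> pd.DataFrame:
    """Counts-per-thousand normalization: 1000 * count / sample depth.

    Every row of the result sums to 1000.
    """
    depths = table.depths
    zero = depths[depths == 0]
    if len(zero):
        raise ValidationError(
            f"zero-depth sample(s): {', '.join(map(str, zero.index))}"
        )
    return table.counts.div(depths, axis=0) * 1000.0


def benjamini_hochberg(p_raw: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1).

    adj_(i) = min_{j>=i} ( m * p_(j) / j ) over the sorted p-values.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _spearman_vs_vector(abund: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each abundance column against y,
    pairwise-complete on missing y; average ranks for ties.

    Returns (rho, p) arrays with NaN where rho is undefined (constant input
    or fewer than 3 complete pairs).
    """
    mask = np.isfinite(y)
    n = int(mask.sum())
    n_otus = abund.shape[1]
    rho = np.full(n_otus, np.nan)
    pval = np.full(n_otus, np.nan)
    if n < 3:
        return rho, pval
    x = abund[mask]
    yy = y[mask]
    ry = stats.rankdata(yy)
    if np.ptp(ry) == 0:
        return rho, pval
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=0) * (ry_c**2).sum())
    ok = denom > 0
    num = (rx_c * ry_c[:, None]).sum(axis=0)
    rho[ok] = num[ok] / denom[ok]
    rho = np.clip(rho, -1.0, 1.0)
    # t-distribution p-value, the standard large-sample Spearman test
    r_ok = rho[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_ok * np.sqrt((n - 2) / (1.0 - r_ok**2))
    p_ok = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_ok[np.isclose(np.abs(r_ok), 1.0)] = 0.0
    pval[ok] = np.minimum(p_ok, 1.0)
    return rho, pval


def spearman_bh(
    abund: pd.DataFrame,
    ratings: RatingsTable,
    r_min: float = 0.3,
    alpha: float = 0.05,
    bh_family: str = "per_rating",
    rating_columns: tuple[str, ...] | None = None,
) -> BioindicatorSet:
    """Spearman correlation of every OTU against every rating with BH control.

    BH is applied within each rating across OTUs by default
    (``bh_family="per_rating"``); ``"pooled"`` adjusts one family across all
    OTU x rating tests. Records failing |rho| >= r_min or p_adj <= alpha are
    dropped. Constant abundance vectors are skipped with a log entry.
    """
    if bh_family not in ("per_rating", "pooled"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    shared = [s for s in abund.index if s in set(ratings.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared samples between abundance and ratings")
    x = abund.loc[shared].to_numpy(dtype=float)
    otu_ids = np.asarray(abund.columns)
    cols = rating_columns if rating_columns is not None else RATING_NAMES
    frames = []
    for rating in cols:
        y = ratings.ratings.loc[shared, rating].to_numpy(dtype=float)
        rho, p_raw = _spearman_vs_vector(x, y)
        skipped = ~np.isfinite(rho)
        if skipped.any():
            logger.warning(
                "spearman_bh: skipped %d constant/undefined OTUs for rating %s",
                int(skipped.sum()), rating,
            )
        frames.append(
            pd.DataFrame(
                {
                    "otu_id": otu_ids[~skipped],
                    "rating": rating,
                    "rho": rho[~skipped],
                    "p_raw": p_raw[~skipped],
                }
            )
        )
    tested = pd.concat(frames, ignore_index=True)
    if bh_family == "per_rating":
        tested["p_adj"] = tested.groupby("rating", sort=False)["p_raw"].transform(
            lambda p: benjamini_hochberg(p.to_numpy())
        )
    else:
        tested["p_adj"] = benjamini_hochberg(tested["p_raw"].to_numpy())
    keep = (np.abs(tested["rho"]) >= r_min) & (tested["p_adj"] <= alpha)
    records = tested[keep].reset_index(drop=True)
    records["direction"] = np.sign(records["rho"]).astype(int)
    return BioindicatorSet(records, r_min=r_min, alpha=alpha)


def summarize_bioindicators(bset: BioindicatorSet) -> dict:
    """Headline summary: indicator counts, ratings-per-OTU, direction
    consistency (all of an OTU's significant rho values share one sign)."""
    rec = bset.records
    if rec.empty:
        return {
            "n_otus": 0,
            "n_records": 0,
            "mean_ratings_per_otu": 0.0,
            "max_ratings_per_otu": 0,
            "consistency_fraction": float("nan"),
            "per_rating_counts": {},
            "per_direction_counts": {},
        }
    per_otu = rec.groupby("otu_id")
    n_ratings = per_otu.size()
    consistent = per_otu["direction"].apply(lambda d: d.nunique() == 1)
    per_rating = (
        rec.groupby(["rating", "direction"]).size().unstack(fill_value=0)
    )
    return {
        "n_otus": int(rec["otu_id"].nunique()),
        "n_records": int(len(rec)),
        "mean_ratings_per_otu": float(n_ratings.mean()),
        "max_ratings_per_otu": int(n_ratings.max()),
        "consistency_fraction": float(consistent.mean()),
        "per_rating_counts": {
            r: {int(d): int(v) for d, v in row.items()}
            for r, row in per_rating.iterrows()
        },
        "per_direction_counts": {
            int(d): int(v) for d, v in rec["direction"].value_counts().items()
        },
    }
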