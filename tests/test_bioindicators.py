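"""Filtering, counts-per-thousand normalization, Spearman-BH calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from soilhealth import (
    OtuTable,
    RatingsTable,
    RATING_NAMES,
    benjamini_hochberg,
    filter_otus,
    normalize_cpt,
    spearman_bh,
    summarize_bioindicators,
)
from soilhealth.bioindicators import BioindicatorSet, EmptyResultError
from soilhealth.tables_io import ValidationError


def _table(counts, samples=None, otus=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    otus = otus or [f"o{i}" for i in range(counts.shape[1])]
    return OtuTable(pd.DataFrame(counts, index=samples, columns=otus))


class TestFilterOtus:
    def test_below_min_sample_prevalence_removed(self, rng):
        # an OTU present in 9 samples is dropped at the min_samples=10 boundary
        n = 40
        counts = rng.integers(5, 50, size=(n, 3))
        counts[:, 1] = 0
        counts[:9, 1] = 100
        out = filter_otus(_table(counts), min_samples=10)
        assert out.otu_ids == ["o0", "o2"]

    def test_exactly_min_samples_retained(self, rng):
        counts = rng.integers(5, 50, size=(20, 2))
        counts[:, 1] = 0
        counts[:10, 1] = 200
        out = filter_otus(_table(counts), min_samples=10)
        assert "o1" in out.otu_ids

    def test_both_rules_evaluated_on_toy(self):
        # depths 100 each; OTU o1 mean count 1/3 passes abundance
        # (threshold 1e-4 * 100) but fails presence in >= 2 samples
        counts = [[99, 0], [100, 0], [99, 1]]
        counts[0][1] = 1  # make row sums 100
        counts = [[99, 1], [100, 0], [100, 0]]
        out = filter_otus(_table(counts), min_samples=2, min_relabund_frac=1e-4)
        assert out.otu_ids == ["o0"]

    def test_abundance_rule_removes_low_mean(self, rng):
        counts = rng.integers(100, 200, size=(30, 2))
        counts[:, 1] = 0
        counts[:15, 1] = 1  # prevalent but mean count far below 1e-2 threshold
        out = filter_otus(_table(counts), min_samples=10, min_relabund_frac=1e-2)
        assert out.otu_ids == ["o0"]

    def test_all_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_otus(_table([[1, 0], [0, 1]]), min_samples=10)


class TestNormalizeCpt:
    def test_closed_form(self):
        out = normalize_cpt(_table([[2, 3, 5]]))
        assert list(out.iloc[0]) == [200.0, 300.0, 500.0]

    def test_rows_sum_to_thousand(self, rng):
        out = normalize_cpt(_table(rng.integers(1, 100, size=(10, 30))))
        assert np.allclose(out.sum(axis=1), 1000.0, atol=1e-9)

    def test_zero_depth_sample_named_in_error(self):
        with pytest.raises(ValidationError, match="s1"):
            normalize_cpt(_table([[1, 2], [0, 0]]))


class TestBenjaminiHochberg:
    def test_hand_derived_triple(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    def test_matches_statsmodels_and_is_monotone_capped(self, p):
        p = np.asarray(p)
        adj = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)
        assert (adj <= 1).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _ratings_from_vector(y, name="organic_matter"):
    idx = [f"s{i}" for i in range(len(y))]
    df = pd.DataFrame(50.0, index=idx, columns=list(RATING_NAMES))
    df[name] = y
    return RatingsTable(df)


class TestSpearmanBH:
    def test_perfect_monotone_gives_rho_one(self):
        n = 12
        abund = pd.DataFrame(
            {"o0": np.arange(n, dtype=float)}, index=[f"s{i}" for i in range(n)]
        )
        ratings = _ratings_from_vector(np.arange(n) * 3.0 + 1)
        out = spearman_bh(abund, ratings, rating_columns=("organic_matter",))
        assert out.records["rho"].iloc[0] == pytest.approx(1.0)

    def test_tied_ranks_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        abund = pd.DataFrame({"o0": x}, index=[f"s{i}" for i in range(4)])
        out = spearman_bh(
            abund,
            _ratings_from_vector(y * 20),
            r_min=0.0,
            alpha=1.0,
            rating_columns=("organic_matter",),
        )
        assert out.records["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_spearmanr(self, rng):
        n = 30
        abund = pd.DataFrame(
            rng.poisson(20, size=(n, 5)).astype(float),
            index=[f"s{i}" for i in range(n)],
            columns=[f"o{i}" for i in range(5)],
        )
        y = rng.uniform(0, 100, n)
        out = spearman_bh(
            abund, _ratings_from_vector(y), r_min=0.0, alpha=1.0,
            rating_columns=("organic_matter",),
        )
        for _, row in out.records.iterrows():
            rho, p = stats.spearmanr(abund[row["otu_id"]], y)
            assert row["rho"] == pytest.approx(rho, abs=1e-12)
            assert row["p_raw"] == pytest.approx(p, abs=1e-9)

    def test_invariant_to_monotone_transform(self, rng):
        n = 25
        x = rng.gamma(2, 10, size=(n, 4))
        idx = [f"s{i}" for i in range(n)]
        y = rng.uniform(0, 100, n)
        a = pd.DataFrame(x, index=idx, columns=list("abcd"))
        b = pd.DataFrame(np.exp(x / 20), index=idx, columns=list("abcd"))
        ra = spearman_bh(a, _ratings_from_vector(y), r_min=0.0, alpha=1.0,
                         rating_columns=("organic_matter",))
        rb = spearman_bh(b, _ratings_from_vector(y), r_min=0.0, alpha=1.0,
                         rating_columns=("organic_matter",))
        assert np.allclose(ra.records["rho"], rb.records["rho"], atol=1e-12)

    def test_constant_abundance_skipped(self):
        n = 10
        abund = pd.DataFrame(
            {"flat": np.ones(n), "o1": np.arange(n, dtype=float)},
            index=[f"s{i}" for i in range(n)],
        )
        out = spearman_bh(
            abund, _ratings_from_vector(np.arange(n) * 5.0),
            r_min=0.0, alpha=1.0, rating_columns=("organic_matter",),
        )
        assert set(out.records["otu_id"]) == {"o1"}

    def test_thresholds_enforced_on_records(self):
        rec = pd.DataFrame(
            {
                "otu_id": ["a"],
                "rating": ["ph"],
                "rho": [0.2],
                "p_raw": [0.01],
                "p_adj": [0.01],
                "direction": [1],
            }
        )
        with pytest.raises(ValidationError):
            BioindicatorSet(rec, r_min=0.3, alpha=0.05)


class TestSummary:
    def _bset(self, rows):
        rec = pd.DataFrame(
            rows, columns=["otu_id", "rating", "rho", "p_raw", "p_adj", "direction"]
        )
        return BioindicatorSet(rec, r_min=0.3, alpha=0.05)

    def test_single_otu_two_positive_ratings_consistent(self):
        s = summarize_bioindicators(
            self._bset(
                [
                    ["a", "organic_matter", 0.5, 0.001, 0.01, 1],
                    ["a", "respiration", 0.4, 0.001, 0.01, 1],
                ]
            )
        )
        assert s["consistency_fraction"] == 1.0
        assert s["mean_ratings_per_otu"] == 2.0

    def test_mixed_directions_inconsistent(self):
        # +organic_matter and -ph differ in rho sign -> inconsistent under
        # the all-signs-agree convention
        s = summarize_bioindicators(
            self._bset(
                [
                    ["a", "organic_matter", 0.5, 0.001, 0.01, 1],
                    ["a", "ph", -0.4, 0.001, 0.01, -1],
                    ["b", "ph", -0.6, 0.001, 0.01, -1],
                ]
            )
        )
        assert s["consistency_fraction"] == pytest.approx(0.5)

    def test_empty_summary_zeroed(self):
        empty = BioindicatorSet(
            pd.DataFrame(
                columns=["otu_id", "rating", "rho", "p_raw", "p_adj", "direction"]
            ),
            r_min=0.3,
            alpha=0.05,
        )
        s = summarize_bioindicators(empty)
        assert s["n_otus"] == 0 and s["max_ratings_per_otu"] == 0
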