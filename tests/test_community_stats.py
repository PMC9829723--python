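"""Bray-Curtis, PERMANOVA partitioning, Mantel, LMG, group tests."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import skbio
from skbio.stats.distance import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

from soilhealth import (
    DistanceMatrix,
    bray_curtis,
    group_tests,
    lmg_importance,
    mantel,
    permanova,
)
from soilhealth.tables_io import ValidationError


def _toy_distance():
    """4 samples in 2 groups; within-group d = 0.5, between d = 1.0."""
    d = np.full((4, 4), 1.0)
    d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.5
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list("abcd"), data=d)


def brute_force_pseudo_f(d: np.ndarray, groups: np.ndarray) -> float:
    """Single-factor pseudo-F from the direct group-sum formulas."""
    n = len(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    levels, counts = np.unique(groups, return_counts=True)
    for level, n_g in zip(levels, counts):
        idx = np.where(groups == level)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / n_g
    ss_between = ss_total - ss_within
    df_b, df_w = len(levels) - 1, n - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        abund = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(abund).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        abund = pd.DataFrame([[2, 0], [0, 2]], index=["a", "b"])
        assert bray_curtis(abund).data[0, 1] == pytest.approx(1.0)

    def test_direct_formula(self):
        abund = pd.DataFrame([[1, 1], [1, 3]], index=["a", "b"])
        assert bray_curtis(abund).data[0, 1] == pytest.approx(1 / 3)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"]))


class TestPermanova:
    def test_hand_derived_toy_partition(self):
        res = permanova(_toy_distance(), {"g": ["x", "x", "y", "y"]}, seed=0)
        total = res.table.set_index("factor")
        assert total.loc["Total", "ss"] == pytest.approx(1.125)
        assert total.loc["g", "ss"] == pytest.approx(0.875)
        assert total.loc["g", "pseudo_F"] == pytest.approx(7.0)
        assert total.loc["g", "r2"] == pytest.approx(0.7778, abs=1e-4)

    def test_matches_skbio_pseudo_f(self, rng):
        n = 14
        abund = pd.DataFrame(rng.poisson(20, size=(n, 25)) + 1,
                             index=[f"s{i}" for i in range(n)])
        dist = bray_curtis(abund)
        groups = list(rng.permutation(["x"] * 7 + ["y"] * 7))
        mine = permanova(dist, {"g": groups}, n_perm=49, seed=0)
        ref = skbio_permanova(SkbioDM(dist.data, ids=dist.ids),
                              grouping=groups, permutations=49)
        f_mine = mine.table.set_index("factor").loc["g", "pseudo_F"]
        assert f_mine == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_exhaustive_p_matches_independent_enumeration(self, rng):
        # 6-sample design: enumerate all 720 sample permutations by hand
        n = 6
        abund = pd.DataFrame(rng.poisson(15, size=(n, 10)) + 1,
                             index=[f"s{i}" for i in range(n)])
        dist = bray_curtis(abund)
        groups = np.array(["x"] * 3 + ["y"] * 3)
        res = permanova(dist, {"g": groups}, seed=0)
        f_obs = brute_force_pseudo_f(dist.data, groups)
        ge = sum(
            brute_force_pseudo_f(dist.data[np.ix_(p, p)], groups) >= f_obs - 1e-12
            for p in map(np.asarray, permutations(range(n)))
        )
        expected = ge / 720
        assert res.table.set_index("factor").loc["g", "p_perm"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_sequential_r2_partitions_sum_to_one(self, rng):
        for _ in range(20):
            n = 12
            abund = pd.DataFrame(rng.poisson(10, size=(n, 15)) + 1,
                                 index=[f"s{i}" for i in range(n)])
            dist = bray_curtis(abund)
            factors = {
                "f1": rng.choice(["a", "b"], n),
                "f2": rng.choice(["u", "v", "w"], n),
            }
            if min(np.unique(factors["f1"], return_counts=True)[1]) < 2:
                continue
            if len(np.unique(factors["f2"])) < 2:
                continue
            res = permanova(dist, factors, n_perm=9, n_order_shuffles=5, seed=0,
                            exhaustive_limit=1)
            assert res.table["r2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_factor_order_average_is_exact(self):
        res = permanova(_toy_distance(), {"g": ["x", "x", "y", "y"]}, seed=1)
        tab = res.table.set_index("factor")
        assert res.r2_order_averaged["g"] == pytest.approx(tab.loc["g", "r2"])

    def test_invariant_to_sample_id_relabeling(self, rng):
        n = 8
        abund = pd.DataFrame(rng.poisson(20, size=(n, 12)) + 1,
                             index=[f"s{i}" for i in range(n)])
        dist = bray_curtis(abund)
        groups = ["x"] * 4 + ["y"] * 4
        r1 = permanova(dist, {"g": groups}, seed=5)
        renamed = DistanceMatrix(ids=[f"q{i}" for i in range(n)], data=dist.data)
        r2 = permanova(renamed, {"g": groups}, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError):
            permanova(_toy_distance(), {"g": ["x"] * 4}, seed=0)


class TestMantel:
    def _sym(self, rng, n=5):
        m = rng.uniform(0, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_identity_r_one(self, rng):
        m = self._sym(rng)
        r, _ = mantel(m, m.copy())
        assert r == pytest.approx(1.0)

    def test_negated_matrix_r_minus_one(self, rng):
        m = self._sym(rng)
        r, _ = mantel(m, -m)
        assert r == pytest.approx(-1.0)

    def test_exhaustive_p_matches_120_permutation_enumeration(self, rng):
        a, b = self._sym(rng), self._sym(rng)
        r_obs, p = mantel(a, b)
        iu = np.triu_indices(5, 1)
        rs = []
        for perm in permutations(range(5)):
            perm = np.asarray(perm)
            rs.append(np.corrcoef(a[iu], b[np.ix_(perm, perm)][iu])[0, 1])
        expected = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_r_matches_skbio(self, rng):
        n = 8
        a, b = self._sym(rng, n), self._sym(rng, n)
        r_mine, _ = mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            SkbioDM(a), SkbioDM(b), method="pearson", permutations=0
        )
        assert r_mine == pytest.approx(r_ref, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            mantel(self._sym(rng, 4), self._sym(rng, 5))


def brute_force_lmg(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LMG by explicit enumeration of every predictor ordering."""

    def r2(cols):
        if not cols:
            return 0.0
        design = np.hstack([np.ones((len(y), 1)), x[:, list(cols)]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

    p = x.shape[1]
    shares = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        done = []
        for j in order:
            before = r2(tuple(done))
            done.append(j)
            shares[j] += r2(tuple(done)) - before
    return shares / len(orders)


class TestLmg:
    def test_single_predictor_share_is_r2(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=30)})
        y = pd.Series(2 * x["a"] + rng.normal(size=30))
        share = lmg_importance(x, y)
        r = np.corrcoef(x["a"], y)[0, 1]
        assert share["a"] == pytest.approx(r**2)

    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        t = np.arange(n)
        a = np.where(t % 2 == 0, 1.0, -1.0)
        b = np.where((t // 2) % 2 == 0, 1.0, -1.0)  # exactly uncorrelated with a
        y = 3 * a + 1 * b
        x = pd.DataFrame({"a": a, "b": b})
        shares = lmg_importance(x, pd.Series(y))
        marginal_a = np.corrcoef(a, y)[0, 1] ** 2
        marginal_b = np.corrcoef(b, y)[0, 1] ** 2
        assert shares["a"] == pytest.approx(marginal_a, abs=1e-9)
        assert shares["b"] == pytest.approx(marginal_b, abs=1e-9)

    @pytest.mark.parametrize("p", [2, 3, 4, 5])
    def test_matches_factorial_brute_force(self, rng, p):
        n = 40
        x = rng.normal(size=(n, p)) @ (np.eye(p) + 0.3 * rng.normal(size=(p, p)))
        y = x @ rng.normal(size=p) + rng.normal(size=n)
        mine = lmg_importance(
            pd.DataFrame(x, columns=[f"v{i}" for i in range(p)]), pd.Series(y)
        )
        ref = brute_force_lmg(x, y)
        assert np.allclose(mine.to_numpy(), ref, atol=1e-9)
        # shares sum to full-model R^2
        full = brute_force_lmg(x, y).sum()
        assert mine.sum() == pytest.approx(full, abs=1e-9)

    def test_collinear_predictors_named(self, rng):
        a = rng.normal(size=30)
        x = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValidationError, match="rank-deficient"):
            lmg_importance(x, pd.Series(rng.normal(size=30)))


class TestGroupTests:
    def test_identical_groups_null(self, rng):
        v = np.tile(rng.normal(size=10), 2)
        g = ["a"] * 10 + ["b"] * 10
        _, p = group_tests(pd.Series(v), pd.Series(g), test="t")
        assert p >= 0.99

    def test_complete_separation_wilcoxon_extreme(self):
        v = pd.Series([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        stat, p = group_tests(v, g, test="wilcoxon")
        assert stat in (0.0, 9.0)  # U at its extreme for n=3/3
        assert p < 0.1

    def test_power_on_shifted_groups(self, rng):
        rejections = 0
        for _ in range(40):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            v = pd.Series(np.concatenate([a, b]))
            g = pd.Series(["a"] * 50 + ["b"] * 50)
            _, p = group_tests(v, g, test="t")
            rejections += p < 0.05
        assert rejections / 40 >= 0.9

    def test_constant_pooled_values_rejected(self):
        with pytest.raises(ValidationError):
            group_tests(
                pd.Series([1.0] * 6), pd.Series(["a"] * 3 + ["b"] * 3), test="t"
            )
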