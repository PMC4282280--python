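import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from herdvuln import (
    compose_indices,
    percentile_extremes,
    prepare_scores,
    spearman_influence,
    vulnerability_additive,
    vulnerability_multiplicative,
    weighted_group_mean,
    wilcoxon_model_compare,
)


def _ranked_results(n):
    return pd.DataFrame({
        "nation_id": [f"N{i:03d}" for i in range(n)],
        "v": np.linspace(1, 0, n),
        "rank": np.arange(1, n + 1),
    })


class TestPercentileExtremes:
    @pytest.mark.parametrize("n,fraction,k", [
        (148, 0.1, 15),  # ceiling(14.8) = 15 per extreme
        (100, 0.1, 10),
        (7, 0.1, 1),
    ])
    def test_ceiling_rule(self, n, fraction, k):
        top, bottom = percentile_extremes(_ranked_results(n), fraction)
        assert len(top) == len(bottom) == k

    def test_lists_ordered_and_disjoint(self):
        top, bottom = percentile_extremes(_ranked_results(50), 0.2)
        assert list(top["rank"]) == sorted(top["rank"])
        assert set(top["nation_id"]).isdisjoint(bottom["nation_id"])
        assert top["rank"].iloc[0] == 1 and bottom["rank"].iloc[0] == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_extremes(pd.DataFrame(), 0.1)


class TestWeightedGroupMean:
    @staticmethod
    def _frame(scores, pops, groups):
        df = pd.DataFrame({"v": scores, "S": scores, "E": scores, "AC": scores})
        return df, pd.Series(pops), pd.Series(groups)

    def test_forced_arithmetic(self):
        df, w, g = self._frame([0.2, 0.6], [1e6, 3e6], ["x", "x"])
        out = weighted_group_mean(df, w, g)
        assert out.loc[0, "v"] == pytest.approx(0.5)

    def test_equal_weights_give_plain_mean(self):
        df, w, g = self._frame([0.1, 0.5, 0.9], [7, 7, 7], ["a", "a", "a"])
        assert weighted_group_mean(df, w, g).loc[0, "v"] == pytest.approx(0.5)

    def test_single_nation_group_returns_its_score(self):
        df, w, g = self._frame([0.3, 0.8], [10, 99], ["solo", "other"])
        out = weighted_group_mean(df, w, g).set_index("group")
        assert out.loc["solo", "v"] == pytest.approx(0.3)

    def test_weighted_mean_within_member_range(self):
        rng = np.random.default_rng(6)
        df, w, g = self._frame(
            rng.uniform(size=30), rng.lognormal(15, 1, 30),
            rng.choice(list("abc"), 30),
        )
        out = weighted_group_mean(df, w, g).set_index("group")
        for label in "abc":
            members = df["v"][np.asarray(g) == label]
            assert members.min() <= out.loc[label, "v"] <= members.max()

    def test_seven_region_ranks_match_loop_oracle(self, synth_cohort):
        table, _ = synth_cohort
        res = vulnerability_additive(
            compose_indices(prepare_scores(table))
        ).set_index("nation_id")
        meta = table.meta
        out = weighted_group_mean(
            res, meta["population"], meta["region"]
        ).set_index("group")
        oracle = {}
        for region in meta["region"].unique():  # brute-force per group
            members = meta.index[meta["region"] == region]
            num = sum(res.loc[m, "v"] * meta.loc[m, "population"]
                      for m in members)
            den = sum(meta.loc[m, "population"] for m in members)
            oracle[region] = num / den
        expected_rank = pd.Series(oracle).rank(ascending=False, method="min")
        for region, wm in oracle.items():
            assert out.loc[region, "v"] == pytest.approx(wm)
            assert out.loc[region, "rank"] == int(expected_rank[region])

    def test_zero_weight_group_rejected(self):
        df, w, g = self._frame([0.2, 0.4], [0, 5], ["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            weighted_group_mean(df, w, g)


class TestSpearmanInfluence:
    def test_identical_and_reversed_rankings(self):
        x = pd.DataFrame({"a": np.arange(10.0)})
        same = spearman_influence(x, pd.DataFrame({"t": np.arange(10.0)}))
        rev = spearman_influence(x, pd.DataFrame({"t": np.arange(10.0)[::-1]}))
        assert same["rho"].iloc[0] == pytest.approx(1.0)
        assert rev["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_difference_formula(self):
        rng = np.random.default_rng(12)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        out = spearman_influence(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        d = sps.rankdata(x) - sps.rankdata(y)
        n = 10
        rho_hand = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))  # no ties
        assert out["rho"].iloc[0] == pytest.approx(rho_hand)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = x + rng.normal(0, 0.5, 25)
        base = spearman_influence(
            pd.DataFrame({"x": x}), pd.DataFrame({"y": y})
        )["rho"].iloc[0]
        warped = spearman_influence(
            pd.DataFrame({"x": np.exp(x)}), pd.DataFrame({"y": y**3})
        )["rho"].iloc[0]
        assert warped == pytest.approx(base)

    def test_constant_vector_reported_not_raised(self):
        out = spearman_influence(
            pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}),
            pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]}),
        )
        assert math.isnan(out["rho"].iloc[0])
        assert not out["significant"].iloc[0]


def _enumerate_signed_rank(d):
    """Exhaustive oracle: distribution of W+ over all sign assignments."""
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
    p = min(1.0, 2 * min(ge, le) / 2**n)
    return w_obs, p


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        a = np.arange(10.0)
        out = wilcoxon_model_compare(a, a)
        assert out.method == "degenerate"
        assert out.n == 0 and out.p_value is None

    def test_six_pair_exact_enumeration(self):
        a = np.array([1.2, 0.8, 3.1, 2.2, 0.5, 1.9])
        b = np.array([0.9, 1.1, 2.0, 2.6, 0.1, 1.0])
        out = wilcoxon_model_compare(a, b)
        w_oracle, p_oracle = _enumerate_signed_rank(a - b)
        assert out.method == "exact"
        assert out.statistic == pytest.approx(w_oracle)
        assert out.p_value == pytest.approx(p_oracle)

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(21)
        d = rng.normal(0.2, 1.0, 12)
        out = wilcoxon_model_compare(d, np.zeros_like(d))
        ref = sps.wilcoxon(d, method="exact")
        assert out.p_value == pytest.approx(ref.pvalue)

    def test_large_cohort_statistic_matches_loop_oracle(self, synth_cohort):
        table, _ = synth_cohort
        idx = compose_indices(prepare_scores(table))
        add = vulnerability_additive(idx).set_index("nation_id")["v"]
        mult = vulnerability_multiplicative(idx).set_index("nation_id")["v"]
        out = wilcoxon_model_compare(add.to_numpy(), mult.to_numpy())
        d = (add - mult).to_numpy()
        d = d[d != 0]
        # independent rank-and-sum implementation
        order = np.argsort(np.abs(d), kind="stable")
        ranks = np.empty(len(d))
        sorted_abs = np.abs(d)[order]
        i = 0
        while i < len(d):
            j = i
            while j < len(d) and sorted_abs[j] == sorted_abs[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        w_plus = ranks[d > 0].sum()
        assert out.method == "approx"
        assert out.statistic == pytest.approx(w_plus)
        ref = sps.wilcoxon(add.to_numpy(), mult.to_numpy(),
                           zero_method="wilcox", correction=False,
                           method="approx")
        assert out.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(30)
        a, b = rng.normal(size=20), rng.normal(size=20)
        base = wilcoxon_model_compare(a, b)
        shifted = wilcoxon_model_compare(a + 5.0, b + 5.0)
        assert base.statistic == shifted.statistic
        assert base.p_value == pytest.approx(shifted.p_value)

    def test_zero_differences_dropped_and_counted(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a.copy()
        b[3:] += np.array([0.5, -0.2, 0.3, 0.9])
        out = wilcoxon_model_compare(a, b)
        assert out.n == 4 and out.n_zero_dropped == 3
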