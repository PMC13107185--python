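from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from escctraj.differential import (annotation_enrichment_1d,
                                   annotation_enrichment_2d, bh_adjust,
                                   classify_de, fisher_overlap, wilcoxon_de)
from escctraj.matrix import ExpressionMatrix


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p by listing every
    assignment of the pooled values to group A."""
    pooled = np.r_[a, b]
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    center = len(a) * len(b) / 2.0
    obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    more_extreme = 0
    total = 0
    for comb in combinations(range(n), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
        more_extreme += abs(u - center) >= abs(obs - center) - 1e-12
        total += 1
    return more_extreme / total


def _matrix_from_groups(a, b):
    vals = np.r_[a, b].reshape(1, -1)
    cols = [f"A{i}" for i in range(len(a))] + [f"B{i}" for i in range(len(b))]
    m = ExpressionMatrix(pd.DataFrame(vals, index=["P1"], columns=cols))
    return m, cols[:len(a)], cols[len(a):]


class TestWilcoxonDE:
    def test_identical_value_multisets_give_p_one(self):
        m, ga, gb = _matrix_from_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        de = wilcoxon_de(m, ga, gb)
        assert de.loc["P1", "p"] == pytest.approx(1.0)
        assert de.loc["P1", "log2fc"] == pytest.approx(0.0)

    def test_fully_separated_small_groups_exact_p(self):
        m, ga, gb = _matrix_from_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        de = wilcoxon_de(m, ga, gb)
        # 2 * 1/C(6,3) = 0.1
        assert de.loc["P1", "p"] == pytest.approx(0.1)

    def test_log2fc_is_difference_of_group_means(self):
        m, ga, gb = _matrix_from_groups([3.0, 3.2, 2.8], [2.0, 2.1, 1.9])
        de = wilcoxon_de(m, ga, gb)
        assert de.loc["P1", "log2fc"] == pytest.approx(1.0)
        assert 2 ** de.loc["P1", "log2fc"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (4, 4), (5, 7), (7, 7)])
    def test_exact_p_matches_enumeration_oracle(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        a, b = rng.normal(size=n_a), rng.normal(0.8, size=n_b)
        m, ga, gb = _matrix_from_groups(a, b)
        de = wilcoxon_de(m, ga, gb)
        assert de.loc["P1", "p"] == pytest.approx(exact_rank_sum_p(a, b))

    def test_group_swap_negates_effect_and_keeps_p(self, rng):
        a, b = rng.normal(size=10), rng.normal(0.5, size=12)
        m, ga, gb = _matrix_from_groups(a, b)
        d1 = wilcoxon_de(m, ga, gb)
        d2 = wilcoxon_de(m, gb, ga)
        assert d1.loc["P1", "p"] == pytest.approx(d2.loc["P1", "p"])
        assert d1.loc["P1", "log2fc"] == pytest.approx(-d2.loc["P1", "log2fc"])
        assert d1.loc["P1", "u"] + d2.loc["P1", "u"] == pytest.approx(len(a) * len(b))

    def test_overlapping_groups_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(tiny_matrix, ["S1", "S2"], ["S2", "S3"])

    def test_insufficient_data_flagged_not_tested(self):
        vals = np.array([[1.0, np.nan, np.nan, 2.0, 3.0, 1.0]])
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=["P1"], columns=["A0", "A1", "A2", "B0", "B1", "B2"]))
        with pytest.warns(UserWarning, match="untestable"):
            de = wilcoxon_de(m, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert np.isnan(de.loc["P1", "p"])
        assert de.loc["P1", "direction"] == "S"


def bh_brute_force(p):
    """Step-up definition applied literally."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_hand_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_constant_vectors_are_fixed_points(self):
        p = np.full(10, 0.2)
        np.testing.assert_allclose(bh_adjust(p), p)
        np.testing.assert_allclose(bh_adjust(bh_adjust(p)), p)

    def test_nan_propagates_and_out_of_range_rejected(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestClassifyDE:
    def test_moderate_fold_change_still_up_when_above_gate(self):
        # 2**0.8 = 1.741 > 1.5
        assert classify_de([0.005], [0.8], require_fc=True)[0] == "U"

    def test_nonsignificant_is_stable(self):
        assert classify_de([0.5], [3.0])[0] == "S"

    def test_sign_symmetry(self):
        assert classify_de([0.005], [-1.0])[0] == "D"
        assert classify_de([0.005], [1.0])[0] == "U"

    def test_fc_gate_blocks_small_changes(self):
        assert classify_de([0.001], [0.3], require_fc=True)[0] == "S"
        assert classify_de([0.001], [0.3], require_fc=False)[0] == "U"


class TestFisherOverlap:
    def test_odds_ratio_from_table_cells(self):
        universe = [f"g{i}" for i in range(100)]
        set_a = universe[:20]              # a=10, b=10
        set_b = universe[10:30]            # c=10, d=70
        res = fisher_overlap(set_a, set_b, universe)
        assert res.table.tolist() == [[10, 10], [10, 70]]
        assert res.odds_ratio == pytest.approx(7.0)

    def test_independence_proportioned_table(self):
        universe = [f"g{i}" for i in range(100)]
        set_a = universe[:10]
        set_b = universe[:1] + universe[10:19]
        res = fisher_overlap(set_a, set_b, universe)
        assert res.table.tolist() == [[1, 9], [9, 81]]
        assert res.odds_ratio == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        universe = [f"g{i}" for i in range(100)]
        set_a, set_b = universe[:20], universe[10:30]
        res = fisher_overlap(set_a, set_b, universe)
        # enrichment p: P(overlap >= 10) with 20 draws from 100, 20 marked
        hg = stats.hypergeom(100, 20, 20)
        p_ge = sum(hg.pmf(k) for k in range(10, 21))
        assert res.p_enrich == pytest.approx(p_ge, rel=1e-10)
        # two-sided: sum of all overlap probabilities <= P(observed)
        p_obs = hg.pmf(10)
        p_two = sum(hg.pmf(k) for k in range(0, 21)
                    if hg.pmf(k) <= p_obs * (1 + 1e-9))
        assert res.p_two_sided == pytest.approx(p_two, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap([], [], [])


class TestAnnotationEnrichment:
    def test_members_at_top_score_one(self):
        values = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        sets = {"top": [f"g{i}" for i in range(10, 20)]}
        res = annotation_enrichment_1d(values, sets, min_members=2)
        assert res.loc["top", "score_s"] == pytest.approx(1.0)

    def test_small_set_matches_pair_counting(self):
        values = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                           index=list("abcde"))
        sets = {"s": ["a", "d"]}  # ranked 1st and 4th
        res = annotation_enrichment_1d(values, sets, min_members=2)
        # pairs (member, non-member): a beats b,c,e; d beats e -> 4/6
        auc = 4 / 6
        assert res.loc["s", "score_s"] == pytest.approx(2 * auc - 1)

    def test_null_scores_center_at_zero(self):
        rng = np.random.default_rng(12)
        ss = []
        for _ in range(200):
            values = pd.Series(rng.normal(size=100),
                               index=[f"g{i}" for i in range(100)])
            sets = {"s": [f"g{i}" for i in rng.choice(100, 20, replace=False)]}
            ss.append(annotation_enrichment_1d(values, sets).loc["s", "score_s"])
        assert abs(np.mean(ss)) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        values = pd.Series(rng.normal(size=50),
                           index=[f"g{i}" for i in range(50)])
        sets = {"s": [f"g{i}" for i in range(0, 50, 3)]}
        r1 = annotation_enrichment_1d(values, sets)
        r2 = annotation_enrichment_1d(np.exp(values * 3), sets)
        assert r1.loc["s", "score_s"] == pytest.approx(r2.loc["s", "score_s"])
        assert r1.loc["s", "p_raw"] == pytest.approx(r2.loc["s", "p_raw"])

    def test_2d_symmetry_and_dimension_swap(self, rng):
        values = pd.Series(rng.normal(size=60),
                           index=[f"g{i}" for i in range(60)])
        sets = {"s": [f"g{i}" for i in range(15)]}
        same = annotation_enrichment_2d(values, values, sets)
        assert same.loc["s", "score_x"] == pytest.approx(same.loc["s", "score_y"])
        other = pd.Series(rng.normal(size=60), index=values.index)
        r12 = annotation_enrichment_2d(values, other, sets)
        r21 = annotation_enrichment_2d(other, values, sets)
        assert r12.loc["s", "score_x"] == pytest.approx(r21.loc["s", "score_y"])
        assert r12.loc["s", "p_raw"] == pytest.approx(r21.loc["s", "p_raw"])

    def test_2d_planted_set_detected_in_one_dimension_only(self):
        rng = np.random.default_rng(5)
        n = 1000
        idx = [f"g{i}" for i in range(n)]
        x = pd.Series(rng.normal(size=n), index=idx)
        y = pd.Series(rng.normal(size=n), index=idx)
        members = idx[:100]
        x.loc[members] += 1.0
        res = annotation_enrichment_2d(x, y, {"s": members})
        assert res.loc["s", "score_x"] > 0.4
        assert abs(res.loc["s", "score_y"]) < 0.1
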