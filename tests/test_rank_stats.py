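import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from spermbeat import (
    GroupSamples,
    adjust_pvalues,
    chisq_contingency,
    compact_letter_display,
    dunn_posthoc,
    exact_u_distribution,
    kruskal_wallis,
    mann_whitney_exact,
)


def brute_force_u_pmf(n1, n2):
    """Enumerate every assignment of ranks 1..n1+n2 to the first group."""
    n = n1 + n2
    counts = {}
    for ranks in combinations(range(1, n + 1), n1):
        u = sum(ranks) - n1 * (n1 + 1) // 2
        counts[u] = counts.get(u, 0) + 1
    total = math.comb(n, n1)
    return np.array([counts.get(u, 0) / total for u in range(n1 * n2 + 1)])


class TestExactUDistribution:
    def test_single_observation_each(self):
        np.testing.assert_array_equal(exact_u_distribution(1, 1), [0.5, 0.5])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 5), (3, 6)])
    def test_equals_complete_enumeration(self, n1, n2):
        np.testing.assert_array_equal(
            exact_u_distribution(n1, n2), brute_force_u_pmf(n1, n2)
        )

    def test_upper_tail_count_for_five_vs_five(self):
        # 252 arrangements in total; 12 of them reach U >= 21
        pmf = exact_u_distribution(5, 5)
        assert pmf[21:].sum() == pytest.approx(12 / 252)

    @given(n1=st.integers(1, 8), n2=st.integers(1, 8))
    @settings(max_examples=25)
    def test_pmf_sums_to_one_and_is_symmetric(self, n1, n2):
        pmf = exact_u_distribution(n1, n2)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)

    def test_cap_guides_to_asymptotic_path(self):
        with pytest.raises(ValueError, match="asymptotic"):
            exact_u_distribution(30, 30, cap=400)


class TestMannWhitneyExact:
    def test_minimal_samples_exhaust_both_tails(self):
        res = mann_whitney_exact([1.0], [2.0])
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0
        assert res.exact

    def test_agrees_with_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(10):
            x = rng.normal(size=rng.integers(3, 9))
            y = rng.normal(loc=rng.normal(), size=rng.integers(3, 9))
            ours = mann_whitney_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.statistic_value == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)
            assert ours.exact and not ours.tie_corrected

    def test_tie_path_matches_independent_enumeration(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0]
        res = mann_whitney_exact(x, y)
        assert res.exact and res.tie_corrected
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        n1 = len(x)
        us = [
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in combinations(range(len(pooled)), n1)
        ]
        us = np.array(us)
        w = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        expected = min(1.0, 2 * min((us <= w + 1e-9).mean(), (us >= w - 1e-9).mean()))
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_monte_carlo_fallback_is_flagged_and_close(self):
        x = [1.0, 2.0, 2.0, 5.0, 6.0]
        y = [2.0, 3.0, 4.0, 7.0]
        exact = mann_whitney_exact(x, y)
        mc = mann_whitney_exact(x, y, enumeration_cap=1, mc_permutations=20000, seed=11)
        assert not mc.exact and mc.tie_corrected
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_large_samples_fall_back_to_normal_approximation(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        res = mann_whitney_exact(x, y, cap=400)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert not res.exact
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_exact([], [1.0])


class TestKruskalWallis:
    def test_identical_group_multisets_give_zero(self):
        groups = GroupSamples(["a", "b"], [np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        res = kruskal_wallis(groups)
        assert res.statistic_value == pytest.approx(0.0)

    def test_all_values_identical(self):
        groups = GroupSamples(["a", "b"], [np.ones(4), np.ones(5)])
        res = kruskal_wallis(groups)
        assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        vals = [rng.normal(size=6), rng.normal(size=7), rng.normal(size=5)]
        g1 = GroupSamples(["a", "b", "c"], vals)
        g2 = GroupSamples(["a", "b", "c"], [np.exp(v) for v in vals])
        assert kruskal_wallis(g1).statistic_value == pytest.approx(
            kruskal_wallis(g2).statistic_value
        )

    def test_agrees_with_scipy_with_ties(self, rng):
        vals = [np.round(rng.normal(size=n), 1) for n in (8, 10, 7, 9)]
        groups = GroupSamples(["a", "b", "c", "d"], vals)
        res = kruskal_wallis(groups)
        ref_h, ref_p = sps.kruskal(*vals)
        assert res.statistic_value == pytest.approx(ref_h, rel=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-12)
        assert res.df == 3


class TestDunnPosthoc:
    def test_identical_groups_not_significant(self):
        groups = GroupSamples(
            ["a", "b", "c"], [np.array([1.0, 2, 3])] * 3
        )
        comp = dunn_posthoc(groups)
        np.testing.assert_allclose(comp.z, 0.0)
        np.testing.assert_allclose(comp.p_raw, 1.0)
        assert comp.letters == {"a": "a", "b": "a", "c": "a"}

    def test_z_antisymmetric_in_group_order(self, rng):
        v1, v2 = rng.normal(size=8), rng.normal(loc=1.0, size=9)
        fwd = dunn_posthoc(GroupSamples(["x", "y"], [v1, v2]))
        rev = dunn_posthoc(GroupSamples(["y", "x"], [v2, v1]))
        assert fwd.z[0] == pytest.approx(-rev.z[0])
        assert fwd.p_raw[0] == pytest.approx(rev.p_raw[0])

    def test_flags_exactly_the_separated_pairs(self):
        """Four groups with two well-separated location pairs: Dunn with a
        Holm family flags the four cross-pair comparisons and nothing
        else in >= 95% of 200 replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            groups = GroupSamples(
                ["a", "b", "c", "d"],
                [
                    rng.normal(0.0, 1.0, 10),
                    rng.normal(0.0, 1.0, 10),
                    rng.normal(8.0, 1.0, 10),
                    rng.normal(8.0, 1.0, 10),
                ],
            )
            comp = dunn_posthoc(groups, alpha=0.05, adjust="holm")
            flagged = {p for p, s in zip(comp.pairs, comp.significant) if s}
            if flagged == {("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")}:
                hits += 1
        assert hits / n_rep >= 0.95


class TestCompactLetterDisplay:
    def test_no_significant_pairs_share_one_letter(self):
        labels = ["g1", "g2", "g3"]
        pairs = list(combinations(labels, 2))
        letters = compact_letter_display(labels, pairs, [False] * 3)
        assert letters == {"g1": "a", "g2": "a", "g3": "a"}

    def test_all_pairs_significant_get_distinct_letters(self):
        labels = ["g1", "g2", "g3"]
        pairs = list(combinations(labels, 2))
        letters = compact_letter_display(labels, pairs, [True] * 3)
        assert letters == {"g1": "a", "g2": "b", "g3": "c"}

    def test_single_extreme_pair_yields_bridged_pattern(self):
        """Only the first-vs-last comparison significant: the canonical
        a / ab / ab / b table layout."""
        labels = ["A", "B", "C", "D"]
        pairs = list(combinations(labels, 2))
        significant = [pair == ("A", "D") for pair in pairs]
        letters = compact_letter_display(labels, pairs, significant)
        assert letters == {"A": "a", "B": "ab", "C": "ab", "D": "b"}


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03], "holm"), [0.03])
        np.testing.assert_allclose(adjust_pvalues([0.03], "bonferroni"), [0.03])

    def test_holm_hand_computation(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04, 0.03], "holm"), [0.03, 0.06, 0.06]
        )

    def test_bonferroni_scalar_multiply(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04, 0.03], "bonferroni"), [0.03, 0.12, 0.09]
        )

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=50)
    def test_matches_statsmodels_and_dominates_raw(self, p):
        for method in ("holm", "bonferroni"):
            ours = adjust_pvalues(p, method)
            ref = multipletests(p, method=method)[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)
            assert np.all(ours >= np.asarray(p) - 1e-15)


class TestChisqContingency:
    def test_proportional_table_is_independent(self):
        res = chisq_contingency(np.array([[10, 20], [30, 60]]))
        assert res.statistic_value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2_closed_form(self):
        res = chisq_contingency(np.array([[10, 0], [0, 10]]))
        assert res.statistic_value == pytest.approx(20.0)
        assert res.df == 1

    def test_two_by_six_degrees_of_freedom(self, rng):
        table = rng.integers(1, 50, size=(2, 6))
        assert chisq_contingency(table).df == 5

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chisq_contingency(np.array([[0, 0], [3, 4]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            chisq_contingency(np.array([[1, -2], [3, 4]]))
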