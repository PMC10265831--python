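import numpy as np
import pytest
from scipy import stats as sps

from glymkin.stats import (
    boxplot_summary,
    compare_groups,
    normality_gate,
    omnibus,
    posthoc_pairs,
    significance_stars,
)


class TestNormalityGate:
    def test_normal_data_usually_passes(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            table = {g: rng.normal(0, 1, 20) for g in "ab"}
            if normality_gate(table).normal:
                hits += 1
        # two groups, each tested at 5%: pass rate ~ 0.95**2 = 0.90
        assert hits / n_seeds >= 0.80

    def test_exponential_group_usually_rejected(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(100):
            table = {"a": rng.normal(0, 1, 50), "b": rng.exponential(1.0, 50)}
            if not normality_gate(table).normal:
                rejections += 1
        assert rejections >= 80

    def test_constant_group_degenerate(self):
        verdict = normality_gate({"a": np.full(10, 2.0), "b": np.random.default_rng(0).normal(0, 1, 10)})
        assert not verdict.normal
        flagged = {g.group: g for g in verdict.per_group}
        assert flagged["a"].degenerate

    def test_small_group_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="excluded"):
            verdict = normality_gate({"tiny": [1.0, 2.0], "ok": rng.normal(0, 1, 10)})
        flagged = {g.group: g for g in verdict.per_group}
        assert not flagged["tiny"].included
        assert flagged["ok"].included

    def test_all_groups_must_pass(self):
        rng = np.random.default_rng(4)
        table = {"a": rng.normal(0, 1, 50), "b": rng.exponential(1.0, 200)}
        assert not normality_gate(table).normal


class TestOmnibus:
    def test_branch_selection(self):
        rng = np.random.default_rng(5)
        table = {g: rng.normal(0, 1, 10) for g in "abc"}
        assert omnibus(table, True).test == "anova"
        assert omnibus(table, False).test == "kruskal-wallis"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            omnibus({"a": [1.0, 2.0, 3.0]}, True)

    def test_two_groups_statistic_finite(self):
        rng = np.random.default_rng(6)
        table = {"a": rng.normal(0, 1, 8), "b": rng.normal(1, 1, 8)}
        result = omnibus(table, True)
        assert np.isfinite(result.statistic)
        assert 0 <= result.p_value <= 1

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            table = {
                "a": rng.normal(0, 1, 8),
                "b": rng.normal(0, 1, 8),
                "c": rng.normal(2, 1, 8),
            }
            if omnibus(table, True).p_value < 0.05:
                hits += 1
        assert hits >= 40


class TestPosthocPairs:
    def test_all_unordered_pairs(self):
        rng = np.random.default_rng(8)
        table = {g: rng.normal(0, 1, 8) for g in "abc"}
        results = posthoc_pairs(table, True)
        pairs = {(r.group_a, r.group_b) for r in results}
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(r.test == "t-test" for r in results)

    def test_self_pair_rejected(self):
        table = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]}
        with pytest.raises(ValueError, match="itself"):
            posthoc_pairs(table, True, pairs=[("a", "a")])

    def test_nonnormal_branch_matches_scipy_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.standard_cauchy(20)
        b = rng.standard_cauchy(20) + 1
        result = posthoc_pairs({"a": a, "b": b}, False)[0]
        assert result.test == "mann-whitney"
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert result.p_value == pytest.approx(p, rel=1e-12)

    def test_normal_branch_matches_scipy_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        result = posthoc_pairs({"a": a, "b": b}, True)[0]
        _, p = sps.ttest_ind(a, b, equal_var=True)
        assert result.p_value == pytest.approx(p, rel=1e-12)

    def test_planted_effect_power(self):
        # cohorts with means 0.964 / 0.936, SD 0.011, n = 7 and 8:
        # t-test separates at p < 0.01 in the large majority of seeds
        rng = np.random.default_rng(13)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            table = {
                "MED": rng.normal(0.964, 0.011, 7),
                "ISO+MED": rng.normal(0.936, 0.011, 8),
            }
            result = posthoc_pairs(table, True)[0]
            if result.p_value < 0.01:
                hits += 1
        assert hits / n_seeds >= 0.80

    def test_monotone_p_in_effect_size(self):
        rng = np.random.default_rng(14)
        medians = []
        for shift in (0.0, 0.5, 1.5):
            ps = []
            for _ in range(100):
                table = {"a": rng.normal(0, 1, 8), "b": rng.normal(shift, 1, 8)}
                ps.append(posthoc_pairs(table, True)[0].p_value)
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_correction_flag(self):
        rng = np.random.default_rng(15)
        table = {g: rng.normal(0, 1, 8) for g in "abc"}
        raw = posthoc_pairs(table, True)
        adj = posthoc_pairs(table, True, correction="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15


class TestBoxplotSummary:
    def test_1_to_100(self):
        s = boxplot_summary(np.arange(1, 101, dtype=float))
        assert s.median == pytest.approx(50.5)
        assert s.q25 == pytest.approx(25.75)
        assert s.q75 == pytest.approx(75.25)
        assert s.p5 == pytest.approx(np.quantile(np.arange(1, 101), 0.05))

    def test_constant_vector(self):
        s = boxplot_summary([4.2] * 7)
        assert s.median == s.mean == s.q25 == s.q75 == s.p5 == s.p95 == 4.2

    def test_single_value(self):
        s = boxplot_summary([3.0])
        assert s.median == s.mean == s.p5 == s.p95 == 3.0
        assert s.n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "")],
    )
    def test_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestCompareGroups:
    def test_branch_consistency(self):
        rng = np.random.default_rng(16)
        table = {"a": rng.exponential(1, 30), "b": rng.exponential(1, 30),
                 "c": rng.exponential(1, 30)}
        result = compare_groups(table)
        branch = "mann-whitney" if not result.verdict.normal else "t-test"
        assert all(p.test == branch for p in result.pairwise)

    def test_posthoc_gating_flag(self):
        rng = np.random.default_rng(17)
        table = {"a": rng.normal(0, 1, 10), "b": rng.normal(0.01, 1, 10)}
        gated = compare_groups(table, gate_posthoc_on_omnibus=True)
        ungated = compare_groups(table)
        assert len(ungated.pairwise) == 1
        if gated.omnibus.p_value >= 0.05:
            assert gated.pairwise == []

    def test_summaries_cover_groups(self):
        rng = np.random.default_rng(18)
        table = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
        result = compare_groups(table)
        assert set(result.summaries) == {"a", "b"}
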