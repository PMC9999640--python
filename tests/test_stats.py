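"""Cohort statistics: summaries, t-tests, models, threshold, ROC."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from ecgrt import (InvalidParameterError, negative_threshold, roc_auc,
                   run_model, se_from_sd, summarize_group, summary_from_stats,
                   t_test_from_summary, weighted_subgroup_mean)


def R(group, rt_pct):
    return SimpleNamespace(group=group, rt_pct=rt_pct)


class TestSummarizeGroup:
    def test_degenerate_equal_values(self):
        s = summarize_group([3.0, 3.0, 3.0])
        assert s.mean == 3.0 and s.sd == 0.0
        assert s.ci_lower == s.ci_upper == 3.0

    def test_hand_computed_five_values(self):
        """{1..5}: mean 3, SD 1.5811, SE 0.7071, CI [1.0368, 4.9632]."""
        s = summarize_group([1, 2, 3, 4, 5])
        assert s.mean == pytest.approx(3.0)
        assert s.sd == pytest.approx(math.sqrt(2.5), abs=1e-4)
        assert s.se == pytest.approx(math.sqrt(0.5), abs=1e-4)
        assert s.ci_lower == pytest.approx(1.0368, abs=1e-3)
        assert s.ci_upper == pytest.approx(4.9632, abs=1e-3)

    def test_published_negative_row_summary_mode(self):
        """n 47, mean 22.30, SE 0.63 reproduces the printed CI upper 23.57."""
        s = summary_from_stats(n=47, mean=22.30, se=0.63)
        assert s.ci_upper == pytest.approx(23.57, abs=0.02)
        assert s.ci_lower == pytest.approx(21.02, abs=0.02)

    def test_single_value_flags_missing_ci(self):
        s = summarize_group([5.0])
        assert s.n == 1 and s.sd is None and s.ci_upper is None

    def test_raw_and_summary_modes_agree(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 2, size=30)
        raw = summarize_group(v)
        from_stats = summary_from_stats(n=raw.n, mean=raw.mean, sd=raw.sd)
        assert from_stats.se == pytest.approx(raw.se, abs=1e-12)
        assert from_stats.ci_upper == pytest.approx(raw.ci_upper, abs=1e-12)
        assert from_stats.ci_lower == pytest.approx(raw.ci_lower, abs=1e-12)


class TestSeFromSd:
    @pytest.mark.parametrize("sd,n,expected", [
        (4.34, 47, 0.63),   # negative arm of the reference tables
        (7.36, 8, 2.60),    # severe-stenosis arm
        (0.0, 10, 0.0),
    ])
    def test_values(self, sd, n, expected):
        assert se_from_sd(sd, n) == pytest.approx(expected, abs=0.005)

    def test_invalid_n(self):
        with pytest.raises(InvalidParameterError):
            se_from_sd(1.0, 0)


class TestTTestFromSummary:
    def test_identical_summaries_give_p_one(self):
        s = summary_from_stats(n=10, mean=5.0, sd=1.0)
        c = t_test_from_summary(s, s)
        assert c.t_statistic == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("policy", ["welch", "pooled"])
    def test_published_model1_comparison_significant(self, policy):
        """(26, 27.96, 6.14) vs (47, 22.30, 4.34): p < 0.001 either way."""
        pos = summary_from_stats(n=26, mean=27.96, sd=6.14, group="positive")
        neg = summary_from_stats(n=47, mean=22.30, sd=4.34, group="negative")
        c = t_test_from_summary(pos, neg, policy)
        assert c.p_raw < 0.001

    def test_pooled_hand_example(self):
        """(5, 1, 1) vs (5, 2, 1) pooled: t = -1.5811, df = 8."""
        a = summary_from_stats(n=5, mean=1.0, sd=1.0)
        b = summary_from_stats(n=5, mean=2.0, sd=1.0)
        c = t_test_from_summary(a, b, "pooled")
        assert c.t_statistic == pytest.approx(-1.5811, abs=1e-4)
        assert c.df == 8

    def test_zero_variance_equal_means_convention(self):
        a = summary_from_stats(n=5, mean=2.0, sd=0.0)
        c = t_test_from_summary(a, a)
        assert c.p_raw == 1.0


class TestRunModel:
    def _cohort(self, rng, deltas):
        res = [R("negative", v) for v in rng.normal(22, 4, 47)]
        for g, d, n in (("normal", deltas[0], 4), ("lt50", deltas[1], 14),
                        ("ge50", deltas[2], 8)):
            res += [R(g, v) for v in rng.normal(22 + d, 4, n)]
        return res

    def test_only_negative_subjects_flags_all_skipped(self):
        rng = np.random.default_rng(0)
        res = [R("negative", v) for v in rng.normal(22, 4, 47)]
        mr = run_model(res, 1)
        assert mr.comparisons == []
        assert mr.skipped == ["positive"]

    def test_model3_bonferroni_times_three(self):
        rng = np.random.default_rng(1)
        mr = run_model(self._cohort(rng, (3, 5, 8)), 3)
        assert len(mr.comparisons) == 3
        for c in mr.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw))
            assert c.p_adjusted >= c.p_raw

    def test_model2_pools_normal_into_lt50(self):
        rng = np.random.default_rng(2)
        mr = run_model(self._cohort(rng, (3, 5, 8)), 2)
        labels = {s.group: s.n for s in mr.summaries}
        assert labels["lt50"] == 18 and labels["ge50"] == 8

    def test_largest_effect_gives_smallest_raw_p(self):
        """With ordered true effects, the severe arm usually attains the
        smallest model-3 raw p vs negative (majority over 20 seeds)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mr = run_model(self._cohort(rng, (1, 3, 8)), 3)
            ps = {c.group_a: c.p_raw for c in mr.comparisons}
            wins += min(ps, key=ps.get) == "ge50"
        assert wins > 10

    def test_anova_reported(self):
        rng = np.random.default_rng(3)
        mr = run_model(self._cohort(rng, (3, 5, 8)), 1)
        assert mr.anova_f is not None and mr.anova_p is not None


class TestWeightedSubgroupMean:
    def test_published_subgroup_means_combine_to_headline(self):
        """(4, 25.25), (14, 27.14), (8, 30.75) -> 27.96."""
        s = [summary_from_stats(n=4, mean=25.25, sd=1),
             summary_from_stats(n=14, mean=27.14, sd=1),
             summary_from_stats(n=8, mean=30.75, sd=1)]
        assert weighted_subgroup_mean(s) == pytest.approx(27.96, abs=0.02)

    def test_single_group_returns_own_mean(self):
        s = [summary_from_stats(n=5, mean=12.5, sd=1)]
        assert weighted_subgroup_mean(s) == 12.5

    def test_equal_sizes_reduce_to_arithmetic_mean(self):
        s = [summary_from_stats(n=7, mean=m, sd=1) for m in (10, 20, 30)]
        assert weighted_subgroup_mean(s) == pytest.approx(20.0)


class TestNegativeThreshold:
    def test_published_negative_row(self):
        s = summary_from_stats(n=47, mean=22.30, se=0.63, group="negative")
        assert negative_threshold(summary=s) == pytest.approx(23.57, abs=0.02)

    def test_constant_values_give_their_value(self):
        assert negative_threshold([5.0, 5.0, 5.0]) == 5.0

    def test_boundary_is_not_positive(self):
        thr = negative_threshold([5.0, 5.0, 5.0])
        assert not (thr > thr)  # strict inequality convention


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_chance_level_for_shuffled_labels(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        r = roc_auc(scores, labels)
        assert abs(r.auc - 0.5) < 0.05

    def test_pair_counting_oracle(self):
        """Brute-force over all (pos, neg) pairs."""
        def brute(scores, labels):
            pos = [s for s, l in zip(scores, labels) if l == 1]
            neg = [s for s, l in zip(scores, labels) if l == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            return wins / (len(pos) * len(neg))

        cases = [([1, 2, 3, 4], [0, 0, 1, 1]),
                 ([1, 3, 2, 4], [0, 0, 1, 1]),
                 ([1, 1, 2, 2, 3], [0, 1, 0, 1, 1])]
        for scores, labels in cases:
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute(scores, labels))
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = (rng.normal(size=60) + scores > 0).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(np.exp(scores), labels).auc
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(7)
        scores = np.round(rng.normal(size=200), 1)  # ties on purpose
        labels = rng.integers(0, 2, size=200)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_curve_spans_corners(self):
        r = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        fpr = 1 - r.specificity
        assert fpr[0] == 0 and r.sensitivity[0] == 0
        assert fpr[-1] == 1 and r.sensitivity[-1] == 1

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            roc_auc([1, 2, 3], [1, 1, 1])
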