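"""ROC/AUC inference, DeLong comparison, thresholds, metrics, overlaps."""

import math

import numpy as np
import pytest

from copdrisk.evaluate import (
    classification_metrics,
    compare_group_means,
    delong_test,
    high_risk_flags,
    overlap_counts,
    roc_with_auc,
    upper_quartile_threshold,
)


def brute_force_auc(scores, labels):
    """Independent oracle: concordant-pair counting over all pos-neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_delong(scores_a, scores_b, labels):
    """Independent evaluation of the paired-AUC z statistic from explicitly
    enumerated placement values."""
    labels = np.asarray(labels).astype(bool)

    def placements(scores):
        scores = np.asarray(scores, dtype=float)
        pos, neg = scores[labels], scores[~labels]
        v10 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for q in neg]) for p in pos])
        v01 = np.array([np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                                 for p in pos]) for q in neg])
        return v10, v01

    va10, va01 = placements(scores_a)
    vb10, vb01 = placements(scores_b)
    m, n = len(va10), len(va01)
    var = (np.var(va10, ddof=1) + np.var(vb10, ddof=1)
           - 2 * np.cov(va10, vb10, ddof=1)[0, 1]) / m + (
          np.var(va01, ddof=1) + np.var(vb01, ddof=1)
           - 2 * np.cov(va01, vb01, ddof=1)[0, 1]) / n
    return (va10.mean() - vb10.mean()) / math.sqrt(var)


class TestRocWithAuc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_with_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_interleaved_labels_give_three_quarters(self):
        # 3 of 4 pos-neg pairs concordant
        assert roc_with_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        assert roc_with_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_placement_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = rng.integers(0, 10, n).astype(float)  # ties likely
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        roc = roc_with_auc(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_is_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        roc = roc_with_auc(scores, labels)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_auc_equals_trapezoidal_curve_area(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 6, 80).astype(float)
        labels = rng.integers(0, 2, 80)
        roc = roc_with_auc(scores, labels)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)

    def test_invariance_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        a = roc_with_auc(scores, labels)
        b = roc_with_auc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_negated_scores_complement_the_auc(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        assert (roc_with_auc(scores, labels).auc
                + roc_with_auc(-scores, labels).auc) == pytest.approx(1.0)

    def test_ci_truncated_to_unit_interval(self):
        roc = roc_with_auc([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert 0.0 <= roc.ci95[0] <= roc.ci95[1] <= 1.0

    def test_logit_scale_ci_is_asymmetric_near_one(self):
        rng = np.random.default_rng(7)
        neg = rng.normal(0, 1, 100)
        pos = rng.normal(1.8, 1, 15)
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(100), np.ones(15)])
        roc = roc_with_auc(scores, labels, ci_scale="logit")
        assert 0.0 < roc.ci95[0] < roc.auc < roc.ci95[1] < 1.0
        assert (roc.auc - roc.ci95[0]) > (roc.ci95[1] - roc.auc)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_with_auc([1, 2, 3], [1, 1, 1])


class TestDelongTest:
    def test_identical_scores_degenerate_with_p_one(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [0, 0, 0, 1, 1, 1]
        result = delong_test(scores, scores, labels)
        assert result.z == 0.0
        assert result.p_value == 1.0
        assert result.degenerate

    def test_swapping_scores_negates_z_keeps_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        fwd = delong_test(a, b, labels)
        rev = delong_test(b, a, labels)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_six_patient_example_matches_hand_evaluated_components(self):
        labels = [1, 1, 1, 0, 0, 0]
        a = [9.0, 7.0, 5.0, 6.0, 4.0, 2.0]
        b = [8.0, 3.0, 6.0, 7.0, 5.0, 1.0]
        result = delong_test(a, b, labels)
        expected_z = brute_force_delong(a, b, labels)
        assert result.z == pytest.approx(expected_z, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_z_matches_brute_force_on_random_paired_scores(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(8), np.zeros(12)].astype(int)
        a = rng.normal(size=20) + labels
        b = rng.normal(size=20) + 0.5 * labels
        result = delong_test(a, b, labels)
        assert result.z == pytest.approx(brute_force_delong(a, b, labels),
                                         abs=1e-10)


class TestUpperQuartile:
    def test_one_to_eight_threshold_and_top_quarter(self):
        scores = np.arange(1, 9, dtype=float)
        threshold = upper_quartile_threshold(scores)
        assert threshold == pytest.approx(6.25)
        assert set(scores[high_risk_flags(scores, threshold)]) == {7.0, 8.0}

    def test_constant_scores_flag_nobody(self):
        scores = np.full(10, 3.0)
        threshold = upper_quartile_threshold(scores)
        assert high_risk_flags(scores, threshold).sum() == 0

    def test_half_integer_threshold_equals_next_integer_rule(self):
        # Q3 landing mid-gap on integer scores: > 18.5 is the same as >= 19
        scores = np.array([10, 12, 14, 16, 18, 19, 21], dtype=float)
        threshold = upper_quartile_threshold(scores)
        assert threshold == pytest.approx(18.5)
        flagged = high_risk_flags(scores, threshold)
        assert set(scores[flagged]) == {19.0, 21.0}

    def test_fraction_above_threshold_at_most_quarter_plus_tie_mass(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores = rng.integers(0, 30, int(rng.integers(4, 200))).astype(float)
            threshold = upper_quartile_threshold(scores)
            frac = high_risk_flags(scores, threshold).mean()
            tie_mass = (scores == threshold).mean()
            # 1/n term: interpolation can land the cut one rank early
            assert frac <= 0.25 + tie_mass + 1.0 / len(scores) + 1e-12

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError):
            upper_quartile_threshold([1.0, 2.0, 3.0])


class TestClassificationMetrics:
    def test_worked_two_by_two_table(self):
        # TP 3, FP 1, FN 1, TN 5
        high_risk = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        report = classification_metrics(high_risk, labels)
        assert (report.tp, report.fp, report.fn, report.tn) == (3, 1, 1, 5)
        assert report.sensitivity == pytest.approx(0.75)
        assert report.specificity == pytest.approx(5 / 6)
        assert report.ppv == pytest.approx(0.75)
        assert report.npv == pytest.approx(5 / 6)
        assert report.accuracy == pytest.approx(0.8)

    def test_perfect_classifier_scores_one_everywhere(self):
        labels = [0, 1, 0, 1, 1]
        report = classification_metrics(labels, labels)
        assert report.sensitivity == report.specificity == 1.0
        assert report.ppv == report.npv == report.accuracy == 1.0

    def test_no_predicted_positives_gives_nan_ppv_zero_sensitivity(self):
        report = classification_metrics([0, 0, 0, 0], [1, 0, 1, 0])
        assert math.isnan(report.ppv)
        assert report.sensitivity == 0.0

    def test_counts_partition_the_cohort(self):
        rng = np.random.default_rng(10)
        hr = rng.integers(0, 2, 50)
        labels = rng.integers(0, 2, 50)
        report = classification_metrics(hr, labels)
        assert report.tp + report.fn == labels.sum()
        assert report.fp + report.tn == 50 - labels.sum()
        assert report.accuracy == pytest.approx((report.tp + report.tn) / 50)


class TestOverlapCounts:
    def test_identical_sets_intersect_fully(self):
        flags = [1, 0, 1, 0, 1]
        report = overlap_counts({"a": flags, "b": flags}, [0, 0, 1, 0, 1])
        assert report.pairwise[("a", "b")] == 3

    def test_disjoint_sets_intersect_empty(self):
        report = overlap_counts({"a": [1, 1, 0, 0], "b": [0, 0, 1, 1]},
                                [0, 1, 0, 1])
        assert report.pairwise[("a", "b")] == 0

    def test_three_sets_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        flags = {name: rng.integers(0, 2, 10).astype(bool) for name in "abc"}
        labels = rng.integers(0, 2, 10).astype(bool)
        report = overlap_counts(flags, labels)
        for (x, y), size in report.pairwise.items():
            expected = sum(fx and fy for fx, fy in zip(flags[x], flags[y]))
            assert size == expected
        for name, size in report.with_deaths.items():
            assert size == sum(f and l for f, l in zip(flags[name], labels))

    def test_containment_check(self):
        report = overlap_counts(
            {"combi": [1, 1, 0, 0], "a": [1, 0, 0, 0], "b": [0, 1, 1, 0]},
            [1, 0, 0, 0])
        assert report.covered_by_union("combi", ["a", "b"])
        assert not report.covered_by_union("b", ["a"])


class TestCompareGroupMeans:
    def test_identical_groups_give_t_zero_p_one(self):
        scores = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = [1, 1, 1, 0, 0, 0]
        result = compare_group_means(scores, labels, mode="vs_survivors")
        assert result.t == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_sized_example_matches_pooled_formula(self):
        group = np.array([5.0, 7.0, 9.0])
        ref = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        scores = np.concatenate([group, ref])
        labels = np.r_[np.ones(3), np.zeros(5)]
        result = compare_group_means(scores, labels, mode="vs_survivors")
        # closed-form pooled two-sample t
        sp2 = ((2 * group.var(ddof=1) + 4 * ref.var(ddof=1)) / 6)
        expected_t = (group.mean() - ref.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 5))
        assert result.t == pytest.approx(expected_t, abs=1e-12)

    def test_reported_moments_are_plain_sample_moments(self):
        scores = np.array([4.0, 8.0, 6.0, 1.0, 3.0])
        labels = np.array([1, 1, 0, 0, 0])
        result = compare_group_means(scores, labels, mode="vs_overall")
        assert result.mean_group == pytest.approx(6.0)
        assert result.sd_group == pytest.approx(np.std([4, 8], ddof=1))
        assert result.mean_reference == pytest.approx(scores.mean())
        assert result.sd_reference == pytest.approx(scores.std(ddof=1))

    def test_vs_overall_and_vs_survivors_differ(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        a = compare_group_means(scores, labels, mode="vs_overall")
        b = compare_group_means(scores, labels, mode="vs_survivors")
        assert a.n_reference == 30
        assert b.n_reference == 30 - labels.sum()
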