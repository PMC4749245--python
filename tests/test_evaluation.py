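"""ROC construction, operating point, metrics, and the statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vfshock import (
    InvalidArgumentError,
    TestUndefinedError,
    UndefinedRocError,
    classification_metrics,
    compare_auc,
    compare_proportions,
    generate_cohort,
    hausman_specification_test,
    kendall_tau,
    parameter_recovery_config,
    roc_curve,
    t_test_independent,
    threshold_at_specificity,
)


def concordance_auc(scores, labels):
    """Brute-force pairwise AUC: P(s+ > s-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(np.sum(p > neg) + 0.5 * np.sum(p == neg) for p in pos)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert curve.auc == 1.0

    def test_all_tied_scores(self):
        curve = roc_curve([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert curve.auc == pytest.approx(0.5)

    def test_worked_small_instance(self):
        curve = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert curve.auc == pytest.approx(0.75)

    def test_matches_concordance_on_random_instances(self, rng):
        for _ in range(30):
            n = rng.integers(10, 200)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
            curve = roc_curve(scores, labels)
            assert curve.auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedRocError):
            roc_curve([0.1, 0.2], [1, 1])


class TestThresholdAtSpecificity:
    def test_enumerated_ten_negatives(self):
        # 10 negatives scored 1..10: only the score-10 negative may pass
        scores = np.r_[np.arange(1.0, 11.0), [10.5, 9.5]]
        labels = np.r_[np.zeros(10, int), [1, 1]]
        thr = threshold_at_specificity(roc_curve(scores, labels), 0.9)
        neg = scores[labels == 0]
        assert np.mean(neg < thr) == pytest.approx(0.9)

    def test_perfectly_separated(self):
        scores = np.r_[np.linspace(0, 0.4, 8), np.linspace(0.6, 1, 8)]
        labels = np.r_[np.zeros(8, int), np.ones(8, int)]
        thr = threshold_at_specificity(roc_curve(scores, labels), 0.9)
        rep = classification_metrics(scores, labels, thr)
        assert rep.specificity == 100.0 and rep.sensitivity == 100.0

    def test_unattainable_target_rises_above_all_negatives(self):
        scores = np.r_[np.arange(1.0, 11.0), [11.0, 12.0]]
        labels = np.r_[np.zeros(10, int), [1, 1]]
        thr = threshold_at_specificity(roc_curve(scores, labels), 0.999)
        assert thr > 10.0  # specificity 1.0, the smallest attainable level

    def test_reapplied_threshold_meets_target(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 150))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            thr = threshold_at_specificity(roc_curve(scores, labels), 0.9)
            neg = scores[labels == 0]
            assert np.mean(neg < thr) >= 0.9

    def test_invalid_target(self):
        curve = roc_curve([0.1, 0.9], [0, 1])
        with pytest.raises(InvalidArgumentError):
            threshold_at_specificity(curve, 1.5)


class TestClassificationMetrics:
    def test_reconstructed_confusion_counts(self):
        """TP=39 FN=12 TN=110 FP=12 reproduces the headline percentages."""
        scores = np.r_[np.ones(39), np.zeros(12), np.zeros(110), np.ones(12)]
        labels = np.r_[np.ones(51, int), np.zeros(122, int)]
        rep = classification_metrics(scores, labels, threshold=0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (39, 12, 110, 12)
        assert rep.sensitivity == pytest.approx(76.5, abs=0.05)
        assert rep.specificity == pytest.approx(90.2, abs=0.05)
        assert rep.npv == pytest.approx(90.2, abs=0.05)
        assert rep.ppv == pytest.approx(76.5, abs=0.05)
        assert rep.pa == pytest.approx(86.1, abs=0.05)
        assert rep.recompute() == {
            "sensitivity": rep.sensitivity, "specificity": rep.specificity,
            "ppv": rep.ppv, "npv": rep.npv, "pa": rep.pa}

    def test_no_positive_predictions(self):
        with pytest.warns(UserWarning, match="PPV"):
            rep = classification_metrics([0.1, 0.2, 0.3], [0, 1, 0], 0.9)
        assert rep.sensitivity == 0.0
        assert np.isnan(rep.ppv)

    def test_threshold_below_all_scores(self):
        with pytest.warns(UserWarning, match="NPV"):
            rep = classification_metrics([0.2, 0.5, 0.8], [0, 1, 0], 0.0)
        assert rep.sensitivity == 100.0 and rep.specificity == 0.0

    def test_nan_threshold_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classification_metrics([0.1, 0.9], [0, 1], float("nan"))


class TestCompareAuc:
    def test_identical_scores(self):
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        scores = np.arange(20.0)
        res = compare_auc(scores, scores, labels)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_variance_matches_brute_force_placements(self, rng):
        """n=8 DeLong variance equals the direct placement computation."""
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        res = compare_auc(a, b, labels)

        def placements(s):
            pos, neg = s[labels == 1], s[labels == 0]
            v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
            v01 = np.array([np.mean((n < pos) + 0.5 * (n == pos)) for n in neg])
            return v10, v01

        va, oa = placements(a)
        vb, ob = placements(b)
        var = (np.cov(va, vb, ddof=1)[0, 0] + np.cov(va, vb, ddof=1)[1, 1]
               - 2 * np.cov(va, vb, ddof=1)[0, 1]) / 4 \
            + (np.cov(oa, ob, ddof=1)[0, 0] + np.cov(oa, ob, ddof=1)[1, 1]
               - 2 * np.cov(oa, ob, ddof=1)[0, 1]) / 4
        expected_z = (va.mean() - vb.mean()) / np.sqrt(var)
        assert res.statistic == pytest.approx(expected_z, abs=1e-9)

    def test_unpaired_reduces_to_normal_comparison(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a, b = rng.normal(size=60), rng.normal(size=60)
        res = compare_auc(a, b, labels, paired=False)
        assert res.name == "unpaired_z"
        assert 0 <= res.p_value <= 1


class TestSimpleTests:
    def test_equal_proportions(self):
        res = compare_proportions(30, 100, 30, 100)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_hand_computed(self):
        # table (39,12;18,33): chi2 = sum (O-E)^2/E without correction
        table = np.array([[39, 12], [18, 33]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = float(np.sum((table - expected) ** 2 / expected))
        res = compare_proportions(39, 51, 18, 51)
        assert res.statistic == pytest.approx(chi2, rel=1e-12)

    def test_extreme_split(self):
        assert compare_proportions(50, 50, 0, 50).p_value < 1e-10

    def test_kendall_tau_limits_and_brute_force(self):
        assert kendall_tau([1, 2, 3, 4], [2, 4, 6, 8]).statistic == 1.0
        assert kendall_tau([1, 2, 3, 4], [8, 6, 4, 2]).statistic == -1.0
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0])
        res = kendall_tau(x, y)
        assert res.statistic == pytest.approx(
            stats.kendalltau(x, y).statistic)  # tau-b, tie-corrected
        # brute-force pair counting over all 15 pairs
        conc = disc = tx = ty = 0
        for i in range(6):
            for j in range(i + 1, 6):
                dx, dy = x[j] - x[i], y[j] - y[i]
                if dx == 0 and dy == 0:
                    continue
                elif dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
        assert res.statistic == pytest.approx((conc - disc) / denom)

    def test_kendall_constant_vector_flagged(self):
        with pytest.warns(UserWarning):
            res = kendall_tau([1, 1, 1], [1, 2, 3])
        assert res.statistic == 0.0 and res.flag is not None

    def test_t_test_identical_and_shifted(self):
        same = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert same.statistic == 0.0 and same.p_value == pytest.approx(1.0)
        far = t_test_independent([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert far.p_value < 1e-6

    def test_t_test_closed_form(self):
        a, b = np.array([1.0, 2.0, 4.0]), np.array([5.0, 6.0, 9.0])
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = t_test_independent(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-12)


class TestHausman:
    def test_equal_coefficients_give_zero(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        res = hausman_specification_test(sub, "amsa")
        # on well-specified data the statistic is small or inconclusive
        assert res.flag is not None or res.p_value > 0.001

    def test_no_within_patient_variation_rejected(self):
        frame = pd.DataFrame({
            "patient_id": ["A", "A", "B", "B"],
            "shock_index": [1, 2, 1, 2],
            "amsa": [10.0, 11.0, 8.0, 9.0],
            "outcome": [0, 0, 1, 1],
        })
        with pytest.raises(TestUndefinedError):
            hausman_specification_test(frame, "amsa")
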