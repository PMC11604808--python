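"""ROC/AUC, Hanley-McNeil intervals, operating points, confusion baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizurecast.evaluate import (
    AucWithCi,
    combine_scores,
    compare_aucs,
    confusion_and_baseline,
    hanley_mcneil_ci,
    match_point,
    operating_points,
    roc_auc,
    vs_random,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with tie midpoints (Mann-Whitney)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCombineScores:
    def test_pure_outputs(self):
        assert combine_scores([[1.0, 0.0]])[0] == 1.0
        assert combine_scores([[0.5, 0.5]])[0] == 0.0

    def test_multiclass_redirected(self):
        with pytest.raises(ValueError, match="confusion"):
            combine_scores(np.zeros((4, 3)))

    def test_equivalent_to_pre_score_when_outputs_complementary(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(size=50)
        outputs = np.column_stack([pre, 1 - pre])
        labels = rng.integers(0, 2, 50)
        a = roc_auc(combine_scores(outputs), labels).auc
        b = roc_auc(pre, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels).auc == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc(np.ones(10), np.r_[np.ones(5), np.zeros(5)]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.ones(4, dtype=int))

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 400), st.integers(1, 6))
    def test_trapezoid_equals_pair_counting_with_ties(self, seed, n, levels):
        """Property: trapezoidal AUC = exhaustive concordant-pair count,
        including heavy score ties."""
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, levels, size=n).astype(float)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = roc_auc(scores, labels).auc
        want = brute_force_auc(scores, labels)
        assert got == pytest.approx(want, abs=1e-12)


class TestHanleyMcNeil:
    def test_closed_form_by_hand_at_half(self):
        """A=0.5, one sample each: Q1=Q2=1/3, SE=0.5."""
        ci = hanley_mcneil_ci(0.5, 1, 1)
        assert ci.half_width == pytest.approx(1.959963985 * 0.5, rel=1e-9)

    def test_matches_independent_reimplementation(self):
        """Recompute SE from the published formula, written separately."""
        from scipy.stats import norm

        for a, n1, n0 in [(0.8, 50, 100), (0.62, 13, 999), (0.99, 7, 7)]:
            q1 = a / (2 - a)
            q2 = 2 * a * a / (1 + a)
            se = np.sqrt(
                (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a))
                / (n1 * n0)
            )
            want = norm.ppf(0.975) * se
            got = hanley_mcneil_ci(a, n1, n0).half_width
            assert got == pytest.approx(want, abs=1e-10)

    def test_half_width_shrinks_with_sample_size(self):
        widths = [
            hanley_mcneil_ci(0.75, n, n).half_width for n in (5, 20, 80, 320)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_agrees_with_stratified_bootstrap(self):
        """CI width within 15% of a 2000-resample bootstrap at n=200/200."""
        rng = np.random.default_rng(7)
        pos = rng.normal(0.8, 1.0, 200)
        neg = rng.normal(0.0, 1.0, 200)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(200, int), np.zeros(200, int)]
        auc = roc_auc(scores, labels).auc
        ci = hanley_mcneil_ci(auc, 200, 200)
        boot = []
        for _ in range(2000):
            p = pos[rng.integers(0, 200, 200)]
            n = neg[rng.integers(0, 200, 200)]
            boot.append(brute_force_auc_fast(p, n))
        hw_boot = 1.96 * np.std(boot)
        assert abs(ci.half_width - hw_boot) / hw_boot < 0.15

    def test_invalid_auc_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_ci(1.2, 5, 5)


def brute_force_auc_fast(pos, neg):
    from scipy.stats import rankdata

    all_scores = np.r_[pos, neg]
    ranks = rankdata(all_scores)
    return (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )


class TestSignificanceRules:
    def test_non_overlapping_intervals_significant(self):
        a = AucWithCi(0.65, 0.05, 10, 10)   # [0.60, 0.70]
        b = AucWithCi(0.80, 0.05, 10, 10)   # [0.75, 0.85]
        assert compare_aucs(a, b)

    def test_touching_intervals_not_significant(self):
        a = AucWithCi(0.68, 0.08, 10, 10)   # [0.60, 0.76]
        b = AucWithCi(0.80, 0.05, 10, 10)   # [0.75, 0.85]
        assert not compare_aucs(a, b)

    def test_vs_random_needs_lower_bound_above_half(self):
        assert not vs_random(AucWithCi(0.55, 0.06, 30, 30))  # lower 0.49
        assert vs_random(AucWithCi(0.55, 0.04, 30, 30))      # lower 0.51


class TestOperatingPoints:
    def test_sentinel_endpoints(self):
        scores = np.array([0.2, 0.6, 0.9, 0.4])
        labels = np.array([0, 1, 1, 0])
        pts = operating_points(scores, labels)
        assert (pts[0].sensitivity, pts[0].time_in_high) == (1.0, 1.0)
        assert (pts[-1].sensitivity, pts[-1].time_in_high) == (0.0, 0.0)

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        pts = operating_points(scores, labels)
        sens = [p.sensitivity for p in pts]
        tih = [p.time_in_high for p in pts]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a >= b for a, b in zip(tih, tih[1:]))

    def test_match_point_equals_exhaustive_search(self):
        scores = np.array([0.1, 0.2, 0.3, 0.35, 0.5, 0.55, 0.7, 0.8, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1])
        for target in (0.2, 0.5, 0.8, 1.0):
            got = match_point(scores, labels, target_sensitivity=target)
            pts = operating_points(scores, labels)
            best = min(
                pts, key=lambda p: (abs(p.sensitivity - target), p.time_in_high)
            )
            assert (got.sensitivity, got.time_in_high) == (
                best.sensitivity, best.time_in_high,
            )
        got = match_point(scores, labels, target_time_in_high=0.3)
        assert got.time_in_high == pytest.approx(0.3)

    def test_exactly_one_target_required(self):
        with pytest.raises(ValueError):
            match_point(np.arange(4.0), np.array([0, 1, 0, 1]))


class TestConfusionBaseline:
    def test_identity_predictions(self):
        y = np.array([0, 1, 2, 3] * 5)
        rep = confusion_and_baseline(y, y, 4)
        assert rep.total_accuracy == 1.0
        np.testing.assert_array_equal(np.diag(rep.counts), 5)
        np.testing.assert_array_equal(rep.row_normalized.sum(axis=1), 1.0)

    def test_baseline_equals_selection_proportion(self):
        """A random predictor selecting a label p of the time has sensitivity
        p for that label; the report uses the model's own selection rate."""
        y_true = np.array([0] * 50 + [1] * 950)
        y_pred = np.array(([0] * 1 + [1] * 49) + ([0] * 20 + [1] * 930))
        rep = confusion_and_baseline(y_true, y_pred, 2)
        assert rep.baseline_sensitivity[0] == pytest.approx(21 / 1000)
        assert rep.selection_proportions[0] == pytest.approx(21 / 1000)

    def test_uniform_random_predictor_baseline_near_inverse_labels(self):
        rng = np.random.default_rng(11)
        y_true = rng.integers(0, 4, 8000)
        y_pred = rng.integers(0, 4, 8000)
        rep = confusion_and_baseline(y_true, y_pred, 4)
        np.testing.assert_allclose(rep.baseline_sensitivity, 0.25, atol=0.02)
        np.testing.assert_allclose(rep.model_sensitivity, 0.25, atol=0.03)
        assert not rep.better_by_margin.any()
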