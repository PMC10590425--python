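"""Evaluation statistics: confusion, ROC/AUROC, Youden, CIs, paired test."""

import numpy as np
import pytest
from scipy import stats

from esdflow.metrics import (
    auroc_mann_whitney,
    confusion_matrix,
    overall_metrics,
    paired_t_test,
    phase_metrics,
    roc_auroc,
    t_confidence_interval,
    youden_threshold,
)
from esdflow.workflow import Phase


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 2, 2])
        cm = confusion_matrix(y, y)
        assert (cm == np.diag(np.bincount(y, minlength=4))).all()

    def test_direct_count_example(self):
        truth = np.array([0, 0, 1, 2])
        pred = np.array([0, 1, 1, 2])
        cm = confusion_matrix(pred, truth)
        assert cm[0, 0] == 1 and cm[0, 1] == 1 and cm[1, 1] == 1 and cm[2, 2] == 1
        assert cm.sum() == 4

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix(np.array([0, 1]), np.array([0]))


class TestOverallMetrics:
    def test_diagonal_matrix_gives_ones(self):
        acc, prec, rec = overall_metrics(np.diag([5, 3, 2, 1]))
        assert (acc, prec, rec) == (1.0, 1.0, 1.0)

    def test_hand_counted_example(self):
        cm = confusion_matrix(np.array([0, 1, 1, 2]), np.array([0, 0, 1, 2]))
        acc, prec, rec = overall_metrics(cm)
        assert acc == pytest.approx(0.75)
        # precision: M 1/1, Inj 1/2, D 1/1 over the 3 phases present
        assert prec == pytest.approx((1 + 0.5 + 1) / 3)
        # recall: M 1/2, Inj 1/1, D 1/1
        assert rec == pytest.approx((0.5 + 1 + 1) / 3)

    def test_all_wrong_single_class(self):
        cm = confusion_matrix(np.ones(5, dtype=int), np.zeros(5, dtype=int))
        acc, _, _ = overall_metrics(cm)
        assert acc == 0.0

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            overall_metrics(np.zeros((4, 4)))


class TestRocAuroc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        curve = roc_auroc(scores, truth)
        assert curve.auroc == 1.0
        assert curve.fpr[0] == 0 and curve.fpr[-1] == 1
        assert curve.tpr[-1] == 1

    def test_all_tied_scores_give_half(self):
        curve = roc_auroc(np.full(10, 0.5), np.array([1, 0] * 5))
        assert curve.auroc == pytest.approx(0.5)

    def test_random_scores_near_half(self, rng):
        scores = rng.random(10000)
        truth = rng.integers(0, 2, size=10000)
        assert 0.49 <= roc_auroc(scores, truth).auroc <= 0.51

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auroc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_trapezoid_equals_mann_whitney_1000_instances(self, rng):
        """The two AUROC formulations agree to 1e-9, ties included."""
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            assert abs(
                roc_auroc(scores, truth).auroc
                - auroc_mann_whitney(scores, truth)
            ) <= 1e-9


class TestYouden:
    def test_six_point_hand_example(self):
        # P scores {.9,.8,.4}, N scores {.7,.3,.2}: J max 2/3 at thr .8 or .4;
        # tie-break to the higher threshold
        scores = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2])
        truth = np.array([1, 1, 0, 1, 0, 0])
        thr, j = youden_threshold(roc_auroc(scores, truth))
        assert j == pytest.approx(2 / 3)
        assert thr == pytest.approx(0.8)

    def test_perfect_separation_reaches_j_one(self):
        curve = roc_auroc(np.array([0.9, 0.8, 0.2, 0.1]),
                          np.array([1, 1, 0, 0]))
        thr, j = youden_threshold(curve)
        assert j == pytest.approx(1.0)
        assert 0.2 < thr <= 0.8

    def test_matches_exhaustive_search_100_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            scores = np.round(rng.random(n), 2)
            truth = rng.integers(0, 2, size=n)
            if truth.min() == truth.max():
                continue
            curve = roc_auroc(scores, truth)
            thr, j = youden_threshold(curve)
            # brute force over all candidate cuts
            best = -np.inf
            for cut in np.concatenate(([scores.max() + 1], np.unique(scores))):
                pos = scores >= cut
                sens = (pos & (truth == 1)).sum() / (truth == 1).sum()
                spec = (~pos & (truth == 0)).sum() / (truth == 0).sum()
                best = max(best, sens + spec - 1)
            assert j == pytest.approx(best, abs=1e-12)
            # the returned threshold achieves that J
            pos = scores >= thr
            sens = (pos & (truth == 1)).sum() / (truth == 1).sum()
            spec = (~pos & (truth == 0)).sum() / (truth == 0).sum()
            assert sens + spec - 1 == pytest.approx(best, abs=1e-12)


class TestPhaseMetrics:
    def test_printed_ratio_arithmetic(self):
        # TP=8, TN=90, FP=1, FN=1 -> sens 8/9, spec 90/91, orderliness 0.98
        sens, spec, orderl = 8 / 9, 90 / 91, 98 / 100
        # construct scores realizing those counts at threshold 0.5
        y = np.array([1] * 9 + [0] * 91)
        scores = np.concatenate(
            [np.full(8, 0.9), [0.1], [0.9], np.full(90, 0.1)]
        )
        labels = np.where(y == 1, 0, 2)  # phase Marking vs rest
        pm = phase_metrics(scores, labels, Phase.MARKING)
        assert pm.sensitivity == pytest.approx(sens)
        assert pm.specificity == pytest.approx(spec)
        assert pm.orderliness == pytest.approx(orderl)
        assert (pm.tp, pm.tn, pm.fp, pm.fn) == (8, 90, 1, 1)

    def test_perfect_classifier_gives_ones(self):
        labels = np.array([0, 0, 2, 2, 3])
        scores = (labels == 0).astype(float)
        pm = phase_metrics(scores, labels, Phase.MARKING)
        assert (pm.sensitivity, pm.specificity, pm.orderliness) == (1, 1, 1)
        assert pm.auroc == 1.0

    def test_absent_phase_marked_unavailable(self):
        labels = np.array([2, 2, 3, 3])
        pm = phase_metrics(np.array([0.1, 0.2, 0.3, 0.4]), labels, Phase.MARKING)
        assert not pm.available

    def test_random_probs_orderliness_at_least_prevalence_bound(self, rng):
        """With uninformative scores the Youden point can still reach the
        majority-class rate, but not systematically exceed it by much."""
        labels = np.where(rng.random(4000) < 0.3, 0, 2)
        scores = rng.random(4000)
        pm = phase_metrics(scores, labels, Phase.MARKING)
        prev = (labels == 0).mean()
        bound = max(prev, 1 - prev)
        assert pm.orderliness <= bound + 0.05


class TestGroupStatistics:
    def test_equal_values_give_zero_width_interval(self):
        lo, hi = t_confidence_interval(np.full(6, 0.8))
        assert lo == pytest.approx(0.8) and hi == pytest.approx(0.8)

    def test_five_point_hand_example(self):
        # mean 3, sd sqrt(2.5), t_{4,.975}=2.776 -> (1.037, 4.963)
        lo, hi = t_confidence_interval(np.array([1, 2, 3, 4, 5.0]))
        assert lo == pytest.approx(1.0368, abs=2e-4)
        assert hi == pytest.approx(4.9632, abs=2e-4)

    def test_single_case_is_error(self):
        with pytest.raises(ValueError, match="n >= 2"):
            t_confidence_interval(np.array([0.9]))

    def test_paired_t_hand_example_and_symmetry(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 5.0])
        p = paired_t_test(a, b)
        # closed form: d=(1,1,2), t = mean/se = 4, df=2
        t_closed = (4 / 3) / (np.std(b - a, ddof=1) / np.sqrt(3))
        assert t_closed == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.t.sf(4.0, df=2), abs=1e-12)
        assert paired_t_test(b, a) == pytest.approx(p)

    def test_paired_t_sign_flip_permutation_reference(self):
        """Exact sign-flip enumeration: 2 of 8 flips reach |t| >= 4."""
        d = np.array([1.0, 1.0, 2.0])
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        hits = 0
        for signs in np.ndindex(2, 2, 2):
            s = d * np.where(np.array(signs) == 1, 1, -1)
            t = s.mean() / (s.std(ddof=1) / np.sqrt(3))
            hits += abs(t) >= abs(t_obs) - 1e-12
        assert hits / 8 == pytest.approx(0.25)

    def test_identical_samples_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
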