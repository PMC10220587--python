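"""Classification formulas against brute force, and boundary matching
against exhaustive enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafnet.metrics import (ConfusionCounts, boundary_sensitivity, confusion,
                            episode_metrics, report)
from pafnet.records import EpisodeSet, ValidationError
from pafnet.segmentation import BeatLabels


def brute_force_report(tp, fp, tn, fn):
    """Re-derive every metric from an explicit label pair list."""
    true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    n = len(true)
    acc = sum(t == p for t, p in zip(true, pred)) / n
    pos = sum(true)
    neg = n - pos
    ppred = sum(pred)
    se = None if pos == 0 else sum(t and p for t, p in zip(true, pred)) / pos
    sp = None if neg == 0 else sum((not t) and (not p) for t, p in zip(true, pred)) / neg
    pr = None if ppred == 0 else tp / ppred
    f1 = None if (se is None or pr is None or se + pr == 0) else 2 * pr * se / (pr + se)
    fpr = None if neg == 0 else fp / neg
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    mcc = None if den == 0 else (tp * tn - fp * fn) / den
    return acc, se, sp, pr, f1, fpr, mcc


class TestConfusion:
    def test_identical_sequences_no_errors(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.FP, c.FN) == (0, 0)

    def test_enumerated_mixed_case(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_all_positive_predictions_on_negatives(self):
        c = confusion([0] * 7, [1] * 7)
        assert (c.TP, c.FP) == (0, 7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion([1], [1, 0])


class TestReport:
    def test_worked_example(self):
        """TP=9, FN=1, FP=1, TN=89 computed by hand."""
        r = report(ConfusionCounts(TP=9, FP=1, TN=89, FN=1))
        assert r.accuracy == pytest.approx(0.98)
        assert r.sensitivity == pytest.approx(0.90)
        assert r.specificity == pytest.approx(89 / 90)
        assert r.precision == pytest.approx(0.90)
        assert r.f1 == pytest.approx(0.90)
        assert r.fpr == pytest.approx(1 / 90)
        assert r.mcc == pytest.approx(800 / 900)

    def test_perfect_prediction(self):
        r = report(ConfusionCounts(TP=10, TN=20))
        assert (r.accuracy, r.sensitivity, r.specificity, r.f1) == (1, 1, 1, 1)
        assert r.fpr == 0 and r.mcc == 1

    def test_balanced_coin_flip(self):
        r = report(ConfusionCounts(TP=25, FP=25, TN=25, FN=25))
        assert r.accuracy == 0.5 and r.mcc == 0

    def test_undefined_metrics_are_none_not_zero(self):
        r = report(ConfusionCounts(TN=50))          # no positives anywhere
        assert r.sensitivity is None
        assert r.precision is None
        assert r.mcc is None
        assert r.specificity == 1.0

    @given(st.tuples(*[st.integers(min_value=0, max_value=40)] * 4))
    @settings(max_examples=1000, deadline=None)
    def test_matches_bruteforce_on_random_tables(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        r = report(ConfusionCounts(tp, fp, tn, fn))
        for got, expect in zip(
                (r.accuracy, r.sensitivity, r.specificity, r.precision,
                 r.f1, r.fpr, r.mcc),
                brute_force_report(tp, fp, tn, fn)):
            if expect is None:
                assert got is None
            else:
                assert got == pytest.approx(expect, abs=1e-12)

    def test_mcc_one_iff_error_free_two_class(self):
        assert report(ConfusionCounts(TP=3, TN=4)).mcc == 1
        assert report(ConfusionCounts(TP=3, TN=4, FP=1)).mcc < 1


def brute_force_matching(true_pts, pred_pts, tol):
    """Exhaustive search over assignments for the maximum one-to-one
    matching within tolerance (small sets only)."""
    from itertools import permutations
    best = 0
    k = min(len(true_pts), len(pred_pts))
    if not k:
        return 0
    for perm in permutations(range(len(pred_pts)), k):
        m = sum(1 for ti, pi in zip(range(len(true_pts))[:k], perm)
                if abs(true_pts[ti] - pred_pts[pi]) <= tol)
        # try every subset of true points via permuting them too
        best = max(best, m)
    for perm_t in permutations(range(len(true_pts)), k):
        for perm_p in permutations(range(len(pred_pts)), k):
            m = sum(1 for ti, pi in zip(perm_t, perm_p)
                    if abs(true_pts[ti] - pred_pts[pi]) <= tol)
            best = max(best, m)
    return best


class TestBoundaryMatching:
    def test_within_three_beats_matched(self):
        truth = EpisodeSet([(10, 40)], 100)
        pred = EpisodeSet([(12, 40)], 100)
        se_on, se_off, _ = boundary_sensitivity(pred, truth)
        assert se_on == 1.0 and se_off == 1.0

    def test_four_beats_off_not_matched(self):
        truth = EpisodeSet([(10, 40)], 100)
        pred = EpisodeSet([(14, 40)], 100)
        se_on, _, _ = boundary_sensitivity(pred, truth)
        assert se_on == 0.0

    def test_identical_sets_full_sensitivity(self):
        eps = [(5, 9), (20, 30), (40, 44), (50, 60), (70, 80)]
        truth = EpisodeSet(eps, 100)
        se_on, se_off, counts = boundary_sensitivity(EpisodeSet(eps, 100), truth)
        assert se_on == 1.0 and se_off == 1.0
        assert counts["matched_onsets"] == 5

    def test_one_to_one_constraint(self):
        """Two predictions near one annotation consume only one match."""
        truth = EpisodeSet([(10, 20)], 100)
        pred = EpisodeSet([(9, 12), (11, 20)], 100)
        _, _, counts = boundary_sensitivity(pred, truth)
        assert counts["matched_onsets"] == 1

    def test_shift_invariance(self, rng):
        eps_t = [(10, 15), (30, 38), (60, 70)]
        eps_p = [(12, 14), (29, 40), (64, 72)]
        base = boundary_sensitivity(EpisodeSet(eps_p, 200), EpisodeSet(eps_t, 200))
        for shift in (5, 17, 60):
            shifted = boundary_sensitivity(
                EpisodeSet([(a + shift, b + shift) for a, b in eps_p], 400),
                EpisodeSet([(a + shift, b + shift) for a, b in eps_t], 400))
            assert shifted[:2] == base[:2]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        true_pts = sorted(rng.choice(60, size=rng.integers(1, 5), replace=False))
        pred_pts = sorted(rng.choice(60, size=rng.integers(0, 5), replace=False))
        _, _, counts = boundary_sensitivity(
            EpisodeSet([(int(p), int(p) + 100) for p in pred_pts], 400),
            EpisodeSet([(int(t), int(t) + 100) for t in true_pts], 400),
            tol_beats=3)
        assert counts["matched_onsets"] == brute_force_matching(
            list(true_pts), list(pred_pts), 3)


class TestEpisodeMetrics:
    def test_perfect_labels(self):
        flags = np.zeros(100, bool)
        flags[10:30] = True
        r = episode_metrics(BeatLabels(flags), BeatLabels(flags.copy()))
        assert r.accuracy == 1 and r.fpr == 0 and r.mcc == 1

    def test_missed_episode_sensitivity(self):
        """100 AF beats in 1000; prediction misses one 10-beat episode."""
        truth = np.zeros(1000, bool)
        truth[100:190] = True     # 90 beats
        truth[500:510] = True     # 10 beats
        pred = truth.copy()
        pred[500:510] = False
        r = episode_metrics(BeatLabels(pred), BeatLabels(truth))
        assert r.sensitivity == pytest.approx(0.90)

    def test_shifted_episode_matches_bruteforce_overlap(self):
        truth = np.zeros(200, bool)
        truth[50:100] = True
        pred = np.zeros(200, bool)
        pred[52:102] = True
        r = episode_metrics(BeatLabels(pred), BeatLabels(truth))
        tp = int(np.sum(truth & pred))
        fn = int(np.sum(truth & ~pred))
        assert r.sensitivity == pytest.approx(tp / (tp + fn))
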