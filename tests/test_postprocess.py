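"""Record classification, beat-label recovery, episode extraction, and the
two-channel merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pafnet.postprocess import (NORMAL, PAROXYSMAL_AF, PERSISTENT_AF,
                                LabelSequence, beat_labels_from_samples,
                                classify_record, decide_record,
                                extract_episodes, merge_channels)
from pafnet.records import ValidationError
from pafnet.segmentation import BeatLabels


def seq(labels, probs=None, rid="r"):
    labels = np.asarray(labels, dtype=bool)
    return LabelSequence(labels, np.arange(len(labels)), rid, probs)


def af_seq(fraction, n=100):
    n_af = int(round(fraction * n))
    return seq([True] * n_af + [False] * (n - n_af))


class TestClassification:
    @pytest.mark.parametrize("fraction,expected", [
        (0.05, NORMAL),
        (0.95, PERSISTENT_AF),
        (0.10, PAROXYSMAL_AF),   # boundary: strict <
        (0.90, PAROXYSMAL_AF),   # boundary: strict >
        (0.50, PAROXYSMAL_AF),
        (0.0, NORMAL),
        (1.0, PERSISTENT_AF),
    ])
    def test_fraction_rule(self, fraction, expected):
        assert classify_record(af_seq(fraction)) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            classify_record(seq([]))

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(min_value=2, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_duplication_invariance(self, labels, k):
        """The class depends only on the AF fraction, so replicating every
        label k times leaves it unchanged."""
        assert classify_record(seq(labels)) == classify_record(seq(labels * k))


class TestBeatRecovery:
    def test_all_af_samples_all_af_beats(self):
        beats = beat_labels_from_samples(seq([True] * 8), n_beats=11)
        assert beats.labels.all()

    def test_vote_matches_bruteforce_enumeration(self):
        labels = [False, False, True, True, True, False, False]
        got = beat_labels_from_samples(seq(labels), n_beats=10)
        n_samples = len(labels)
        for b in range(10):
            votes = [labels[s] for s in range(max(0, b - 2), min(n_samples, b + 1))]
            if votes:
                expect = sum(votes) * 2 >= len(votes)
                assert got.labels[b] == expect, f"beat {b}"

    def test_isolated_af_sample_suppressed(self):
        """One AF sample inside a non-AF run never wins a majority."""
        labels = [False] * 10 + [True] + [False] * 10
        beats = beat_labels_from_samples(seq(labels), n_beats=24)
        assert not beats.labels.any()

    def test_uncovered_edge_beats_take_nearest_label(self):
        beats = beat_labels_from_samples(seq([True, True, True]), n_beats=7)
        # beats 5..6 are covered by no sample (max covered beat is 2+2)
        assert beats.labels[5] == beats.labels[4]
        assert beats.labels[6] == beats.labels[4]


class TestEpisodeExtraction:
    def test_all_negative_empty(self):
        assert extract_episodes(BeatLabels(np.zeros(50, bool))).episodes == []

    def test_single_run_inclusive_bounds(self):
        flags = np.zeros(100, bool)
        flags[30:60] = True
        eps = extract_episodes(BeatLabels(flags))
        assert eps.episodes == [(30, 59)]

    def test_short_gap_merged(self):
        """AFx5, gap of 1, AFx4 -> one episode spanning 10 beats."""
        flags = np.array([True] * 5 + [False] + [True] * 4)
        eps = extract_episodes(BeatLabels(flags), min_len=2)
        assert eps.episodes == [(0, 9)]

    def test_isolated_single_beat_omitted(self):
        flags = np.zeros(30, bool)
        flags[10] = True
        assert extract_episodes(BeatLabels(flags), min_len=2).episodes == []

    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    @settings(max_examples=80, deadline=None)
    def test_matches_bruteforce_run_processing(self, flags):
        """Oracle: merge sub-min_len gaps, then drop sub-min_len runs,
        computed by explicit run-length scanning."""
        min_len = 2
        f = list(flags)
        # close short gaps
        runs = []
        i = 0
        while i < len(f):
            if f[i]:
                j = i
                while j < len(f) and f[j]:
                    j += 1
                runs.append((i, j - 1))
                i = j
            else:
                i += 1
        for (a, b), (c, d) in zip(runs[:-1], runs[1:]):
            if c - b - 1 < min_len:
                for k in range(b, c + 1):
                    f[k] = True
        # re-scan and filter
        expect = []
        i = 0
        while i < len(f):
            if f[i]:
                j = i
                while j < len(f) and f[j]:
                    j += 1
                if j - i >= min_len:
                    expect.append((i, j - 1))
                i = j
            else:
                i += 1
        got = extract_episodes(BeatLabels(np.array(flags, bool)), min_len).episodes
        assert got == expect


class TestMergeChannels:
    def test_and_rule(self):
        merged = merge_channels(seq([True, True, False]), seq([True, False, False]))
        assert list(merged.labels) == [True, False, False]

    def test_identical_inputs_unchanged(self):
        a = seq([True, False, True])
        merged = merge_channels(a, seq([True, False, True]))
        assert np.array_equal(merged.labels, a.labels)

    def test_high_disagreement_dominant_channel_wins(self):
        labels1 = [True] * 6 + [False] * 4
        labels2 = [not v for v in labels1[:6]] + [True] * 4   # 100% disagreement
        confident = seq(labels1, probs=np.where(labels1, 0.95, 0.05))
        wobbly = seq(labels2, probs=np.full(10, 0.52))
        merged = merge_channels(confident, wobbly)
        assert np.array_equal(merged.labels, confident.labels)

    def test_and_never_increases_af_count(self, rng):
        a = seq(rng.random(50) < 0.5)
        b = seq(rng.random(50) < 0.5)
        merged = merge_channels(a, b)
        assert merged.labels.sum() <= min(a.labels.sum(), b.labels.sum())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            merge_channels(seq([True]), seq([True, False]))


class TestRecordDecision:
    def test_all_af_persistent_full_span(self):
        decision = decide_record(seq([True] * 50), n_beats=53)
        assert decision.rhythm_class == PERSISTENT_AF
        assert decision.episodes.episodes == [(0, 52)]

    def test_all_negative_normal_empty(self):
        decision = decide_record(seq([False] * 50), n_beats=53)
        assert decision.rhythm_class == NORMAL
        assert decision.episodes.episodes == []

    def test_contiguous_block_recovered_within_one_beat(self):
        """50% AF in one block -> paroxysmal with the block localized."""
        labels = [False] * 25 + [True] * 50 + [False] * 25
        decision = decide_record(seq(labels), n_beats=103)
        assert decision.rhythm_class == PAROXYSMAL_AF
        assert len(decision.episodes) == 1
        on, off = decision.episodes.episodes[0]
        assert abs(on - 25) <= 1
        # sample i covers beats i..i+2, so the last AF beat is 74+2
        assert abs(off - 76) <= 1
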