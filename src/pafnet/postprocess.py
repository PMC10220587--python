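"""From per-sample label sequences to record-level decisions.

Covers the whole-record rhythm rule (AF fraction < 0.1 -> normal,
> 0.9 -> persistent AF, otherwise paroxysmal), majority-vote recovery of
per-beat labels from the overlapping 3-beat samples, run-length episode
extraction with isolated-label suppression, and the two-channel voting
merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import EpisodeSet, ValidationError
from .segmentation import BEATS_PER_SAMPLE, BeatLabels

__all__ = [
    "LabelSequence",
    "RecordDecision",
    "classify_record",
    "beat_labels_from_samples",
    "extract_episodes",
    "merge_channels",
    "decide_record",
    "NORMAL",
    "PERSISTENT_AF",
    "PAROXYSMAL_AF",
]

NORMAL = "non-AF"
PERSISTENT_AF = "persistent-AF"
PAROXYSMAL_AF = "paroxysmal-AF"

AF_FRACTION_LOW = 0.1    # below this the record is normal (strict <)
AF_FRACTION_HIGH = 0.9   # above this the record is persistent AF (strict >)
MIN_EPISODE_BEATS = 2    # runs shorter than this count as isolated labels


@dataclass
class LabelSequence:
    """Ordered binary per-sample predictions aligned to start-beat indices."""

    labels: np.ndarray
    start_beats: np.ndarray
    record_id: str = "record"
    probabilities: np.ndarray | None = None
    channel: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)
        self.start_beats = np.asarray(self.start_beats, dtype=np.int64)
        if self.labels.shape != self.start_beats.shape:
            raise ValidationError("labels and start_beats must align")
        if self.start_beats.size and np.any(np.diff(self.start_beats) != 1):
            raise ValidationError("start_beats must increase by exactly 1")
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=np.float64).ravel()
            if self.probabilities.shape != self.labels.shape:
                raise ValidationError("probabilities must align with labels")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def af_fraction(self) -> float:
        if len(self) == 0:
            raise ValidationError("empty label sequence")
        return float(self.labels.mean())


@dataclass
class RecordDecision:
    """Whole-recording rhythm class with localized AF episodes."""

    rhythm_class: str
    episodes: EpisodeSet
    af_fraction: float
    record_id: str = "record"

    def validate(self) -> None:
        if self.rhythm_class == NORMAL and len(self.episodes):
            raise ValidationError("normal records carry no episodes")
        if self.rhythm_class == PERSISTENT_AF and len(self.episodes) != 1:
            raise ValidationError("persistent AF must span the whole record")


def classify_record(seq: LabelSequence) -> str:
    """Three-class rule on the AF sample fraction; boundaries 0.1 and 0.9
    fall in the paroxysmal class (strict inequalities)."""
    frac = seq.af_fraction
    if frac < AF_FRACTION_LOW:
        return NORMAL
    if frac > AF_FRACTION_HIGH:
        return PERSISTENT_AF
    return PAROXYSMAL_AF


def beat_labels_from_samples(seq: LabelSequence, n_beats: int) -> BeatLabels:
    """Majority vote over the <=3 samples covering each beat.

    Sample s covers beats s, s+1, s+2, so beat b is covered by samples
    starting at b-2, b-1 and b.  Ties resolve toward AF.  Edge beats with
    no covering sample inherit the label of the nearest covered beat.
    """
    labels = seq.labels
    n_samples = len(labels)
    out = np.zeros(n_beats, dtype=bool)
    covered = np.zeros(n_beats, dtype=bool)
    for b in range(n_beats):
        lo = max(0, b - BEATS_PER_SAMPLE + 1)
        hi = min(n_samples, b + 1)
        if hi <= lo:
            continue
        votes = labels[lo:hi]
        covered[b] = True
        out[b] = votes.sum() * 2 >= votes.size  # ties -> AF
    if covered.any() and not covered.all():
        cov_idx = np.flatnonzero(covered)
        for b in np.flatnonzero(~covered):
            nearest = cov_idx[np.argmin(np.abs(cov_idx - b))]
            out[b] = out[nearest]
    return BeatLabels(out)


def extract_episodes(beat_labels: BeatLabels,
                     min_len: int = MIN_EPISODE_BEATS) -> EpisodeSet:
    """Maximal AF runs as episodes, after closing short gaps and dropping
    isolated labels.

    Gaps of fewer than ``min_len`` non-AF beats between AF runs are merged
    first; then runs shorter than ``min_len`` beats are omitted.
    """
    flags = beat_labels.labels.copy()
    runs = EpisodeSet.from_beat_flags(flags).episodes
    # close spurious gaps between adjacent runs
    for (_, prev_off), (next_on, _) in zip(runs[:-1], runs[1:]):
        if next_on - prev_off - 1 < min_len:
            flags[prev_off:next_on + 1] = True
    merged = EpisodeSet.from_beat_flags(flags).episodes
    kept = [(on, off) for on, off in merged if off - on + 1 >= min_len]
    return EpisodeSet(kept, len(flags))


def merge_channels(seq1: LabelSequence, seq2: LabelSequence,
                   disagreement_threshold: float = 0.5) -> LabelSequence:
    """Two-channel voting merge.

    Default rule: a sample is AF only when both channels say AF (logical
    AND).  When the channels disagree on more than half of the samples,
    the channel with the higher mean confidence |p - 0.5| dominates and
    its sequence is returned unchanged.
    """
    if len(seq1) != len(seq2):
        raise ValidationError("channel label sequences differ in length")
    disagree = float(np.mean(seq1.labels != seq2.labels)) if len(seq1) else 0.0
    if disagree > disagreement_threshold:
        def confidence(s: LabelSequence) -> float:
            if s.probabilities is None:
                return 0.0
            return float(np.mean(np.abs(s.probabilities - 0.5)))
        return seq1 if confidence(seq1) >= confidence(seq2) else seq2
    probs = None
    if seq1.probabilities is not None and seq2.probabilities is not None:
        probs = np.minimum(seq1.probabilities, seq2.probabilities)
    return LabelSequence(seq1.labels & seq2.labels, seq1.start_beats,
                         seq1.record_id, probs)


def decide_record(seq: LabelSequence, n_beats: int,
                  min_len: int = MIN_EPISODE_BEATS) -> RecordDecision:
    """Compose classification and episode localization for one recording.

    Normal records return no episodes; persistent AF returns the single
    full-span episode; paroxysmal AF returns the extracted episode set.
    """
    rhythm = classify_record(seq)
    if rhythm == NORMAL:
        episodes = EpisodeSet([], n_beats)
    elif rhythm == PERSISTENT_AF:
        episodes = EpisodeSet([(0, n_beats - 1)], n_beats)
    else:
        beats = beat_labels_from_samples(seq, n_beats)
        episodes = extract_episodes(beats, min_len)
    decision = RecordDecision(rhythm, episodes, seq.af_fraction, seq.record_id)
    decision.validate()
    return decision
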