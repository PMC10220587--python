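"""Three-beat sample construction.

A sample covers three consecutive cardiac cycles — signal from R peak i to
R peak i+3 — linearly time-scaled to 600 points with amplitudes untouched.
With N detected peaks every channel yields exactly N-3 samples (sliding
step of one cycle).  A sample is labeled AF if any of its three covered
beats is AF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import RPeakSeries
from .records import EcgRecord, EpisodeSet, ValidationError

__all__ = [
    "SAMPLE_POINTS",
    "BEATS_PER_SAMPLE",
    "EcgSample",
    "BeatLabels",
    "beats_from_episodes",
    "scale_to_600",
    "split_samples",
    "samples_from_record",
]

SAMPLE_POINTS = 600
BEATS_PER_SAMPLE = 3


@dataclass
class EcgSample:
    """One fixed-length, 3-beat network input."""

    values: np.ndarray          # 600 amplitudes, mV
    label: bool                 # True = AF
    start_beat: int             # index of the first covered beat
    record_id: str
    channel: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                f"sample values must be a 1-D series, got {self.values.shape}")


@dataclass
class BeatLabels:
    """Per-beat binary rhythm flags aligned to an R-peak series."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return int(self.labels.size)


def beats_from_episodes(peaks: RPeakSeries | int, episodes: EpisodeSet) -> BeatLabels:
    """Label beat i as AF iff some inclusive [onset, offset] episode holds i."""
    n_beats = peaks if isinstance(peaks, int) else len(peaks)
    for on, off in episodes.episodes:
        if on < 0 or off >= n_beats:
            raise ValidationError(
                f"episode ({on}, {off}) outside the {n_beats}-beat axis")
    return BeatLabels(episodes.beat_flags(n_beats))


def scale_to_600(segment: np.ndarray, n_points: int = SAMPLE_POINTS) -> np.ndarray:
    """Linear time-scaling of a segment onto ``n_points`` abscissae.

    Endpoints are preserved exactly; no padding is used.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size < 2:
        raise ValidationError("segment must have at least 2 samples")
    src = np.arange(segment.size)
    dst = np.linspace(0.0, segment.size - 1, n_points)
    return np.interp(dst, src, segment)


def split_samples(record: EcgRecord, peaks: RPeakSeries,
                  beat_labels: BeatLabels, channel: int = 0,
                  normalize: bool = False) -> list[EcgSample]:
    """Slide a 3-cycle window one cycle at a time over the recording.

    Sample i spans signal[peaks[i] .. peaks[i+3]] and takes the any-AF
    label of beats i, i+1, i+2.  Amplitudes are kept in mV unless
    ``normalize`` requests per-sample z-scoring.
    """
    n = len(peaks)
    if n < BEATS_PER_SAMPLE + 1:
        warnings.warn(f"only {n} R peaks; no 3-beat samples", stacklevel=2)
        return []
    sig = record.signal[channel]
    labels = beat_labels.labels
    out: list[EcgSample] = []
    for i in range(n - BEATS_PER_SAMPLE):
        lo = int(peaks.indices[i])
        hi = int(peaks.indices[i + BEATS_PER_SAMPLE])
        seg = scale_to_600(sig[lo:hi + 1])
        if normalize:
            sd = seg.std()
            seg = (seg - seg.mean()) / (sd if sd > 0 else 1.0)
        label = bool(labels[i:i + BEATS_PER_SAMPLE].any())
        out.append(EcgSample(seg, label, i, record.record_id, channel))
    return out


def samples_from_record(record: EcgRecord, peaks: RPeakSeries | None = None,
                        channel: int = 0) -> list[EcgSample]:
    """Samples for one channel using ground-truth beats/episodes when present.

    When ``peaks`` is omitted the record's annotated beat times are used,
    which keeps sample labels exact for synthetic corpora.
    """
    if peaks is None:
        if record.beat_times is None:
            raise ValidationError("record has no beat annotations; pass peaks")
        peaks = RPeakSeries(record.beat_times,
                            record.signal[channel][record.beat_times], record.fs)
    episodes = record.episodes or EpisodeSet([], len(peaks))
    labels = beats_from_episodes(len(peaks), episodes)
    return split_samples(record, peaks, labels, channel)
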