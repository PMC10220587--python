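"""Noise stress harness: white, EMG-like and motion-artifact surrogates
mixed into raw records at exact signal-to-noise ratios, and an
accuracy-vs-SNR sweep through the full detection pipeline.

The surrogates are generated (unit power, seed-deterministic) rather than
read from a noise database, so the harness runs without downloads; an
external noise recording can be passed to ``scale_and_mix`` directly with
identical mixing semantics.  Baseline wander is deliberately absent from
the catalogue — the preprocessing stage removes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .model import predict_labels
from .preprocess import preprocess_record
from .records import EcgRecord, ValidationError
from .segmentation import split_samples

__all__ = [
    "NoiseSpec",
    "NOISE_KINDS",
    "scale_and_mix",
    "synth_noise",
    "add_noise_to_record",
    "stress_sweep",
    "DEFAULT_SNR_GRID_DB",
]

NOISE_KINDS = ("white", "emg", "motion_artifact")
DEFAULT_SNR_GRID_DB = tuple(range(30, -15, -5))   # 30, 25, ..., -10


@dataclass
class NoiseSpec:
    kind: str
    snr_db: float
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if not np.isfinite(self.snr_db):
            raise ValidationError("snr_db must be finite")


def scale_and_mix(signal: np.ndarray, noise: np.ndarray, snr_db: float,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Add noise scaled so 10 log10(P_signal / P_noise) equals ``snr_db``.

    Powers are mean squares after mean removal over the mixed span.  A
    shorter noise series is tiled with a random offset first.
    """
    signal = np.asarray(signal, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    n = signal.size
    if noise.size < n:
        reps = -(-n // noise.size) + 1
        tiled = np.tile(noise, reps)
        offset = int((rng or np.random.default_rng(0)).integers(0, noise.size))
        noise = tiled[offset:offset + n]
    else:
        noise = noise[:n]
    p_sig = np.mean((signal - signal.mean()) ** 2)
    p_noise = np.mean((noise - noise.mean()) ** 2)
    if p_sig == 0 or p_noise == 0:
        raise ValidationError("zero-power signal or noise")
    scale = np.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return signal + scale * noise


def synth_noise(kind: str, length: int, fs: float, seed: int = 0) -> np.ndarray:
    """Unit-power noise surrogate of the requested kind.

    white: i.i.d. Gaussian.  emg: Gaussian band-passed 20 Hz to 90% of
    Nyquist.  motion_artifact: low-pass-filtered random walk gated by
    random burst envelopes (< 5 Hz energy).
    """
    rng = np.random.default_rng(seed)
    if kind == "white":
        x = rng.standard_normal(length)
    elif kind == "emg":
        sos = butter(4, [20.0, 0.45 * fs], btype="band", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(length + 2000))[1000:-1000]
    elif kind == "motion_artifact":
        walk = np.cumsum(rng.standard_normal(length))
        sos = butter(4, 5.0, btype="low", fs=fs, output="sos")
        x = sosfiltfilt(sos, walk)
        x = x - sosfiltfilt(butter(2, 0.05, btype="low", fs=fs, output="sos"), x)
        envelope = np.zeros(length)
        n_bursts = max(1, length // int(10 * fs))
        for _ in range(n_bursts):
            start = int(rng.integers(0, max(1, length - int(2 * fs))))
            width = int(rng.uniform(1.0, 4.0) * fs)
            stop = min(length, start + width)
            t = np.linspace(0, np.pi, stop - start)
            envelope[start:stop] = np.maximum(envelope[start:stop], np.sin(t))
        x = x * (0.2 + envelope)
    else:
        raise ValidationError(f"unknown noise kind {kind!r}")
    power = np.mean((x - x.mean()) ** 2)
    return (x - x.mean()) / np.sqrt(power)


def add_noise_to_record(record: EcgRecord, spec: NoiseSpec) -> EcgRecord:
    """Record copy with noise mixed into every raw channel at spec.snr_db."""
    spec.validate()
    noisy = np.empty_like(record.signal)
    for ch in range(record.n_channels):
        noise = synth_noise(spec.kind, record.n_samples, record.fs,
                            seed=spec.seed + 7919 * ch)
        noisy[ch] = scale_and_mix(record.signal[ch], noise, spec.snr_db)
    return replace(record, signal=noisy)


def _record_class_accuracy(network, record: EcgRecord, threshold: float
                           ) -> tuple[int, int, int, int]:
    """(correct_normal, n_normal, correct_af, n_af) sample counts for one
    record through the full pipeline (denoise, detect, segment, predict).

    Sample truth labels come from the record's ground-truth beats/episodes
    mapped onto the detected peaks by nearest-beat index.
    """
    _, peaks = preprocess_record(record, channel=0)
    truth_flags = record.episodes.beat_flags(len(record.beat_times))
    # nearest true beat for every detected peak
    pos = np.searchsorted(record.beat_times, peaks.indices)
    pos = np.clip(pos, 1, len(record.beat_times) - 1)
    left = record.beat_times[pos - 1]
    right = record.beat_times[pos]
    nearest = np.where(peaks.indices - left <= right - peaks.indices, pos - 1, pos)
    det_flags = truth_flags[nearest]

    from .segmentation import BeatLabels
    samples = split_samples(record, peaks, BeatLabels(det_flags), channel=0)
    if not samples:
        return 0, 0, 0, 0
    seq = predict_labels(network, samples, threshold)
    truth = np.asarray([s.label for s in samples])
    pred = seq.labels
    n_af = int(truth.sum())
    n_normal = len(truth) - n_af
    correct_af = int(np.sum(pred[truth]))
    correct_normal = int(np.sum(~pred[~truth]))
    return correct_normal, n_normal, correct_af, n_af


def stress_sweep(network, records: list[EcgRecord],
                 kinds=NOISE_KINDS, snr_grid_db=DEFAULT_SNR_GRID_DB,
                 threshold: float = 0.5, seed: int = 0,
                 include_clean: bool = True) -> pd.DataFrame:
    """Per-class sample accuracy of the full pipeline at each (kind, SNR).

    Returns one row per (kind, snr_db) with columns ``accuracy_normal``
    and ``accuracy_af``; the unperturbed baseline appears as kind
    ``clean`` when requested.
    """
    rows = []

    def sweep_point(kind: str | None, snr: float | None) -> dict:
        cn = nn = ca = na = 0
        for i, rec in enumerate(records):
            noisy = rec if kind is None else add_noise_to_record(
                rec, NoiseSpec(kind, snr, seed=seed + 104729 * i))
            a, b, c, d = _record_class_accuracy(network, noisy, threshold)
            cn, nn, ca, na = cn + a, nn + b, ca + c, na + d
        return {
            "kind": kind or "clean",
            "snr_db": np.nan if snr is None else float(snr),
            "accuracy_normal": cn / nn if nn else np.nan,
            "accuracy_af": ca / na if na else np.nan,
            "n_normal": nn, "n_af": na,
        }

    if include_clean:
        rows.append(sweep_point(None, None))
    for kind in kinds:
        for snr in snr_grid_db:
            rows.append(sweep_point(kind, float(snr)))
    return pd.DataFrame(rows)
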