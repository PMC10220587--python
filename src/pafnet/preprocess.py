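"""ECG denoising and R-peak location.

Order of the chain: median-cascade baseline removal (0.2 s then 0.6 s
windows), impulse rejection against a 5-point rolling median, a zero-phase
40 Hz Butterworth low-pass, Pan-Tompkins QRS detection, and an amplitude
based correction pass that deletes spurious detections inside
physiologically too-short (< 0.5 s) R-R intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, sosfiltfilt

from .records import EcgRecord, ValidationError

__all__ = [
    "RPeakSeries",
    "remove_baseline",
    "lowpass_40hz",
    "remove_impulses",
    "denoise",
    "detect_rpeaks",
    "correct_rpeaks",
    "preprocess_record",
    "MIN_RR_S",
    "AMPLITUDE_RATIO",
]

MIN_RR_S = 0.5          # R-R intervals shorter than this trigger correction
AMPLITUDE_RATIO = 0.6   # "obviously lower" = below this fraction of neighbours
IMPULSE_K = 8.0         # impulse threshold in robust standard deviations


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak sample indices with their amplitudes."""

    indices: np.ndarray
    amplitudes: np.ndarray
    fs: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValidationError("R-peak indices must be strictly increasing")
        if self.indices.shape != self.amplitudes.shape:
            raise ValidationError("indices and amplitudes must align")

    def __len__(self) -> int:
        return int(self.indices.size)

    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.indices) / self.fs


def _odd(n: int) -> int:
    return n if n % 2 else n + 1


def remove_baseline(signal: np.ndarray, fs: float) -> np.ndarray:
    """Subtract the baseline estimated by cascaded 0.2 s and 0.6 s medians."""
    signal = np.asarray(signal, dtype=np.float64)
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    w_long = _odd(int(round(0.6 * fs)))
    if signal.size < w_long:
        raise ValidationError(
            f"signal of {signal.size} samples shorter than the 0.6 s window")
    w_short = _odd(int(round(0.2 * fs)))
    baseline = median_filter(
        median_filter(signal, size=w_short, mode="nearest"),
        size=w_long, mode="nearest")
    return signal - baseline


def lowpass_40hz(signal: np.ndarray, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass, -3 dB at 40 Hz."""
    if fs <= 80:
        raise ValidationError("need fs > 80 Hz for a 40 Hz cutoff")
    b, a = butter(order, 40.0, btype="low", fs=fs)
    return filtfilt(b, a, np.asarray(signal, dtype=np.float64))


def remove_impulses(signal: np.ndarray, k: float = IMPULSE_K) -> np.ndarray:
    """Replace isolated impulse samples by the local 5-point rolling median.

    A sample is an impulse when its deviation from the rolling median
    exceeds ``k`` times the global robust scale of the signal (1.4826 MAD).
    Clean signals pass through unchanged.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValidationError("empty signal")
    rolling = median_filter(signal, size=5, mode="nearest")
    scale = 1.4826 * np.median(np.abs(signal - np.median(signal)))
    if scale == 0:
        return signal.copy()
    bad = np.abs(signal - rolling) > k * scale
    out = signal.copy()
    out[bad] = rolling[bad]
    return out


def denoise(signal: np.ndarray, fs: float) -> np.ndarray:
    """Full conditioning chain: baseline -> impulses -> 40 Hz low-pass."""
    return lowpass_40hz(remove_impulses(remove_baseline(signal, fs)), fs)


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------


def _moving_integration(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks(signal: np.ndarray, fs: float) -> RPeakSeries:
    """Pan-Tompkins detector on a denoised single-channel signal.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds with search-back.
    Each detection is refined to the signal maximum within +/-40 ms.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2 * fs:
        raise ValidationError("need at least 2 s of signal for QRS detection")

    sos = butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    band = sosfiltfilt(sos, signal)
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    integ = _moving_integration(deriv * deriv, max(1, int(round(0.150 * fs))))

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated waveform
    cand = np.flatnonzero((integ[1:-1] > integ[:-2]) & (integ[1:-1] >= integ[2:])) + 1
    if cand.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return RPeakSeries(np.array([], dtype=np.int64), np.array([]), fs)

    spki = float(np.max(integ[:int(2 * fs)])) * 0.25
    npki = float(np.mean(integ[:int(2 * fs)])) * 0.5
    peaks: list[int] = []
    rr_hist: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < cand.size:
        c = cand[i]
        level = integ[c]
        if peaks and c - peaks[-1] < refractory:
            i += 1
            continue
        if level > threshold1():
            spki = 0.125 * level + 0.875 * spki
            if peaks:
                rr_hist.append(c - peaks[-1])
                rr_hist[:] = rr_hist[-8:]
            peaks.append(int(c))
        else:
            npki = 0.125 * level + 0.875 * npki
            # search-back: no beat within 1.66x the running R-R average
            if peaks and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if c - peaks[-1] > 1.66 * rr_avg:
                    window = cand[(cand > peaks[-1] + refractory) & (cand <= c)]
                    if window.size:
                        best = window[np.argmax(integ[window])]
                        if integ[best] > 0.5 * threshold1():
                            spki = 0.25 * integ[best] + 0.75 * spki
                            rr_hist.append(best - peaks[-1])
                            rr_hist[:] = rr_hist[-8:]
                            peaks.append(int(best))
        i += 1

    if not peaks:
        warnings.warn("no R peaks above threshold", stacklevel=2)
        return RPeakSeries(np.array([], dtype=np.int64), np.array([]), fs)

    # the integration peak lags the QRS by up to half the window: snap to
    # the QRS-band maximum first, then to the signal maximum within +/-40 ms
    snap = int(round(0.100 * fs))
    half = int(round(0.040 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - snap), min(signal.size, p + snap + 1)
        p = lo + int(np.argmax(band[lo:hi]))
        lo, hi = max(0, p - half), min(signal.size, p + half + 1)
        refined.append(lo + int(np.argmax(signal[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    return RPeakSeries(refined, signal[refined], fs)


def correct_rpeaks(peaks: RPeakSeries, signal: np.ndarray, fs: float,
                   min_rr_s: float = MIN_RR_S,
                   alpha: float = AMPLITUDE_RATIO) -> RPeakSeries:
    """Delete low-amplitude detections that create too-short R-R intervals.

    For every interval shorter than ``min_rr_s``, the member of the pair
    whose amplitude falls below ``alpha`` times the smaller of its two
    neighbouring peak amplitudes is removed; the pass repeats until no
    short interval has a deletable member.  Genuine short AF intervals
    between comparable-amplitude beats are kept.
    """
    signal = np.asarray(signal, dtype=np.float64)
    idx = list(peaks.indices)
    amps = list(np.asarray(signal)[peaks.indices]) if len(peaks) else []
    floor = min_rr_s * fs

    def neighbour_floor(j: int) -> float:
        neigh = []
        if j - 1 >= 0:
            neigh.append(amps[j - 1])
        if j + 1 < len(amps):
            neigh.append(amps[j + 1])
        return min(neigh) if neigh else np.inf

    changed = True
    while changed:
        changed = False
        for j in range(len(idx) - 1):
            if idx[j + 1] - idx[j] >= floor:
                continue
            for member in (j, j + 1):
                if amps[member] < alpha * neighbour_floor(member):
                    del idx[member], amps[member]
                    changed = True
                    break
            if changed:
                break
    return RPeakSeries(np.asarray(idx, dtype=np.int64),
                       np.asarray(amps, dtype=np.float64), fs)


def preprocess_record(record: EcgRecord, channel: int = 0) -> tuple[np.ndarray, RPeakSeries]:
    """Denoise one channel and return it with corrected R peaks."""
    clean = denoise(record.signal[channel], record.fs)
    peaks = detect_rpeaks(clean, record.fs)
    return clean, correct_rpeaks(peaks, clean, record.fs)
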