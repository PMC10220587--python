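"""ECG record containers, WFDB-style file I/O, and a synthetic generator.

The on-disk layout follows the MIT/PhysioNet conventions: a text header
(``.hea``), 16-bit interleaved signal samples (``.dat``, format 16), and a
binary annotation file (``.atr``) holding beat marks plus rhythm-change
strings such as ``(AFIB`` / ``(N`` in AUX fields.  Only the subset of the
format needed for dynamic-ECG rhythm work is supported.

The generator builds records from Gaussian P-QRS-T bumps.  Atrial
fibrillation segments drop the P wave, superimpose a fibrillatory (f-wave)
oscillation, and draw R-R intervals with a much larger coefficient of
variation than sinus rhythm — the three ECG hallmarks the classifier is
meant to pick up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "EpisodeSet",
    "EcgRecord",
    "SynthConfig",
    "read_record",
    "write_record",
    "generate_record",
    "generate_corpus",
    "TARGET_FS",
    "AF_RHYTHM_CODES",
]

TARGET_FS = 200  # every record is resampled to this rate on read

#: rhythm strings mapped to the positive (AF) class; everything else is non-AF.
AF_RHYTHM_CODES = frozenset({"(AFIB", "(AFL"})

# MIT annotation type codes used here
_CODE_NORMAL = 1      # beat annotation
_CODE_RHYTHM = 28     # rhythm change, aux string holds the label
_CODE_SKIP = 59
_CODE_NUM = 60
_CODE_SUB = 61
_CODE_CHN = 62
_CODE_AUX = 63

_ADC_GAIN = 1000.0    # adu per mV -> quantization step 1 uV


class ValidationError(ValueError):
    """Raised when a record or config violates its invariants."""


@dataclass
class EpisodeSet:
    """AF episodes as inclusive (onset_beat, offset_beat) index pairs."""

    episodes: list[tuple[int, int]] = field(default_factory=list)
    n_beats_total: int = 0

    def validate(self) -> None:
        prev_off = -1
        for on, off in self.episodes:
            if on > off:
                raise ValidationError(f"episode onset {on} after offset {off}")
            if on <= prev_off:
                raise ValidationError("episodes overlap or are unsorted")
            if self.n_beats_total and off >= self.n_beats_total:
                raise ValidationError(
                    f"episode offset {off} outside beat range {self.n_beats_total}")
            prev_off = off

    def beat_flags(self, n_beats: int | None = None) -> np.ndarray:
        """Boolean per-beat AF flags implied by the episodes."""
        n = self.n_beats_total if n_beats is None else n_beats
        flags = np.zeros(n, dtype=bool)
        for on, off in self.episodes:
            flags[on:off + 1] = True
        return flags

    def __len__(self) -> int:
        return len(self.episodes)

    @classmethod
    def from_beat_flags(cls, flags: np.ndarray) -> "EpisodeSet":
        flags = np.asarray(flags, dtype=bool)
        eps: list[tuple[int, int]] = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                eps.append((start, i - 1))
                start = None
        if start is not None:
            eps.append((start, len(flags) - 1))
        return cls(eps, int(len(flags)))


@dataclass
class EcgRecord:
    """A multichannel ECG with optional ground-truth beats and episodes."""

    signal: np.ndarray                  # (n_channels, n_samples), mV
    fs: float
    channel_names: list[str]
    beat_times: np.ndarray | None = None    # sample indices of R peaks
    episodes: EpisodeSet | None = None      # beat-indexed AF episodes
    record_id: str = "record"

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise ValidationError("signal must be (n_channels, n_samples)")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError("one name per channel required")
        if self.beat_times is not None:
            bt = np.asarray(self.beat_times)
            if bt.size and (np.any(np.diff(bt) <= 0)):
                raise ValidationError("beat_times must be strictly increasing")
            if bt.size and (bt[0] < 0 or bt[-1] >= self.n_samples):
                bad = bt[0] if bt[0] < 0 else bt[-1]
                raise ValidationError(f"beat index {bad} outside signal")
        if self.episodes is not None:
            n_beats = 0 if self.beat_times is None else len(self.beat_times)
            es = EpisodeSet(self.episodes.episodes, n_beats)
            es.validate()


# ---------------------------------------------------------------------------
# WFDB-style I/O
# ---------------------------------------------------------------------------


def _base_path(path) -> Path:
    p = Path(path)
    if p.suffix in {".hea", ".dat", ".atr"}:
        p = p.with_suffix("")
    return p


def _write_annotations(path: Path, annotations: list[tuple[int, int, str | None]]) -> None:
    """Write (sample, code, aux) annotations in MIT .atr binary format."""
    words = bytearray()
    prev = 0
    for t, code, aux in sorted(annotations, key=lambda a: (a[0], a[1] != _CODE_RHYTHM)):
        delta = t - prev
        if delta > 1023 or delta < 0:
            words += int((_CODE_SKIP << 10)).to_bytes(2, "little")
            words += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            words += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        words += ((code << 10) | delta).to_bytes(2, "little")
        prev = t
        if aux is not None:
            raw = aux.encode("ascii")
            words += ((_CODE_AUX << 10) | len(raw)).to_bytes(2, "little")
            words += raw
            if len(raw) % 2:
                words += b"\x00"
    words += (0).to_bytes(2, "little")
    path.write_bytes(bytes(words))


def _read_annotations(path: Path) -> list[tuple[int, int, str | None]]:
    data = path.read_bytes()
    out: list[tuple[int, int, str | None]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = int.from_bytes(data[i:i + 2], "little")
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _CODE_SKIP and delta == 0:
            hi = int.from_bytes(data[i:i + 2], "little")
            lo = int.from_bytes(data[i + 2:i + 4], "little")
            i += 4
            t += (hi << 16) | lo
            continue
        if code == _CODE_AUX:
            aux = data[i:i + delta].decode("ascii")
            i += delta + (delta % 2)
            if out:
                s, c, _ = out[-1]
                out[-1] = (s, c, aux)
            continue
        if code in (_CODE_NUM, _CODE_SUB, _CODE_CHN):
            continue
        t += delta
        out.append((t, code, None))
    return out


def _episodes_to_rhythm_labels(record: EcgRecord) -> list[tuple[int, str]]:
    """Rhythm-change annotations (sample, label) implied by the episodes."""
    if record.episodes is None or not record.episodes.episodes:
        return []
    bt = np.asarray(record.beat_times)
    flags = record.episodes.beat_flags(len(bt))
    labels = [(int(bt[0]), "(AFIB" if flags[0] else "(N")]
    for i in range(1, len(flags)):
        if flags[i] != flags[i - 1]:
            labels.append((int(bt[i]), "(AFIB" if flags[i] else "(N"))
    return labels


def _rhythm_labels_to_episodes(labels: list[tuple[int, str]],
                               beat_times: np.ndarray,
                               n_samples: int) -> EpisodeSet:
    """Inverse of the above: label switches -> inclusive beat-index episodes."""
    n_beats = len(beat_times)
    if not labels or n_beats == 0:
        return EpisodeSet([], n_beats)
    for sample, _ in labels:
        if sample >= n_samples:
            raise ValidationError(
                f"rhythm annotation at sample {sample} beyond signal length {n_samples}")
    flags = np.zeros(n_beats, dtype=bool)
    starts = np.searchsorted(beat_times, [s for s, _ in labels], side="left")
    for (sample, label), start in zip(labels, starts):
        flags[start:] = label in AF_RHYTHM_CODES
    return EpisodeSet.from_beat_flags(flags)


def write_record(record: EcgRecord, path) -> None:
    """Write .hea/.dat (+ .atr when annotations exist) for ``record``."""
    record.validate()
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    digital = np.clip(np.round(record.signal * _ADC_GAIN), -32768, 32767).astype(np.int16)
    lines = [f"{base.name} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for ch in range(record.n_channels):
        d = digital[ch]
        first = int(d[0]) if d.size else 0
        checksum = int(np.int16(d.astype(np.int64).sum() & 0xFFFF))
        lines.append(
            f"{base.name}.dat 16 {_ADC_GAIN:g}(0)/mV 16 0 {first} {checksum} 0 "
            f"{record.channel_names[ch]}")
    (base.parent / f"{base.name}.hea").write_text("\n".join(lines) + "\n")
    (base.parent / f"{base.name}.dat").write_bytes(
        np.ascontiguousarray(digital.T).astype("<i2").tobytes())
    if record.beat_times is not None:
        anns = [(int(t), _CODE_NORMAL, None) for t in np.asarray(record.beat_times)]
        anns += [(s, _CODE_RHYTHM, lab) for s, lab in _episodes_to_rhythm_labels(record)]
        _write_annotations(base.parent / f"{base.name}.atr", anns)


def read_record(path, target_fs: float | None = TARGET_FS,
                af_codes: frozenset[str] = AF_RHYTHM_CODES) -> EcgRecord:
    """Read a WFDB header/signal pair (and .atr rhythm annotations if present).

    Rhythm strings in ``af_codes`` map to AF; all others map to non-AF.
    When the stored rate differs from ``target_fs`` the signal is resampled
    with a polyphase filter and all annotation indices are rescaled.
    """
    base = _base_path(path)
    hea = base.parent / f"{base.name}.hea"
    dat = base.parent / f"{base.name}.dat"
    if not hea.exists() or not dat.exists():
        raise FileNotFoundError(f"missing WFDB files for record {base}")
    header = [ln for ln in hea.read_text().splitlines()
              if ln.strip() and not ln.startswith("#")]
    rid, nsig, fs, nsamp = header[0].split()[:4]
    nsig, fs, nsamp = int(nsig), float(fs), int(nsamp)
    gains, baselines, names = [], [], []
    for ln in header[1:1 + nsig]:
        tok = ln.split()
        if tok[1] != "16":
            raise ValidationError(f"unsupported signal format {tok[1]}")
        gspec = tok[2]
        gain_part = gspec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_part))
            baselines.append(0)
        names.append(tok[8] if len(tok) > 8 else f"ch{len(names)}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2").reshape(-1, nsig).T
    signal = (raw.astype(np.float64) - np.array(baselines)[:, None]) \
        / np.array(gains)[:, None]

    beat_times = None
    episodes = None
    atr = base.parent / f"{base.name}.atr"
    if atr.exists():
        anns = _read_annotations(atr)
        for sample, _, _ in anns:
            if sample >= nsamp:
                raise ValidationError(
                    f"annotation index {sample} beyond signal length {nsamp}")
        beats = [s for s, c, _ in anns if c == _CODE_NORMAL]
        rhythms = [(s, aux) for s, c, aux in anns
                   if c == _CODE_RHYTHM and aux is not None]
        beat_times = np.asarray(beats, dtype=np.int64)
        episodes = _rhythm_labels_to_episodes(rhythms, beat_times, nsamp)

    if target_fs is not None and fs != target_fs:
        frac = Fraction(target_fs).limit_denominator() / Fraction(fs).limit_denominator()
        signal = np.stack([
            resample_poly(signal[ch], frac.numerator, frac.denominator)
            for ch in range(nsig)])
        if beat_times is not None:
            beat_times = np.round(beat_times * float(frac)).astype(np.int64)
            beat_times = np.minimum(beat_times, signal.shape[1] - 1)
        fs = float(target_fs)

    rec = EcgRecord(signal=signal, fs=fs, channel_names=names,
                    beat_times=beat_times, episodes=episodes, record_id=rid)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Synthetic dynamic-ECG generator
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Conditions for one synthetic dynamic-ECG record.

    ``rhythm_plan`` is an ordered list of (rhythm, n_beats) with rhythm in
    {"NSR", "AF"}.  R-R intervals are lognormal per rhythm; AF must be more
    irregular than sinus rhythm (``rr_cv_af > rr_jitter_nsr``).  AF beats
    lose their P bump and gain a fibrillatory oscillation of ``f_wave_amp``
    mV at ``f_wave_hz``.
    """

    duration_s: float | None = None
    fs: float = float(TARGET_FS)
    rhythm_plan: list[tuple[str, int]] | None = None
    mean_hr_bpm: float = 75.0
    rr_jitter_nsr: float = 0.05
    rr_cv_af: float = 0.25
    f_wave_hz: float = 6.0
    f_wave_amp: float = 0.1
    r_amp: float = 1.0
    n_channels: int = 2
    sensor_noise_mv: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.rhythm_plan is not None and len(self.rhythm_plan) == 0:
            raise ValidationError("rhythm_plan must not be empty")
        if self.rhythm_plan is None and self.duration_s is None:
            raise ValidationError("either rhythm_plan or duration_s is required")
        if self.rr_cv_af <= self.rr_jitter_nsr:
            raise ValidationError("AF R-R variability must exceed NSR variability")
        if self.f_wave_amp >= self.r_amp:
            raise ValidationError("f-wave amplitude must stay below the R wave")
        if not 4.0 <= self.f_wave_hz <= 10.0:
            raise ValidationError("f-wave frequency outside the 4-10 Hz band")
        for rhythm, n in self.rhythm_plan or []:
            if rhythm not in ("NSR", "AF") or n < 1:
                raise ValidationError(f"bad rhythm plan entry ({rhythm}, {n})")


def _lognormal_rr(rng: np.random.Generator, mean_rr: float, cv: float, n: int) -> np.ndarray:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean_rr) - sigma2 / 2.0
    rr = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.clip(rr, 0.3, 3.0)


def _add_bump(sig: np.ndarray, fs: float, center_s: float, sd_s: float,
              amp: float) -> None:
    lo = max(0, int((center_s - 4 * sd_s) * fs))
    hi = min(len(sig), int((center_s + 4 * sd_s) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sd_s) ** 2)


def generate_record(config: SynthConfig) -> EcgRecord:
    """Generate one record with exact ground-truth beats and episodes.

    Pure function of ``config.seed``: identical configs give bit-identical
    signals.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mean_rr = 60.0 / config.mean_hr_bpm

    plan = config.rhythm_plan
    if plan is None:
        plan = [("NSR", max(4, int(config.duration_s / mean_rr)))]

    rhythms: list[str] = []
    rr: list[np.ndarray] = []
    for rhythm, n in plan:
        cv = config.rr_cv_af if rhythm == "AF" else config.rr_jitter_nsr
        rr.append(_lognormal_rr(rng, mean_rr, cv, n))
        rhythms.extend([rhythm] * n)
    rr_all = np.concatenate(rr)
    beat_t = 0.5 + np.concatenate([[0.0], np.cumsum(rr_all[:-1])])
    n_beats = len(beat_t)
    af_flags = np.array([r == "AF" for r in rhythms])

    total_s = beat_t[-1] + mean_rr
    if config.duration_s is not None:
        total_s = max(total_s, config.duration_s)
    n_samples = int(round(total_s * config.fs))

    rr_prev = np.concatenate([[rr_all[0]], rr_all[:-1]])
    rr_next = rr_all

    signal = np.zeros((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        sig = signal[ch]
        # channel-specific morphology: lead II-like vs a scaled lead I-like
        ch_scale = 1.0 if ch == 0 else 0.75
        amp_jit = rng.normal(1.0, 0.03, size=n_beats)
        for i in range(n_beats):
            r = beat_t[i]
            sp = rr_prev[i] / 0.8   # stretch latencies with the local cycle
            sn = rr_next[i] / 0.8
            a = config.r_amp * ch_scale * amp_jit[i]
            if not af_flags[i]:
                _add_bump(sig, config.fs, r - 0.17 * sp, 0.022 * sp, 0.12 * ch_scale)
            _add_bump(sig, config.fs, r - 0.025, 0.010, -0.15 * ch_scale)
            _add_bump(sig, config.fs, r, 0.012, a)
            _add_bump(sig, config.fs, r + 0.030, 0.012, -0.25 * ch_scale)
            _add_bump(sig, config.fs, r + 0.25 * math.sqrt(sn), 0.05 * sn,
                      0.35 * ch_scale)
        # fibrillatory oscillation over each AF span
        for on, off in EpisodeSet.from_beat_flags(af_flags).episodes:
            t0 = beat_t[on] - 0.5 * rr_prev[on]
            t1 = beat_t[off] + 0.5 * rr_next[off]
            lo, hi = max(0, int(t0 * config.fs)), min(n_samples, int(t1 * config.fs))
            n = hi - lo
            if n <= 0:
                continue
            phase = (2 * math.pi * config.f_wave_hz * np.arange(n) / config.fs
                     + np.cumsum(rng.normal(0.0, 0.15, size=n))
                     + rng.uniform(0, 2 * math.pi))
            sig[lo:hi] += config.f_wave_amp * ch_scale * np.sin(phase)
        if config.sensor_noise_mv > 0:
            sig += rng.normal(0.0, config.sensor_noise_mv, size=n_samples)

    beat_times = np.round(beat_t * config.fs).astype(np.int64)
    episodes = EpisodeSet.from_beat_flags(af_flags)
    rec = EcgRecord(
        signal=signal, fs=config.fs,
        channel_names=[f"lead{'I' * (ch + 1)}" for ch in range(config.n_channels)],
        beat_times=beat_times, episodes=episodes,
        record_id=f"synth{config.seed:05d}")
    rec.validate()
    return rec


def generate_corpus(n_records: int = 200, beats_per_record: int = 100,
                    seed: int = 0, n_channels: int = 1,
                    class_mix: tuple[float, float, float] = (0.51, 0.33, 0.16),
                    ) -> list[EcgRecord]:
    """A corpus of normal / persistent-AF / paroxysmal-AF records.

    ``class_mix`` is the (normal, persistent, paroxysmal) record fraction,
    defaulting to the roughly 51/33/16 split of dynamic-ECG challenge
    corpora.  Paroxysmal records carry one or two AF episodes of at least
    5 beats at random positions.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_normal = int(round(class_mix[0] * n_records))
    n_persistent = int(round(class_mix[1] * n_records))
    kinds = (["normal"] * n_normal + ["persistent"] * n_persistent
             + ["paroxysmal"] * (n_records - n_normal - n_persistent))
    out = []
    for i, kind in enumerate(kinds):
        if kind == "normal":
            plan = [("NSR", beats_per_record)]
        elif kind == "persistent":
            plan = [("AF", beats_per_record)]
        else:
            n_eps = int(rng.integers(1, 3))
            plan = []
            remaining = beats_per_record
            for e in range(n_eps):
                pre = int(rng.integers(5, max(6, remaining // (2 * n_eps))))
                af = int(rng.integers(5, max(6, remaining // (2 * n_eps))))
                plan += [("NSR", pre), ("AF", af)]
                remaining -= pre + af
            plan.append(("NSR", max(4, remaining)))
        cfg = SynthConfig(rhythm_plan=plan, n_channels=n_channels,
                          mean_hr_bpm=float(rng.uniform(60, 95)),
                          seed=int(rng.integers(0, 2 ** 31)))
        rec = generate_record(cfg)
        rec.record_id = f"synth{i:04d}"
        out.append(rec)
    return out
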