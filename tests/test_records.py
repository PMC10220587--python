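"""Record container, WFDB-style round-trips, resampling, and the generator."""

import numpy as np
import pytest

from pafnet.records import (AF_RHYTHM_CODES, EcgRecord, EpisodeSet, SynthConfig,
                            ValidationError, generate_corpus, generate_record,
                            read_record, write_record)
from pafnet.records import _rhythm_labels_to_episodes


class TestRoundTrip:
    def test_annotations_preserved_exactly(self, paroxysmal_record, tmp_path):
        rid = paroxysmal_record.record_id
        write_record(paroxysmal_record, tmp_path / rid)
        back = read_record(tmp_path / rid)
        assert np.array_equal(back.beat_times, paroxysmal_record.beat_times)
        assert back.episodes.episodes == paroxysmal_record.episodes.episodes
        assert back.record_id == paroxysmal_record.record_id

    def test_signal_within_quantization(self, paroxysmal_record, tmp_path):
        write_record(paroxysmal_record, tmp_path / "r")
        back = read_record(tmp_path / "r")
        assert back.signal.shape == paroxysmal_record.signal.shape
        # 16-bit ADC at 1000 adu/mV: error bounded by half a step
        assert np.max(np.abs(back.signal - paroxysmal_record.signal)) <= 0.5 / 1000

    def test_empty_episodes_write_no_rhythm_labels(self, nsr_record, tmp_path):
        write_record(nsr_record, tmp_path / "r")
        back = read_record(tmp_path / "r")
        assert back.episodes.episodes == []

    def test_missing_files_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_record(tmp_path / "nonexistent")

    def test_two_channel_round_trip(self, tmp_path):
        rec = generate_record(SynthConfig(rhythm_plan=[("NSR", 20)], seed=5,
                                          n_channels=2))
        write_record(rec, tmp_path / "r")
        back = read_record(tmp_path / "r")
        assert back.n_channels == 2
        assert np.max(np.abs(back.signal - rec.signal)) <= 0.5 / 1000


class TestResampling:
    def test_beat_index_scaling_360_to_200(self, tmp_path):
        """A beat annotated at sample 720 of a 360 Hz record lands at 400."""
        fs = 360.0
        n = 1440
        t = np.arange(n) / fs
        sig = np.sin(2 * np.pi * 1.0 * t)[None, :]
        rec = EcgRecord(sig, fs, ["ch0"], beat_times=np.array([360, 720, 1080]),
                        episodes=EpisodeSet([], 3), record_id="r360")
        write_record(rec, tmp_path / "r360")
        back = read_record(tmp_path / "r360", target_fs=200)
        assert back.fs == 200
        assert list(back.beat_times) == [200, 400, 600]

    @pytest.mark.parametrize("fs", [128, 200, 250, 300, 360])
    def test_episode_structure_survives_resampling(self, fs, tmp_path):
        rng = np.random.default_rng(fs)
        n = int(10 * fs)
        beats = np.arange(int(0.5 * fs), n - fs, int(0.8 * fs))
        sig = rng.standard_normal((1, n)) * 0.1
        eps = EpisodeSet([(2, 4), (7, 9)], len(beats))
        rec = EcgRecord(sig, float(fs), ["ch0"], beats, eps, f"r{fs}")
        write_record(rec, tmp_path / f"r{fs}")
        back = read_record(tmp_path / f"r{fs}")
        assert back.episodes.episodes == eps.episodes
        assert back.fs == 200

    def test_annotation_beyond_signal_rejected(self, tmp_path):
        rec = EcgRecord(np.zeros((1, 100)), 200.0, ["ch0"],
                        beat_times=np.array([10, 50]), record_id="bad")
        write_record(rec, tmp_path / "bad")
        # corrupt: claim fewer samples in the header than annotated
        hea = tmp_path / "bad.hea"
        lines = hea.read_text().splitlines()
        parts = lines[0].split()
        parts[3] = "20"
        hea.write_text("\n".join([" ".join(parts)] + lines[1:]) + "\n")
        with pytest.raises(ValidationError, match="50"):
            read_record(tmp_path / "bad")


class TestRhythmLabelMapping:
    def test_label_switches_build_inclusive_episodes(self):
        """(N at beat 0), (AFIB at 50), (N at 120) -> episode (50, 119)."""
        beat_times = np.arange(200) * 160 + 100
        labels = [(int(beat_times[0]), "(N"),
                  (int(beat_times[50]), "(AFIB"),
                  (int(beat_times[120]), "(N")]
        eps = _rhythm_labels_to_episodes(labels, beat_times, 40000)
        assert eps.episodes == [(50, 119)]

    def test_afl_is_positive_class(self):
        beat_times = np.arange(10) * 160
        labels = [(0, "(AFL")]
        eps = _rhythm_labels_to_episodes(labels, beat_times, 2000)
        assert eps.episodes == [(0, 9)]
        assert "(AFL" in AF_RHYTHM_CODES

    def test_junctional_rhythm_is_negative(self):
        beat_times = np.arange(10) * 160
        eps = _rhythm_labels_to_episodes([(0, "(J")], beat_times, 2000)
        assert eps.episodes == []


class TestGenerator:
    def test_determinism(self):
        cfg = SynthConfig(rhythm_plan=[("NSR", 10), ("AF", 10)], seed=7)
        a = generate_record(cfg)
        b = generate_record(cfg)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_plan_produces_exact_episode(self):
        rec = generate_record(SynthConfig(
            rhythm_plan=[("NSR", 50), ("AF", 30), ("NSR", 40)], seed=1))
        assert rec.episodes.episodes == [(50, 79)]
        assert len(rec.beat_times) == 120

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_af_rr_more_irregular_than_nsr(self, seed):
        nsr = generate_record(SynthConfig(rhythm_plan=[("NSR", 1000)], seed=seed))
        af = generate_record(SynthConfig(rhythm_plan=[("AF", 1000)], seed=seed))

        def cv(rec):
            rr = np.diff(rec.beat_times)
            return rr.std() / rr.mean()

        assert cv(af) > cv(nsr)

    def test_af_beats_lack_p_wave_power(self):
        """Mean pre-R amplitude in the P window is higher for NSR."""
        nsr = generate_record(SynthConfig(rhythm_plan=[("NSR", 100)], seed=3,
                                          sensor_noise_mv=0.0, f_wave_amp=0.05))
        af = generate_record(SynthConfig(rhythm_plan=[("AF", 100)], seed=3,
                                         sensor_noise_mv=0.0, f_wave_amp=0.05))

        def p_window_peak(rec):
            fs = rec.fs
            vals = []
            for t in rec.beat_times[1:-1]:
                lo, hi = int(t - 0.22 * fs), int(t - 0.10 * fs)
                vals.append(rec.signal[0, lo:hi].max())
            return np.median(vals)

        assert p_window_peak(nsr) > 2 * p_window_peak(af)

    def test_empty_plan_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(rhythm_plan=[]).validate()

    def test_af_variability_invariant_enforced(self):
        with pytest.raises(ValidationError):
            SynthConfig(rhythm_plan=[("AF", 5)], rr_jitter_nsr=0.3,
                        rr_cv_af=0.2).validate()

    def test_corpus_mix_and_determinism(self):
        c1 = generate_corpus(n_records=20, beats_per_record=30, seed=9)
        c2 = generate_corpus(n_records=20, beats_per_record=30, seed=9)
        assert len(c1) == 20
        assert all(np.array_equal(a.signal, b.signal) for a, b in zip(c1, c2))
        fracs = [r.episodes.beat_flags(len(r.beat_times)).mean() for r in c1]
        assert any(f == 0 for f in fracs)          # normal records
        assert any(f == 1 for f in fracs)          # persistent AF
        assert any(0 < f < 1 for f in fracs)       # paroxysmal


class TestInvariantChecks:
    def test_nonmonotonic_beats_rejected(self):
        rec = EcgRecord(np.zeros((1, 100)), 200.0, ["ch0"],
                        beat_times=np.array([10, 5]))
        with pytest.raises(ValidationError):
            rec.validate()

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(ValidationError):
            EpisodeSet([(0, 5), (3, 8)], 10).validate()
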