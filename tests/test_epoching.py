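"""Windowing arithmetic, extrema detection and label derivation."""

import numpy as np
import pytest

from ecgbp import Epoch, SignalRecord, SimConfig, generate_subject, segment
from ecgbp.epoching import (
    LabelDerivationError,
    derive_labels,
    detect_extrema,
    is_usable,
    read_signal_csv,
)


def _bp_epoch(samples, fs=64.0, duration=None):
    samples = np.asarray(samples, dtype=float)
    duration = duration if duration is not None else samples.size / fs
    return Epoch(samples=samples, sampling_rate_hz=fs, duration_s=duration,
                 subject_id="S0", modality="BP", start_index=0)


class TestSegment:
    def test_count_and_window_size(self):
        rec = SignalRecord(np.arange(640.0), 64.0)
        epochs = segment(rec, 2.0)
        assert len(epochs) == 5
        assert all(e.samples.size == 128 for e in epochs)

    def test_trailing_partial_window_dropped(self):
        rec = SignalRecord(np.arange(9 * 64, dtype=float), 64.0)
        assert len(segment(rec, 2.0)) == 4

    def test_duration_longer_than_record(self):
        rec = SignalRecord(np.arange(64.0), 64.0)
        assert segment(rec, 2.0) == []

    @pytest.mark.parametrize("n_seconds,duration", [(60, 2), (60, 7), (123, 20)])
    def test_count_matches_direct_loop(self, n_seconds, duration):
        fs = 64.0
        rec = SignalRecord(np.zeros(int(n_seconds * fs)), fs)
        # oracle: walk windows explicitly
        expected, start, win = 0, 0, int(duration * fs)
        while start + win <= rec.samples.size:
            expected += 1
            start += win
        assert len(segment(rec, duration)) == expected

    def test_partition_property(self):
        rec = SignalRecord(np.random.default_rng(0).normal(size=500), 64.0)
        epochs = segment(rec, 1.5)
        concat = np.concatenate([e.samples for e in epochs])
        np.testing.assert_array_equal(concat, rec.samples[: concat.size])
        assert all(e.start_index == i * 96 for i, e in enumerate(epochs))


class TestDetectExtrema:
    def test_four_beats_in_four_seconds(self):
        _, bp, _ = generate_subject(SimConfig(
            duration_s=4.0, noise_sd=0.0, sbp_sd_mmHg=0, dbp_sd_mmHg=0,
            hr_jitter_frac=0.0,
        ))
        maxima, minima = detect_extrema(segment(bp, 4.0)[0])
        assert maxima.size == 4 and minima.size == 4

    def test_beat_count_oracle_72_bpm(self):
        """A noiseless 10 s epoch at 72 bpm holds floor(10 * 72 / 60) = 12 beats."""
        _, bp, _ = generate_subject(SimConfig(
            duration_s=10.0, heart_rate_bpm=72.0, noise_sd=0.0,
            sbp_sd_mmHg=0, dbp_sd_mmHg=0, hr_jitter_frac=0.0,
        ))
        maxima, _ = detect_extrema(segment(bp, 10.0)[0])
        assert maxima.size == 12

    def test_constant_signal_unusable(self):
        epoch = _bp_epoch(np.full(256, 100.0))
        assert not is_usable(epoch)

    def test_requires_bp_modality(self):
        epoch = Epoch(np.zeros(128), 64.0, 2.0, "S0", "ECG", 0)
        with pytest.raises(ValueError):
            detect_extrema(epoch)


class TestDeriveLabels:
    def test_mean_of_extrema_values(self):
        """A synthetic pressure trace whose beat peaks are 120,122,118,120 and
        troughs 80,80,82,78 labels as their means (120, 80)."""
        fs, beat = 64.0, 1.0
        peaks = [120.0, 122.0, 118.0, 120.0]
        troughs = [80.0, 80.0, 82.0, 78.0]
        t = np.arange(int(4 * fs)) / fs
        beat_idx = np.minimum((t // beat).astype(int), 3)
        phase = t % beat
        lo = np.array(troughs)[beat_idx]
        hi = np.array(peaks)[beat_idx]
        samples = lo + (hi - lo) * 0.5 * (1 + np.sin(2 * np.pi * phase))
        label = derive_labels(_bp_epoch(samples))
        assert label.sbp_mmHg == pytest.approx(np.mean(peaks), abs=0.05)
        assert label.dbp_mmHg == pytest.approx(np.mean(troughs), abs=0.05)

    def test_shift_equivariance(self):
        _, bp, _ = generate_subject(SimConfig(duration_s=6.0, seed=3))
        epoch = segment(bp, 6.0)[0]
        shifted = _bp_epoch(epoch.samples + 10.0, duration=6.0)
        a = derive_labels(epoch)
        b = derive_labels(shifted)
        assert b.sbp_mmHg == pytest.approx(a.sbp_mmHg + 10.0, abs=1e-9)
        assert b.dbp_mmHg == pytest.approx(a.dbp_mmHg + 10.0, abs=1e-9)

    def test_unusable_epoch_reports_provenance(self):
        epoch = Epoch(np.full(256, 90.0), 64.0, 4.0, "S7", "BP", 512, epoch_index=2)
        with pytest.raises(LabelDerivationError, match="S7"):
            derive_labels(epoch)


class TestReader:
    def test_two_column_csv_infers_rate(self, tmp_path):
        path = tmp_path / "sig.csv"
        t = np.arange(100) / 64.0
        path.write_text("time_s,value\n" + "\n".join(f"{a},{b}" for a, b in zip(t, np.sin(t))))
        rec = read_signal_csv(path)
        assert rec.sampling_rate_hz == pytest.approx(64.0)
        assert rec.samples.size == 100

    def test_single_column_requires_rate(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("\n".join(str(v) for v in range(50)))
        with pytest.raises(ValueError):
            read_signal_csv(path)
        rec = read_signal_csv(path, sampling_rate_hz=10.0)
        assert rec.duration_s == pytest.approx(5.0)
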