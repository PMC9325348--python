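"""The generator must encode known per-beat pressures in the BP waveform,
couple the ECG morphology to them as configured, and be fully reproducible."""

import dataclasses

import numpy as np
import pytest

from ecgbp import Coupling, SimConfig, generate_cohort, generate_subject, segment
from ecgbp.epoching import derive_labels, read_signal_csv
from ecgbp.pipeline import build_feature_table
from ecgbp.selection import rank_features
from ecgbp.synthetic import write_subject


def _constant_config(**kwargs):
    base = dict(
        duration_s=4.0, noise_sd=0.0, sbp_sd_mmHg=0.0, dbp_sd_mmHg=0.0,
        hr_jitter_frac=0.0, heart_rate_bpm=60.0,
    )
    base.update(kwargs)
    return SimConfig(**base)


class TestGenerateSubject:
    def test_shared_rate_and_length(self):
        cfg = SimConfig(duration_s=10.0, seed=5)
        ecg, bp, _ = generate_subject(cfg)
        assert ecg.sampling_rate_hz == bp.sampling_rate_hz == 64.0
        assert ecg.samples.size == bp.samples.size == cfg.n_samples == 640

    def test_constant_pressure_waveform_extrema(self):
        """4 s at 60 bpm with fixed 120/80: the pressure trace carries exactly
        four maxima equal to 120 and four minima equal to 80."""
        ecg, bp, truth = generate_subject(_constant_config())
        epoch = segment(bp, 4.0)[0]
        label = derive_labels(epoch)
        assert label.n_maxima == 4
        assert label.n_minima == 4
        assert label.sbp_mmHg == pytest.approx(120.0, abs=1e-6)
        assert label.dbp_mmHg == pytest.approx(80.0, abs=1e-6)

    def test_determinism(self):
        cfg = SimConfig(duration_s=30.0, seed=17)
        a = generate_subject(cfg)
        b = generate_subject(cfg)
        np.testing.assert_array_equal(a[0].samples, b[0].samples)
        np.testing.assert_array_equal(a[1].samples, b[1].samples)
        np.testing.assert_array_equal(a[2].sbp_mmHg, b[2].sbp_mmHg)

    def test_per_beat_ordering_invariant(self):
        _, _, truth = generate_subject(SimConfig(duration_s=300.0, seed=9, sbp_sd_mmHg=15, dbp_sd_mmHg=12))
        assert np.all(truth.sbp_mmHg > truth.dbp_mmHg)

    @pytest.mark.parametrize("bad", [
        dict(duration_s=-1.0),
        dict(duration_s=10.0, sampling_rate_hz=0.0),
        dict(duration_s=10.0, heart_rate_bpm=-5.0),
        dict(duration_s=10.0, sbp_mean_mmHg=80.0, dbp_mean_mmHg=120.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)

    def test_label_distribution_matches_config(self):
        """At ~1000 beats the per-beat label moments match the configured
        means/SDs within 3 standard errors."""
        cfg = SimConfig(duration_s=1000.0, seed=2)
        _, _, truth = generate_subject(cfg)
        n = truth.sbp_mmHg.size
        assert n >= 950
        se_mean = cfg.sbp_sd_mmHg / np.sqrt(n)
        assert abs(truth.sbp_mmHg.mean() - 120.0) < 3 * se_mean
        assert abs(truth.dbp_mmHg.mean() - 80.0) < 3 * (cfg.dbp_sd_mmHg / np.sqrt(n))
        # SD of an SD estimate ~ sd / sqrt(2(n-1))
        assert abs(truth.sbp_mmHg.std(ddof=1) - 10.0) < 3 * 10.0 / np.sqrt(2 * (n - 1))
        assert abs(truth.dbp_mmHg.std(ddof=1) - 7.0) < 3 * 7.0 / np.sqrt(2 * (n - 1))

    def test_noiseless_label_roundtrip(self):
        """Labels recovered from the generated pressure waveform equal the
        per-beat truth means within interpolation error."""
        cfg = SimConfig(duration_s=120.0, noise_sd=0.0, hr_jitter_frac=0.02, seed=4)
        _, bp, truth = generate_subject(cfg)
        errors = []
        for ep in segment(bp, 10.0):
            label = derive_labels(ep)
            t0, t1 = ep.start_time_s, ep.start_time_s + 10.0
            in_win = (truth.beat_times_s >= t0) & (truth.beat_times_s < t1)
            errors.append(abs(label.sbp_mmHg - truth.sbp_mmHg[in_win].mean()))
            errors.append(abs(label.dbp_mmHg - truth.dbp_mmHg[in_win].mean()))
        assert np.mean(errors) < 1.0


class TestCohort:
    def test_count_and_lengths(self):
        cohort = generate_cohort(5, SimConfig(duration_s=20.0, seed=1))
        assert len(cohort) == 5
        lengths = {ecg.samples.size for ecg, _, _ in cohort}
        assert lengths == {1280}

    def test_reproducible_and_subjects_differ(self):
        cfg = SimConfig(duration_s=20.0, seed=8)
        a = generate_cohort(3, cfg)
        b = generate_cohort(3, cfg)
        for (ea, _, _), (eb, _, _) in zip(a, b):
            np.testing.assert_array_equal(ea.samples, eb.samples)
        assert not np.array_equal(a[0][0].samples, a[1][0].samples)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            generate_cohort(0, SimConfig(duration_s=10.0))


def test_zero_coupling_leaves_labels_independent_of_features():
    """With coupling off, no ECG feature correlates with the SBP labels
    beyond the null spread (|r_s| < 0.1 over 500 decorrelated epochs)."""
    cfg = SimConfig(
        duration_s=2000.0, coupling=Coupling.zero(), drift_timescale_s=4.0, seed=0,
    )
    subject = generate_subject(cfg)
    table = build_feature_table([subject], 4.0)
    assert len(table) == 500
    ranked = rank_features(table, table["sbp"].to_numpy(), target="SBP")
    assert np.abs(ranked.r_s).max() < 0.1


def test_writer_roundtrip(tmp_path):
    cfg = SimConfig(duration_s=8.0, seed=6)
    ecg, bp, truth = generate_subject(cfg)
    paths = write_subject(tmp_path, ecg, bp, truth, config=cfg)
    back = read_signal_csv(paths["bp"], subject_id=bp.subject_id, modality="BP")
    assert back.sampling_rate_hz == pytest.approx(64.0, rel=1e-6)
    np.testing.assert_allclose(back.samples, bp.samples, atol=1e-6)
    assert paths["truth"].exists()
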