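"""Synthetic paired ECG/BP generator with known per-beat ground truth.

The generator emulates the kind of recording the pipeline consumes: a
beat-periodic ECG-like spike train and a synchronized arterial-pressure-like
oscillation whose per-beat extrema encode the true systolic (SBP) and
diastolic (DBP) pressures.  Because the truth is known per beat, every
downstream stage — epoching, labelling, feature extraction, selection,
regression — can be tested quantitatively.

Model
-----
Beats occur at jittered intervals around the configured heart rate.  Three
standardized per-beat latent series drive the physiology:

* ``z_amp`` — a slow (drift-timescale) amplitude process, shared between the
  ECG spike height and the pressure targets;
* ``z_rate`` — the per-beat rate deviation (the jitter, standardized);
* independent slow drift and white-noise residuals per target.

Per-beat pressures are linear in the latents,

    SBP_i = sbp_mean + sbp_sd * (wa*z_amp_i + wr*z_rate_i + wd*d_i + we*e_i)

with the coupling weights ``wa, wr`` taken from the configuration and the
residual weights chosen so the total variance equals ``sbp_sd**2`` (80 % of
the residual variance goes to the slow drift, 20 % to white noise).  DBP is
built the same way from its own residuals, then clipped to stay at least
5 mmHg below SBP so the systolic/diastolic ordering always holds.

The ECG is a train of Gaussian R-spikes (FWHM 40 ms) whose height is
``1 + 0.25 * z_amp``; the pressure waveform rises within each beat from the
diastolic trough to the systolic peak and back along a phase-shifted raised
cosine, so every beat contributes exactly one interior maximum and one
interior minimum.  White measurement noise of standard deviation ``noise_sd``
is added to both signals.

Everything is driven by ``numpy.random.default_rng(seed)``: identical
configurations produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .epoching import SignalRecord, write_signal_csv

#: Gaussian R-spike width: full width at half maximum, seconds
_SPIKE_FWHM_S = 0.040
_SPIKE_SIGMA_S = _SPIKE_FWHM_S / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: ECG spike-height modulation per unit amplitude z-score
_AMP_MODULATION = 0.25

#: minimum systolic-diastolic gap enforced per beat, mmHg
_MIN_PULSE_PRESSURE = 5.0


@dataclass(frozen=True)
class Coupling:
    """Standardized-latent coupling weights linking ECG morphology to BP.

    Each weight is the fraction of the target's standard deviation explained
    by the corresponding latent; ``amp`` couples to the slow ECG spike-height
    process and ``rate`` to the per-beat rate deviation.  The squared weights
    per target must not exceed 1.
    """

    amp_to_sbp: float = 0.6
    rate_to_sbp: float = 0.2
    amp_to_dbp: float = 0.6
    rate_to_dbp: float = 0.2

    def __post_init__(self) -> None:
        for a, r, name in (
            (self.amp_to_sbp, self.rate_to_sbp, "SBP"),
            (self.amp_to_dbp, self.rate_to_dbp, "DBP"),
        ):
            if a * a + r * r > 1.0 + 1e-12:
                raise ValueError(f"{name} coupling weights exceed unit variance")

    @classmethod
    def zero(cls) -> "Coupling":
        """No ECG↔BP coupling: labels are independent of the ECG."""
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class SimConfig:
    """Configuration of one synthetic recording.

    Defaults follow a resting healthy adult: 64 Hz sampling, 60 bpm,
    120/80 mmHg with 10/7 mmHg beat-to-beat standard deviations and a
    one-minute drift timescale.
    """

    duration_s: float
    sampling_rate_hz: float = 64.0
    heart_rate_bpm: float = 60.0
    hr_jitter_frac: float = 0.03
    sbp_mean_mmHg: float = 120.0
    sbp_sd_mmHg: float = 10.0
    dbp_mean_mmHg: float = 80.0
    dbp_sd_mmHg: float = 7.0
    drift_timescale_s: float = 60.0
    coupling: Coupling = field(default_factory=Coupling)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if self.hr_jitter_frac < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise must be non-negative")
        if self.sbp_sd_mmHg < 0 or self.dbp_sd_mmHg < 0:
            raise ValueError("pressure SDs must be non-negative")
        if self.sbp_mean_mmHg <= self.dbp_mean_mmHg:
            raise ValueError("mean SBP must exceed mean DBP")
        if self.drift_timescale_s <= 0:
            raise ValueError("drift_timescale_s must be positive")
        if isinstance(self.coupling, dict):
            self.coupling = Coupling(**self.coupling)

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.duration_s))


@dataclass
class GroundTruth:
    """Per-beat truth of one synthetic subject."""

    beat_times_s: np.ndarray
    sbp_mmHg: np.ndarray
    dbp_mmHg: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.sbp_mmHg = np.asarray(self.sbp_mmHg, dtype=float)
        self.dbp_mmHg = np.asarray(self.dbp_mmHg, dtype=float)
        if not np.all(self.sbp_mmHg > self.dbp_mmHg):
            raise ValueError("per-beat SBP must exceed DBP")


def _slow_latent(n: int, beats_per_drift: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized slowly varying per-beat latent series.

    A Gaussian random walk input is smoothed with an exponential moving
    average whose memory spans ``beats_per_drift`` beats, then empirically
    standardized so the weights in the pressure model are exact fractions of
    the target SD.
    """
    white = rng.standard_normal(n)
    if n < 2:
        return np.zeros(n)
    alpha = 1.0 / max(1.0, beats_per_drift)
    out = np.empty(n)
    out[0] = white[0]
    for i in range(1, n):
        out[i] = (1 - alpha) * out[i - 1] + alpha * white[i]
    sd = out.std()
    if sd == 0:
        return np.zeros(n)
    return (out - out.mean()) / sd


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _residualize(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Project out the (standardized, zero-mean) basis columns and
    re-standardize.

    Slow latents are strongly autocorrelated, so over a finite recording two
    independent draws can show a large sample correlation; orthogonalizing
    them in-sample makes the coupling weights exact variance fractions and
    the configured pressure SDs exact per record.
    """
    out = x - x.mean()
    for b in basis:
        denom = float(b @ b)
        if denom > 0:
            out = out - (out @ b) / denom * b
    return _standardize(out)


def _pressure_series(
    mean: float,
    sd: float,
    w_amp: float,
    w_rate: float,
    z_amp: np.ndarray,
    z_rate: np.ndarray,
    rng: np.random.Generator,
    beats_per_drift: float,
) -> np.ndarray:
    residual = max(0.0, 1.0 - w_amp**2 - w_rate**2)
    w_drift = np.sqrt(0.8 * residual)
    w_eps = np.sqrt(0.2 * residual)
    n = z_amp.size
    drift = _residualize(_slow_latent(n, beats_per_drift, rng), [z_amp, z_rate])
    eps = _residualize(rng.standard_normal(n), [z_amp, z_rate, drift])
    return mean + sd * (w_amp * z_amp + w_rate * z_rate + w_drift * drift + w_eps * eps)


def generate_subject(
    config: SimConfig,
) -> tuple[SignalRecord, SignalRecord, GroundTruth]:
    """Generate one subject's paired ECG and BP records plus the beat truth.

    Returns ``(ecg, bp, truth)``; the two records share sampling rate and
    length (``config.n_samples``).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = config.n_samples
    t = np.arange(n) / fs

    # --- beat schedule -----------------------------------------------------
    mean_period = 60.0 / config.heart_rate_bpm
    max_beats = int(np.ceil(config.duration_s / mean_period)) + 2
    jitter = rng.standard_normal(max_beats)
    periods = mean_period * (1.0 + config.hr_jitter_frac * jitter)
    periods = np.clip(periods, 0.4 * mean_period, 2.0 * mean_period)
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    keep = starts < config.duration_s
    starts, periods, jitter = starts[keep], periods[keep], jitter[keep]
    n_beats = starts.size

    # --- latent processes and per-beat pressures ---------------------------
    beats_per_drift = config.drift_timescale_s / mean_period
    z_amp = _slow_latent(n_beats, beats_per_drift, rng)
    if config.hr_jitter_frac > 0:
        z_rate = _residualize(_standardize(jitter), [z_amp])
    else:
        z_rate = np.zeros(n_beats)
    cpl = config.coupling
    sbp = _pressure_series(
        config.sbp_mean_mmHg, config.sbp_sd_mmHg,
        cpl.amp_to_sbp, cpl.rate_to_sbp, z_amp, z_rate, rng, beats_per_drift,
    )
    dbp = _pressure_series(
        config.dbp_mean_mmHg, config.dbp_sd_mmHg,
        cpl.amp_to_dbp, cpl.rate_to_dbp, z_amp, z_rate, rng, beats_per_drift,
    )
    dbp = np.minimum(dbp, sbp - _MIN_PULSE_PRESSURE)

    # --- ECG: Gaussian R-spike train ---------------------------------------
    amp = np.clip(1.0 + _AMP_MODULATION * z_amp, 0.2, None)
    ecg = np.zeros(n)
    half_width = 4.0 * _SPIKE_SIGMA_S
    for t0, a in zip(starts, amp):
        lo = max(0, int(np.floor((t0 - half_width) * fs)))
        hi = min(n, int(np.ceil((t0 + half_width) * fs)) + 1)
        ecg[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - t0) / _SPIKE_SIGMA_S) ** 2)

    # --- BP: one interior max (SBP) and min (DBP) per beat -----------------
    beat_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_beats - 1)
    phase = (t - starts[beat_idx]) / periods[beat_idx]
    bp = dbp[beat_idx] + (sbp[beat_idx] - dbp[beat_idx]) * 0.5 * (
        1.0 + np.sin(2.0 * np.pi * phase)
    )

    if config.noise_sd > 0:
        ecg = ecg + config.noise_sd * rng.standard_normal(n)
        bp = bp + config.noise_sd * rng.standard_normal(n)

    ecg_rec = SignalRecord(ecg, fs, subject_id=f"S{config.seed}", modality="ECG")
    bp_rec = SignalRecord(bp, fs, subject_id=f"S{config.seed}", modality="BP")
    truth = GroundTruth(beat_times_s=starts, sbp_mmHg=sbp, dbp_mmHg=dbp)
    return ecg_rec, bp_rec, truth


def generate_cohort(
    n_subjects: int, config: SimConfig
) -> list[tuple[SignalRecord, SignalRecord, GroundTruth]]:
    """Generate ``n_subjects`` independent subjects.

    Subject ``k`` uses seed ``config.seed + k``, so cohorts are reproducible
    and subjects differ in their drift realizations.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    cohort = []
    for k in range(n_subjects):
        sub_cfg = dataclasses.replace(config, seed=config.seed + k)
        ecg, bp, truth = generate_subject(sub_cfg)
        ecg.subject_id = bp.subject_id = f"S{k}"
        cohort.append((ecg, bp, truth))
    return cohort


def write_subject(
    out_dir: str | Path,
    ecg: SignalRecord,
    bp: SignalRecord,
    truth: GroundTruth,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write one subject as two-column CSVs plus a JSON truth/config sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = ecg.subject_id
    paths = {
        "ecg": out_dir / f"{sid}_ecg.csv",
        "bp": out_dir / f"{sid}_bp.csv",
        "truth": out_dir / f"{sid}_truth.json",
    }
    write_signal_csv(ecg, paths["ecg"])
    write_signal_csv(bp, paths["bp"])
    sidecar = {
        "subject_id": sid,
        "beat_times_s": truth.beat_times_s.tolist(),
        "sbp_mmHg": truth.sbp_mmHg.tolist(),
        "dbp_mmHg": truth.dbp_mmHg.tolist(),
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        sidecar["config"] = cfg
    paths["truth"].write_text(json.dumps(sidecar))
    return paths
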