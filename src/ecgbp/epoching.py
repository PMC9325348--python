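"""Segmentation of paired ECG/BP waveforms into fixed-duration epochs and
derivation of per-epoch systolic/diastolic labels from the arterial pressure
waveform.

A continuous blood-pressure waveform oscillates once per heartbeat between the
diastolic trough and the systolic peak.  The per-epoch label is therefore the
mean of the interior local maxima (SBP) and the mean of the interior local
minima (DBP) of the pressure samples inside the window.

Windows are 0-based and half-open, ``[start, start + round(duration * fs))``;
a trailing partial window is discarded.  Extrema detection applies a light
5-sample moving average before the peak search and enforces a minimum peak
separation of 0.33 s, which caps the detectable heart rate at 180 bpm.
Extrema at the first or last sample of a window are excluded: they are window
artifacts, not beats.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

#: canonical epoch durations, in seconds
EPOCH_DURATIONS_S: tuple[float, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)

#: minimum separation between detected beats, seconds (180 bpm ceiling)
MIN_PEAK_SEPARATION_S = 0.33

#: moving-average window applied before the extrema search, samples
SMOOTHING_SAMPLES = 5


class LabelDerivationError(ValueError):
    """Raised when an epoch has no usable pressure extrema."""


@dataclass
class SignalRecord:
    """One subject's uniformly sampled waveform.

    Parameters
    ----------
    samples : array-like of float
        The waveform values.
    sampling_rate_hz : float
        Sampling frequency, must be positive.
    subject_id : str
        Identifier of the recorded subject.
    modality : {"ECG", "BP"}
        Which physiological signal the record holds.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    subject_id: str = "S0"
    modality: str = "ECG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a signal record needs at least two samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.modality not in ("ECG", "BP"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass
class Epoch:
    """A fixed-duration contiguous window of a record."""

    samples: np.ndarray
    sampling_rate_hz: float
    duration_s: float
    subject_id: str
    modality: str
    start_index: int
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(self.duration_s * self.sampling_rate_hz))
        if self.samples.size != expected:
            raise ValueError(
                f"epoch of {self.duration_s} s at {self.sampling_rate_hz} Hz "
                f"must hold {expected} samples, got {self.samples.size}"
            )

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.sampling_rate_hz


@dataclass
class EpochLabel:
    """Per-epoch blood-pressure label derived from the pressure extrema."""

    sbp_mmHg: float
    dbp_mmHg: float
    n_maxima: int
    n_minima: int

    def __post_init__(self) -> None:
        if self.sbp_mmHg < self.dbp_mmHg:
            raise ValueError("systolic label below diastolic label")


def segment(record: SignalRecord, duration_s: float) -> list[Epoch]:
    """Split ``record`` into consecutive non-overlapping epochs.

    The trailing partial window is discarded, so the epoch count equals
    ``floor(len(record) / (duration_s * fs))``.  A duration longer than the
    record yields an empty list.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    win = int(round(duration_s * record.sampling_rate_hz))
    if win < 2:
        raise ValueError("epoch window must span at least two samples")
    n_epochs = record.samples.size // win
    return [
        Epoch(
            samples=record.samples[k * win : (k + 1) * win],
            sampling_rate_hz=record.sampling_rate_hz,
            duration_s=duration_s,
            subject_id=record.subject_id,
            modality=record.modality,
            start_index=k * win,
            epoch_index=k,
        )
        for k in range(n_epochs)
    ]


def _smooth(x: np.ndarray, width: int = SMOOTHING_SAMPLES) -> np.ndarray:
    if x.size < width:
        return x
    kernel = np.ones(width) / width
    # reflect-pad so the smoothed series keeps the input length and no
    # spurious edge extrema are introduced by zero padding
    pad = width // 2
    padded = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]])
    return np.convolve(padded, kernel, mode="valid")


def detect_extrema(bp_epoch: Epoch) -> tuple[np.ndarray, np.ndarray]:
    """Locate interior local maxima and minima of a pressure epoch.

    Returns ``(maxima_indices, minima_indices)`` into the epoch's samples.
    Boundary samples are never reported as extrema.
    """
    if bp_epoch.modality != "BP":
        raise ValueError("extrema detection expects a BP epoch")
    x = _smooth(bp_epoch.samples)
    distance = max(1, int(round(MIN_PEAK_SEPARATION_S * bp_epoch.sampling_rate_hz)))
    maxima, _ = find_peaks(x, distance=distance)
    minima, _ = find_peaks(-x, distance=distance)
    return maxima, minima


def is_usable(bp_epoch: Epoch) -> bool:
    """An epoch is usable when it contains at least one maximum and minimum."""
    maxima, minima = detect_extrema(bp_epoch)
    return maxima.size >= 1 and minima.size >= 1


def derive_labels(bp_epoch: Epoch) -> EpochLabel:
    """Average the pressure values at the detected extrema.

    SBP is the mean of the raw samples at the maxima, DBP the mean at the
    minima.  Raises :class:`LabelDerivationError` for epochs without usable
    extrema, carrying the epoch provenance in the message.
    """
    maxima, minima = detect_extrema(bp_epoch)
    if maxima.size < 1 or minima.size < 1:
        raise LabelDerivationError(
            f"epoch {bp_epoch.epoch_index} of subject {bp_epoch.subject_id} "
            f"(start sample {bp_epoch.start_index}, {bp_epoch.duration_s} s) "
            "has no usable pressure extrema"
        )
    return EpochLabel(
        sbp_mmHg=float(np.mean(bp_epoch.samples[maxima])),
        dbp_mmHg=float(np.mean(bp_epoch.samples[minima])),
        n_maxima=int(maxima.size),
        n_minima=int(minima.size),
    )


def read_signal_csv(
    path: str | Path,
    sampling_rate_hz: float | None = None,
    subject_id: str = "S0",
    modality: str = "ECG",
) -> SignalRecord:
    """Read a two-column ``time_s,value`` CSV (or a single-column value file).

    When the file has a time column the sampling rate is inferred from the
    median time step unless ``sampling_rate_hz`` is given explicitly.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row:
                continue
            try:
                float(row[0])
            except ValueError:
                continue  # header
            rows.append(row)
    if not rows:
        raise ValueError(f"{path} contains no numeric rows")
    arr = np.asarray([[float(v) for v in row] for row in rows])
    if arr.shape[1] >= 2:
        times, values = arr[:, 0], arr[:, 1]
        if sampling_rate_hz is None:
            step = float(np.median(np.diff(times)))
            if step <= 0:
                raise ValueError("time column is not increasing")
            sampling_rate_hz = 1.0 / step
    else:
        values = arr[:, 0]
        if sampling_rate_hz is None:
            raise ValueError("single-column input requires sampling_rate_hz")
    return SignalRecord(
        samples=values,
        sampling_rate_hz=sampling_rate_hz,
        subject_id=subject_id,
        modality=modality,
    )


def write_signal_csv(record: SignalRecord, path: str | Path) -> None:
    """Write a record as a two-column ``time_s,value`` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(record.times_s, record.samples):
            writer.writerow([f"{t:.6f}", f"{v:.8g}"])
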