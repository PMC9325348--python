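"""Time-domain statistical features of an ECG epoch.

Twenty-five descriptive statistics are computed on the raw (unfiltered)
samples of each epoch.  The set mixes ordinary moments (mean, standard
deviation, skewness, kurtosis, a 10th central moment), robust summaries
(median, IQR, trimmed means, mean absolute deviation), energy measures
(average energy, RMS, curve length, Teager energy), the three Hjorth
parameters, and shape descriptors (coefficient of variation, shape factor,
Euclidean norm).

Conventions
-----------
* ``std`` uses the sample convention (divisor ``n - 1``); ``hjorth_activity``
  is its square.
* ``kurtosis`` and ``skewness`` use divisor ``(n - 1) * S**k`` with the
  sample standard deviation ``S`` — note this is *not* excess kurtosis.
* Hjorth mobility is ``sqrt(var(dx) / var(x))`` with ``dx`` the first
  difference; complexity is ``mobility(dx) / mobility(x)``.
* Geometric and harmonic means are computed on ``|x| + 1e-12`` because a
  zero-mean ECG contains negative samples on which both are undefined.
* Trimmed means trim symmetrically: ``trimmed_mean_25`` removes 12.5 % of
  the points per tail, ``trimmed_mean_50`` removes 25 % per tail, with the
  per-tail count rounded half-up.
* Ratio statistics (``cv``, ``skewness``, ``kurtosis``, ``shape_factor``,
  ``hjorth_mobility``, ``hjorth_complexity``) return 0 when their
  denominator vanishes (constant input), so feature matrices stay finite.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .epoching import Epoch

#: the frozen feature order; downstream ranking tie-breaks use this index
FEATURE_NAMES: tuple[str, ...] = (
    "kurtosis",
    "skewness",
    "iqr",
    "cv",
    "geometric_mean",
    "harmonic_mean",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "maximum",
    "median",
    "mean_abs_deviation",
    "minimum",
    "central_moment_10",
    "mean",
    "curve_length",
    "avg_energy",
    "rms",
    "standard_error",
    "std",
    "shape_factor",
    "svd_norm",
    "trimmed_mean_25",
    "trimmed_mean_50",
    "teager_energy",
)

N_FEATURES = len(FEATURE_NAMES)

_EPS = 1e-12  # offset shielding geometric/harmonic means from zeros

#: metadata columns of a feature table, before the 25 feature columns
TABLE_META_COLUMNS = ("subject_id", "duration_s", "epoch_index", "sbp", "dbp")


def _as_array(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise ValueError("feature input must be a 1-D sequence of length >= 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("feature input must be finite")
    return arr


def _sample_std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def _kurtosis(x: np.ndarray) -> float:
    s = _sample_std(x)
    n = x.size
    return _safe_ratio(float(np.sum((x - x.mean()) ** 4)), (n - 1) * s**4)


def _skewness(x: np.ndarray) -> float:
    s = _sample_std(x)
    n = x.size
    return _safe_ratio(float(np.sum((x - x.mean()) ** 3)), (n - 1) * s**3)


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def _cv(x: np.ndarray) -> float:
    return _safe_ratio(_sample_std(x), float(x.mean())) * 100.0


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(np.abs(x) + _EPS))))


def _harmonic_mean(x: np.ndarray) -> float:
    return float(x.size / np.sum(1.0 / (np.abs(x) + _EPS)))


def _mobility_of(x: np.ndarray) -> float:
    num = float(np.var(np.diff(x), ddof=1)) if x.size >= 3 else 0.0
    den = float(np.var(x, ddof=1))
    return math.sqrt(_safe_ratio(num, den)) if den != 0 else 0.0


def _hjorth_mobility(x: np.ndarray) -> float:
    return _mobility_of(x)


def _hjorth_complexity(x: np.ndarray) -> float:
    m = _mobility_of(x)
    return _safe_ratio(_mobility_of(np.diff(x)), m)


def _median(x: np.ndarray) -> float:
    return float(np.median(x))


def _mad(x: np.ndarray) -> float:
    return float(np.mean(np.abs(x - x.mean())))


def _central_moment_10(x: np.ndarray) -> float:
    return float(np.mean((x - x.mean()) ** 10))


def _curve_length(x: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(x)))) / x.size


def _avg_energy(x: np.ndarray) -> float:
    return float(np.mean(x**2))


def _rms(x: np.ndarray) -> float:
    return math.sqrt(_avg_energy(x))


def _standard_error(x: np.ndarray) -> float:
    return _sample_std(x) / math.sqrt(x.size)


def _shape_factor(x: np.ndarray) -> float:
    return _safe_ratio(_rms(x), float(np.mean(np.abs(x))))


def _svd_norm(x: np.ndarray) -> float:
    # the sole singular value of a 1 x n matrix is its Euclidean norm
    return float(np.linalg.norm(x))


def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def _trimmed_mean(x: np.ndarray, total_percent: float) -> float:
    k = _round_half_up(x.size * total_percent / 200.0)
    k = min(k, (x.size - 1) // 2)
    s = np.sort(x)
    return float(np.mean(s[k : x.size - k]))


def _teager_energy(x: np.ndarray) -> float:
    # mean of x[i-1]^2 - x[i]*x[i-2] over the interior, normalized by n
    return float(np.sum(x[1:-1] ** 2 - x[2:] * x[:-2])) / x.size


_FEATURE_FUNCS: dict[str, Callable[[np.ndarray], float]] = {
    "kurtosis": _kurtosis,
    "skewness": _skewness,
    "iqr": _iqr,
    "cv": _cv,
    "geometric_mean": _geometric_mean,
    "harmonic_mean": _harmonic_mean,
    "hjorth_activity": lambda x: float(np.var(x, ddof=1)),
    "hjorth_mobility": _hjorth_mobility,
    "hjorth_complexity": _hjorth_complexity,
    "maximum": lambda x: float(np.max(x)),
    "median": _median,
    "mean_abs_deviation": _mad,
    "minimum": lambda x: float(np.min(x)),
    "central_moment_10": _central_moment_10,
    "mean": lambda x: float(np.mean(x)),
    "curve_length": _curve_length,
    "avg_energy": _avg_energy,
    "rms": _rms,
    "standard_error": _standard_error,
    "std": _sample_std,
    "shape_factor": _shape_factor,
    "svd_norm": _svd_norm,
    "trimmed_mean_25": lambda x: _trimmed_mean(x, 25.0),
    "trimmed_mean_50": lambda x: _trimmed_mean(x, 50.0),
    "teager_energy": _teager_energy,
}

assert set(_FEATURE_FUNCS) == set(FEATURE_NAMES)


def compute_feature(name: str, x: Sequence[float]) -> float:
    """Compute a single named feature of a sequence.

    Raises ``KeyError`` for an unknown feature name and ``ValueError`` for
    inputs shorter than 3 samples or containing non-finite values.
    """
    func = _FEATURE_FUNCS[name]
    return func(_as_array(x))


def extract_features(epoch: Epoch | Sequence[float]) -> dict[str, float]:
    """Compute all 25 features of an ECG epoch, in the frozen order."""
    samples = epoch.samples if isinstance(epoch, Epoch) else epoch
    x = _as_array(samples)
    return {name: _FEATURE_FUNCS[name](x) for name in FEATURE_NAMES}


def feature_table(
    rows: Iterable[tuple[Epoch, float, float]],
) -> pd.DataFrame:
    """Build a feature table from ``(ecg_epoch, sbp, dbp)`` triples.

    Columns are the metadata (subject, duration, epoch index, labels)
    followed by the 25 features in their frozen order.
    """
    records = []
    for epoch, sbp, dbp in rows:
        rec = {
            "subject_id": epoch.subject_id,
            "duration_s": epoch.duration_s,
            "epoch_index": epoch.epoch_index,
            "sbp": sbp,
            "dbp": dbp,
        }
        rec.update(extract_features(epoch))
        records.append(rec)
    return pd.DataFrame(records, columns=list(TABLE_META_COLUMNS) + list(FEATURE_NAMES))


def per_subject_layout(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a pooled feature table into the wide per-subject layout.

    Each subject contributes its own copy of the 25 feature columns, named
    ``<subject_id>:<feature>`` — a 5-subject cohort yields 125 feature
    columns.  Rows are aligned on the epoch index; subjects with fewer
    epochs leave missing values.
    """
    wide = table.pivot_table(
        index="epoch_index",
        columns="subject_id",
        values=list(FEATURE_NAMES),
        aggfunc="first",
    )
    wide.columns = [f"{sid}:{feat}" for feat, sid in wide.columns]
    # deterministic ordering: subject-major, feature order within subject
    subjects = sorted(table["subject_id"].unique())
    ordered = [f"{sid}:{feat}" for sid in subjects for feat in FEATURE_NAMES]
    return wide[ordered]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in list(TABLE_META_COLUMNS) + list(FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return table
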