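"""Performance measures for pressure prediction, plus Bland–Altman agreement.

Seven quantities are reported per model, with ``e_i = t_i - y_i`` the
per-sample error of prediction ``y`` against truth ``t``:

* MAPE — mean of ``|e_i / t_i|``, times 100 (a percentage);
* MAD  — mean absolute deviation ``mean(|e_i|)``, in mmHg;
* SE   — standard error of the estimate ``sqrt(sum(e_i^2) / (n - 2))``;
* MSE  — ``mean(e_i^2)``;
* RMSE — ``sqrt(MSE)``;
* R    — Pearson correlation of ``t`` and ``y``;
* R²   — the square of R (not the coefficient of determination).

Bland–Altman agreement reports the mean difference and the mean ± 1.96·SD
limits of agreement of the differences ``d_i = t_i - y_i`` (sample SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PerformanceRow:
    mape: float
    mad: float
    se: float
    mse: float
    rmse: float
    r: float
    r2: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "MAPE": self.mape,
            "MAD": self.mad,
            "SE": self.se,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "R": self.r,
            "R2": self.r2,
            "n": self.n,
        }


@dataclass
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float


def _check_pair(t, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("true and predicted vectors differ in length")
    if t.size < min_n:
        raise ValueError(f"at least {min_n} pairs are required")
    return t, y


def compute_metrics(t, y) -> PerformanceRow:
    """The seven-metric performance row of predictions ``y`` against ``t``."""
    t, y = _check_pair(t, y)
    if np.any(t == 0):
        raise ValueError("MAPE is undefined when a true value is 0")
    e = t - y
    mape = float(np.mean(np.abs(e / t))) * 100.0
    mad = float(np.mean(np.abs(e)))
    # the n - 2 divisor leaves SE undefined for exactly two pairs
    se = float(np.sqrt(np.sum(e**2) / (t.size - 2))) if t.size > 2 else float("inf")
    mse = float(np.mean(e**2))
    rmse = float(np.sqrt(mse))
    if np.std(t) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in inputs: correlation set to 0")
        r = 0.0
    else:
        r = float(np.corrcoef(t, y)[0, 1])
    return PerformanceRow(
        mape=mape, mad=mad, se=se, mse=mse, rmse=rmse, r=r, r2=r * r, n=int(t.size)
    )


def bland_altman(t, y) -> BlandAltman:
    """Mean difference and 95 % limits of agreement of ``t - y``."""
    t, y = _check_pair(t, y, min_n=3)
    d = t - y
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        mean_difference=mean_d,
        loa_low=mean_d - 1.96 * sd,
        loa_high=mean_d + 1.96 * sd,
    )
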