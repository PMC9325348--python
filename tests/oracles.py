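"""Independent literal-formula reimplementations of the 25 features.

Coded with explicit Python loops, separately from the production path in
``ecgbp.features``, so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math


def mean(x):
    return sum(x) / len(x)


def sample_std(x):
    m = mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def kurtosis(x):
    s = sample_std(x)
    if s == 0:
        return 0.0
    m = mean(x)
    return sum((v - m) ** 4 for v in x) / ((len(x) - 1) * s**4)


def skewness(x):
    s = sample_std(x)
    if s == 0:
        return 0.0
    m = mean(x)
    return sum((v - m) ** 3 for v in x) / ((len(x) - 1) * s**3)


def _quantile(sorted_x, q):
    # linear interpolation between order statistics (the default convention)
    n = len(sorted_x)
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac


def iqr(x):
    s = sorted(x)
    return _quantile(s, 0.75) - _quantile(s, 0.25)


def cv(x):
    m = mean(x)
    return sample_std(x) / m * 100.0 if m != 0 else 0.0


def geometric_mean(x):
    logs = [math.log(abs(v) + 1e-12) for v in x]
    return math.exp(mean(logs))


def harmonic_mean(x):
    return len(x) / sum(1.0 / (abs(v) + 1e-12) for v in x)


def variance(x):
    m = mean(x)
    return sum((v - m) ** 2 for v in x) / (len(x) - 1)


def first_diff(x):
    return [x[i] - x[i - 1] for i in range(1, len(x))]


def hjorth_activity(x):
    return variance(x)


def hjorth_mobility(x):
    den = variance(x)
    if den == 0:
        return 0.0
    return math.sqrt(variance(first_diff(x)) / den)


def hjorth_complexity(x):
    m = hjorth_mobility(x)
    return hjorth_mobility(first_diff(x)) / m if m != 0 else 0.0


def maximum(x):
    return max(x)


def median(x):
    s = sorted(x)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def mean_abs_deviation(x):
    m = mean(x)
    return mean([abs(v - m) for v in x])


def minimum(x):
    return min(x)


def central_moment_10(x):
    m = mean(x)
    return mean([(v - m) ** 10 for v in x])


def curve_length(x):
    return sum(abs(x[i] - x[i - 1]) for i in range(1, len(x))) / len(x)


def avg_energy(x):
    return mean([v * v for v in x])


def rms(x):
    return math.sqrt(avg_energy(x))


def standard_error(x):
    return sample_std(x) / math.sqrt(len(x))


def shape_factor(x):
    den = mean([abs(v) for v in x])
    return rms(x) / den if den != 0 else 0.0


def svd_norm(x):
    return math.sqrt(sum(v * v for v in x))


def _trimmed(x, total_percent):
    n = len(x)
    k = int(math.floor(n * total_percent / 200.0 + 0.5))
    k = min(k, (n - 1) // 2)
    s = sorted(x)[k : n - k]
    return mean(s)


def trimmed_mean_25(x):
    return _trimmed(x, 25.0)


def trimmed_mean_50(x):
    return _trimmed(x, 50.0)


def teager_energy(x):
    # 1-based: (1/n) * sum_{i=3..n} x_{i-1}^2 - x_i * x_{i-2}
    n = len(x)
    total = 0.0
    for i in range(2, n):  # 0-based i corresponds to 1-based i+1
        total += x[i - 1] ** 2 - x[i] * x[i - 2]
    return total / n


FEATURE_ORACLES = {
    "kurtosis": kurtosis,
    "skewness": skewness,
    "iqr": iqr,
    "cv": cv,
    "geometric_mean": geometric_mean,
    "harmonic_mean": harmonic_mean,
    "hjorth_activity": hjorth_activity,
    "hjorth_mobility": hjorth_mobility,
    "hjorth_complexity": hjorth_complexity,
    "maximum": maximum,
    "median": median,
    "mean_abs_deviation": mean_abs_deviation,
    "minimum": minimum,
    "central_moment_10": central_moment_10,
    "mean": mean,
    "curve_length": curve_length,
    "avg_energy": avg_energy,
    "rms": rms,
    "standard_error": standard_error,
    "std": sample_std,
    "shape_factor": shape_factor,
    "svd_norm": svd_norm,
    "trimmed_mean_25": trimmed_mean_25,
    "trimmed_mean_50": trimmed_mean_50,
    "teager_energy": teager_energy,
}
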