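"""Spearman-correlation feature ranking and percentage-based subset levels.

Features are ranked by the magnitude of their Spearman rank correlation with
the target pressure (SBP or DBP).  Subsets are then formed at 11 "levels":
the top 5 %, 10 %, ..., 50 % and finally 100 % of the 25 features, with the
count rounded half-up — for 25 features the ladder of subset sizes is
1, 3, 4, 5, 6, 8, 9, 10, 11, 13, 25.  Levels are nested: each level's subset
is a prefix of the next.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FEATURE_NAMES

#: the 11 level percentages
LEVEL_PERCENTS: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 100)


@dataclass(frozen=True)
class LevelSpec:
    level: int
    percent: int
    count: int


@dataclass
class RankedFeatures:
    """Feature names ordered by descending |r_s| with the target."""

    names: list[str]
    r_s: np.ndarray
    target: str

    def __post_init__(self) -> None:
        self.r_s = np.asarray(self.r_s, dtype=float)
        if len(self.names) != self.r_s.size:
            raise ValueError("names and correlations differ in length")
        if np.any(np.diff(np.abs(self.r_s)) > 1e-12):
            raise ValueError("|r_s| must be non-increasing along the ranking")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "features": self.names,
            "r_s": [float(v) for v in self.r_s],
        }


def round_half_up(v: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.floor(v + 0.5))


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive their average rank.  Returns 0 (with a warning) when either
    argument has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must share a length of at least 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("zero rank variance: Spearman correlation set to 0")
        return 0.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    return max(-1.0, min(1.0, r))


def rank_features(
    table: pd.DataFrame, labels, target: str = "SBP"
) -> RankedFeatures:
    """Rank the 25 features by |r_s| with the target labels.

    Ties (including constant columns, which score 0) break by the frozen
    feature order: the lower feature index ranks first.
    """
    labels = np.asarray(labels, dtype=float)
    if table[list(FEATURE_NAMES)].isna().any().any() or np.any(np.isnan(labels)):
        raise ValueError("feature table and labels must have no missing values")
    corrs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in FEATURE_NAMES:
            corrs[name] = spearman(table[name].to_numpy(), labels)
    order = sorted(
        FEATURE_NAMES, key=lambda n: (-abs(corrs[n]), FEATURE_NAMES.index(n))
    )
    return RankedFeatures(
        names=order,
        r_s=np.array([corrs[n] for n in order]),
        target=target,
    )


def level_sizes(total: int = 25) -> list[LevelSpec]:
    """The 11 subset levels for ``total`` ranked features."""
    if total < 1:
        raise ValueError("total must be at least 1")
    return [
        LevelSpec(level=i + 1, percent=p, count=min(total, max(1, round_half_up(p * total / 100.0))))
        for i, p in enumerate(LEVEL_PERCENTS)
    ]


def select_level(ranked: RankedFeatures, level: LevelSpec) -> list[str]:
    """The top ``level.count`` feature names of the ranking."""
    if level.count > len(ranked.names):
        raise ValueError("level count exceeds the number of ranked features")
    return ranked.names[: level.count]
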