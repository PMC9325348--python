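"""Grid orchestration: epoch durations × feature levels × models × targets.

For every epoch duration the pipeline segments each subject's paired ECG/BP
records, derives SBP/DBP labels from the pressure extrema, extracts the 25
ECG features, pools epochs across subjects, splits 80/20, ranks features by
Spearman correlation **on the training split only**, and evaluates the 11
feature levels × 3 models on the held-out split — 33 performance rows per
target per duration.

The minimum measurement time is then the smallest duration whose best model
simultaneously (for both SBP and DBP) attains the maximum correlation R over
durations and a MAPE within ``delta_mape`` of the minimum over durations.
If no duration satisfies both targets jointly, the rule relaxes to the
duration minimizing the summed MAPE ranks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .epoching import (
    EPOCH_DURATIONS_S,
    Epoch,
    LabelDerivationError,
    SignalRecord,
    derive_labels,
    segment,
)
from .features import FEATURE_NAMES, feature_table
from .metrics import PerformanceRow, bland_altman, compute_metrics
from .regression import ALGORITHMS, ModelSpec, predict, train
from .selection import LevelSpec, RankedFeatures, level_sizes, rank_features, round_half_up, select_level

logger = logging.getLogger(__name__)

TARGETS = ("SBP", "DBP")

#: preference order used to break remaining ties for the best model
_MODEL_PREFERENCE = {"GPR": 0, "EBT": 1, "FT": 2}

GRID_COLUMNS = (
    "target", "duration_s", "level", "fn", "fp", "algorithm",
    "MAPE", "MAD", "SE", "MSE", "RMSE", "R", "R2", "n",
)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 80 % train by default, random over pooled epochs."""

    train_fraction: float = 0.8
    seed: int = 0
    method: str = "random"  # or "sequential"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.method not in ("random", "sequential"):
            raise ValueError("method must be 'random' or 'sequential'")


def split(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition of ``range(n)``.

    The train count is ``round_half_up(train_fraction * n)``; e.g. 4832
    epochs at 0.8 give 3866 train and 966 test.
    """
    if n < 5:
        raise ValueError("at least 5 rows are required to split")
    n_train = round_half_up(spec.train_fraction * n)
    if spec.method == "sequential":
        idx = np.arange(n)
    else:
        idx = np.random.default_rng(spec.seed).permutation(n)
    return np.sort(idx[:n_train]), np.sort(idx[n_train:])


@dataclass
class GridConfig:
    """Everything that fixes a grid run, so runs are reproducible."""

    durations_s: Sequence[float] = EPOCH_DURATIONS_S
    split: SplitSpec = field(default_factory=SplitSpec)
    seed: int = 0
    delta_mape: float = 0.1
    min_epochs: int = 50
    subject_holdout: str | None = None  # subject id held out for testing
    hyperparameters: dict[str, dict[str, Any]] = field(default_factory=dict)

    def model_spec(self, algorithm: str) -> ModelSpec:
        return ModelSpec(
            algorithm=algorithm,
            seed=self.seed,
            hyperparameters=self.hyperparameters.get(algorithm, {}),
        )


@dataclass
class GridResult:
    """All performance rows plus the retained best-cell predictions."""

    table: pd.DataFrame
    rankings: dict[tuple[str, float], RankedFeatures] = field(default_factory=dict)
    best_predictions: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    config: GridConfig | None = None

    def best_per_duration(self, target: str) -> pd.DataFrame:
        """One row per duration: lowest MAPE, ties to higher R, then model
        preference GPR > EBT > FT."""
        sub = self.table[self.table["target"] == target].copy()
        sub["_pref"] = sub["algorithm"].map(_MODEL_PREFERENCE)
        sub = sub.sort_values(["duration_s", "MAPE", "R", "_pref"],
                              ascending=[True, True, False, True],
                              kind="mergesort")
        best = sub.groupby("duration_s", as_index=False).first()
        return best.drop(columns="_pref")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.table.to_dict(orient="records"),
            "rankings": {
                f"{t}:{d}": r.to_dict() for (t, d), r in self.rankings.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GridResult":
        payload = json.loads(Path(path).read_text())
        table = pd.DataFrame(payload["rows"], columns=list(GRID_COLUMNS))
        rankings = {}
        for key, r in payload.get("rankings", {}).items():
            target, dur = key.rsplit(":", 1)
            rankings[(target, float(dur))] = RankedFeatures(
                names=r["features"], r_s=np.array(r["r_s"]), target=r["target"]
            )
        return cls(table=table, rankings=rankings)


def build_feature_table(
    cohort: Iterable[tuple[SignalRecord, SignalRecord, Any]],
    duration_s: float,
) -> pd.DataFrame:
    """Epoch, label and featurize one duration across a cohort.

    ECG and BP are segmented identically; an epoch pair is kept only when
    the pressure window yields usable extrema, so features and labels stay
    paired.
    """
    rows: list[tuple[Epoch, float, float]] = []
    for item in cohort:
        ecg, bp = item[0], item[1]
        ecg_epochs = segment(ecg, duration_s)
        bp_epochs = segment(bp, duration_s)
        for e_ep, b_ep in zip(ecg_epochs, bp_epochs):
            try:
                label = derive_labels(b_ep)
            except LabelDerivationError:
                continue
            rows.append((e_ep, label.sbp_mmHg, label.dbp_mmHg))
    return feature_table(rows)


def _split_for(table: pd.DataFrame, config: GridConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.subject_holdout is not None:
        mask = (table["subject_id"] == config.subject_holdout).to_numpy()
        if mask.all() or not mask.any():
            raise ValueError(
                f"subject_holdout {config.subject_holdout!r} must match a proper "
                "subset of the cohort"
            )
        return np.flatnonzero(~mask), np.flatnonzero(mask)
    return split(len(table), config.split)


def evaluate_duration(
    table: pd.DataFrame, config: GridConfig, duration_s: float
) -> tuple[list[dict], dict, dict]:
    """Evaluate the 33 (level × model) cells for both targets at one duration."""
    train_idx, test_idx = _split_for(table, config)
    levels = level_sizes(len(FEATURE_NAMES))
    rows: list[dict] = []
    rankings: dict = {}
    best_preds: dict = {}
    for target in TARGETS:
        label_col = target.lower()
        y = table[label_col].to_numpy(dtype=float)
        ranked = rank_features(table.iloc[train_idx], y[train_idx], target=target)
        rankings[(target, duration_s)] = ranked
        cell_preds: dict[tuple[int, str], np.ndarray] = {}
        for level in levels:
            names = select_level(ranked, level)
            X_train = table.iloc[train_idx][names]
            X_test = table.iloc[test_idx][names]
            for algorithm in ALGORITHMS:
                model = train(config.model_spec(algorithm), X_train, y[train_idx])
                y_hat = predict(model, X_test)
                perf = compute_metrics(y[test_idx], y_hat)
                cell_preds[(level.level, algorithm)] = y_hat
                rows.append({
                    "target": target, "duration_s": duration_s,
                    "level": level.level, "fn": level.count, "fp": level.percent,
                    "algorithm": algorithm, **perf.as_dict(),
                })
        # retain predictions of this duration's best cell for agreement plots
        dur_rows = [r for r in rows if r["target"] == target and r["duration_s"] == duration_s]
        best = min(dur_rows, key=lambda r: (r["MAPE"], -r["R"], _MODEL_PREFERENCE[r["algorithm"]]))
        best_preds[(target, duration_s)] = (
            y[test_idx], cell_preds[(best["level"], best["algorithm"])]
        )
    return rows, rankings, best_preds


def run_grid(
    cohort: Sequence[tuple[SignalRecord, SignalRecord, Any]],
    config: GridConfig | None = None,
) -> GridResult:
    """Run the full (duration × level × model × target) grid on a cohort.

    Durations pooling fewer than ``config.min_epochs`` usable epochs are
    skipped with a logged warning.  Deterministic given the config.
    """
    config = config or GridConfig()
    all_rows: list[dict] = []
    rankings: dict = {}
    best_preds: dict = {}
    for duration_s in config.durations_s:
        table = build_feature_table(cohort, duration_s)
        if len(table) < config.min_epochs:
            logger.warning(
                "duration %s s pooled only %d usable epochs (< %d); skipped",
                duration_s, len(table), config.min_epochs,
            )
            continue
        rows, ranks, preds = evaluate_duration(table, config, duration_s)
        all_rows.extend(rows)
        rankings.update(ranks)
        best_preds.update(preds)
    table = pd.DataFrame(all_rows, columns=list(GRID_COLUMNS))
    return GridResult(table=table, rankings=rankings,
                      best_predictions=best_preds, config=config)


def select_min_time(grid: GridResult, delta_mape: float = 0.1) -> float:
    """The smallest epoch duration preserving peak performance.

    A duration qualifies for one target when its best-model row attains the
    maximum R over durations and a MAPE within ``delta_mape`` of the minimum
    over durations.  The selected duration is the smallest one qualifying
    for **both** SBP and DBP; if none does, the duration with the lowest
    summed MAPE rank across targets is returned.
    """
    if grid.table.empty:
        raise ValueError("empty grid")
    qualifying: list[set] = []
    mape_ranks: dict[float, float] = {}
    for target in TARGETS:
        best = grid.best_per_duration(target)
        if best.empty:
            raise ValueError(f"no best rows for target {target}")
        r_max = best["R"].max()
        mape_min = best["MAPE"].min()
        ok = best[(best["R"] >= r_max - 1e-9) & (best["MAPE"] <= mape_min + delta_mape + 1e-9)]
        qualifying.append(set(ok["duration_s"]))
        for dur, rank in zip(best["duration_s"], best["MAPE"].rank(method="average")):
            mape_ranks[dur] = mape_ranks.get(dur, 0.0) + rank
    joint = set.intersection(*qualifying)
    if joint:
        return float(min(joint))
    return float(min(mape_ranks, key=lambda d: (mape_ranks[d], d)))


def report(grid: GridResult, out_dir: str | Path) -> list[Path]:
    """Write per-duration tables, the best-model summary, Bland–Altman data
    and a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out_dir / "grid.csv"
    grid.table.to_csv(path, index=False)
    written.append(path)

    for target in TARGETS:
        for duration_s in sorted(grid.table["duration_s"].unique()):
            sub = grid.table[
                (grid.table["target"] == target)
                & (grid.table["duration_s"] == duration_s)
            ]
            sub = sub.rename(columns={"level": "L", "fn": "FN", "fp": "FP",
                                      "algorithm": "Model"})
            path = out_dir / f"table_{target}_{duration_s:g}s.csv"
            sub[["L", "FN", "FP", "Model", "MAPE", "MAD", "SE", "MSE",
                 "RMSE", "R", "R2"]].to_csv(path, index=False)
            written.append(path)

    summary = pd.concat(
        [grid.best_per_duration(t).assign(target=t) for t in TARGETS],
        ignore_index=True,
    )
    path = out_dir / "summary_best_models.csv"
    summary.to_csv(path, index=False)
    written.append(path)

    ba_rows = []
    for (target, duration_s), (t, y) in sorted(grid.best_predictions.items()):
        ba = bland_altman(t, y)
        ba_rows.append({
            "target": target, "duration_s": duration_s,
            "mean_difference": ba.mean_difference,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": len(t),
        })
    if ba_rows:
        path = out_dir / "bland_altman.csv"
        pd.DataFrame(ba_rows).to_csv(path, index=False)
        written.append(path)

    manifest = {
        "package_version": __version__,
        "config": _config_dict(grid.config),
        "n_rows": int(len(grid.table)),
        "selected_min_duration_s": select_min_time(
            grid, grid.config.delta_mape if grid.config else 0.1
        ) if not grid.table.empty else None,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    written.append(path)
    return written


def _config_dict(config: GridConfig | None) -> dict | None:
    if config is None:
        return None
    d = dataclasses.asdict(config)
    d["durations_s"] = [float(v) for v in d["durations_s"]]
    return d
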