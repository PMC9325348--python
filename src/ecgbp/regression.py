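"""The three regressors: fine tree, ensemble bagged trees, exponential-kernel
Gaussian process.

* **FT** (fine tree): a single deep regression tree with a small minimum leaf
  size (4), the "fine" preset of tree toolboxes.
* **EBT** (ensemble bagged trees): 30 bootstrap-aggregated regression trees
  with minimum leaf size 8; the ensemble prediction is exactly the mean of
  the member predictions.
* **GPR**: Gaussian process regression with an exponential
  (Ornstein–Uhlenbeck) covariance, i.e. a Matérn kernel with ``nu = 1/2``,
  plus a fitted white-noise term.  Length-scale, signal variance and noise
  variance are fitted by marginal-likelihood maximization with 3 optimizer
  restarts.  Inputs are standardized to zero mean / unit variance with
  training statistics; targets are centred internally by the fitter.

Exact Gaussian-process fitting costs O(n^3); above ``gpr_max_train`` rows
(default 1000) the GPR is fitted on a deterministic random subset of the
training data, the classic subset-of-data approximation.  Tree models always
use the full training set.

No hyperparameter search is performed: each model is a single fit with the
frozen defaults, reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.tree import DecisionTreeRegressor

ALGORITHMS = ("FT", "EBT", "GPR")

_DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "FT": {"min_samples_leaf": 4},
    "EBT": {"n_estimators": 30, "min_samples_leaf": 8},
    "GPR": {"n_restarts_optimizer": 3, "gpr_max_train": 1000, "noise_level": None},
}


@dataclass(frozen=True)
class ModelSpec:
    """Which algorithm to fit, with optional hyperparameter overrides."""

    algorithm: str
    seed: int = 0
    hyperparameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    def resolved(self) -> dict[str, Any]:
        params = dict(_DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparameters)
        return params


@dataclass
class TrainedModel:
    """A fitted predictor with the metadata needed to apply it safely."""

    spec: ModelSpec
    estimator: Any
    feature_names: list[str]
    x_mean: np.ndarray | None = None  # standardization stats (GPR only)
    x_std: np.ndarray | None = None

    def _matrix(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"prediction input is missing feature columns: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
                )
        if self.x_mean is not None:
            X = (X - self.x_mean) / self.x_std
        return X


def _as_matrix(X: pd.DataFrame | np.ndarray, feature_names: list[str] | None):
    if isinstance(X, pd.DataFrame):
        names = feature_names if feature_names is not None else list(X.columns)
        return X[names].to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    else:
        names = list(feature_names)
    return X, names


def train(
    spec: ModelSpec,
    X: pd.DataFrame | np.ndarray,
    y,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit the specified model; deterministic given the spec's seed."""
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if Xm.shape[0] < 10:
        raise ValueError("at least 10 training rows are required")
    if np.any(~np.isfinite(Xm)) or np.any(~np.isfinite(y)):
        raise ValueError("training data must be finite with no missing values")
    params = spec.resolved()

    if spec.algorithm == "FT":
        est = DecisionTreeRegressor(
            min_samples_leaf=params["min_samples_leaf"], random_state=spec.seed
        )
        est.fit(Xm, y)
        return TrainedModel(spec=spec, estimator=est, feature_names=names)

    if spec.algorithm == "EBT":
        est = BaggingRegressor(
            estimator=DecisionTreeRegressor(
                min_samples_leaf=params["min_samples_leaf"]
            ),
            n_estimators=params["n_estimators"],
            random_state=spec.seed,
        )
        est.fit(Xm, y)
        return TrainedModel(spec=spec, estimator=est, feature_names=names)

    # GPR: standardize inputs, optionally subset the training data
    max_train = params["gpr_max_train"]
    if max_train is not None and Xm.shape[0] > max_train:
        rng = np.random.default_rng(spec.seed)
        keep = rng.choice(Xm.shape[0], size=max_train, replace=False)
        Xm_fit, y_fit = Xm[keep], y[keep]
    else:
        Xm_fit, y_fit = Xm, y
    x_mean = Xm_fit.mean(axis=0)
    x_std = Xm_fit.std(axis=0)
    x_std[x_std == 0] = 1.0
    Xs = (Xm_fit - x_mean) / x_std

    noise = params["noise_level"]
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=1.0, length_scale_bounds=(1e-2, 1e3), nu=0.5
    )
    if noise is None:
        kernel = kernel + WhiteKernel(1e-2, (1e-10, 1e1))
        alpha = 1e-10
    else:
        alpha = float(noise)  # fixed noise variance, no white-noise fitting
    est = GaussianProcessRegressor(
        kernel=kernel,
        alpha=alpha,
        normalize_y=True,
        n_restarts_optimizer=params["n_restarts_optimizer"],
        random_state=spec.seed,
    )
    est.fit(Xs, y_fit)
    return TrainedModel(
        spec=spec, estimator=est, feature_names=names, x_mean=x_mean, x_std=x_std
    )


def predict(model: TrainedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Apply a trained model; one finite prediction per row."""
    Xm = model._matrix(X)
    out = np.asarray(model.estimator.predict(Xm), dtype=float)
    if np.any(~np.isfinite(out)):
        raise FloatingPointError("model produced non-finite predictions")
    return out
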