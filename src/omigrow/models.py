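"""Regressor families, benchmark metrics and fitting.

Three model families map a standardized conditions x features matrix to
per-condition growth rates, with hyperparameters fixed to the published
configuration this package reimplements:

* ANN — multilayer perceptron, 12 hidden layers of 200 neurons,
  1000 iterations, seed 42 (ReLU activation, Adam optimizer — the
  conventional defaults, since only depth/width/iterations/seed are
  prescribed).
* RF — random forest with 1000 trees.
* SVR — RBF kernel, C=100, epsilon=0.01.

Evaluation is in-sample by default (the models are deliberately trained
on the complete dataset so that every feature's contribution can be
interrogated afterwards); an optional leave-one-out mode gives an
honest generalization estimate and is clearly a departure from that
protocol.

Accuracy is defined as ``100 * (1 - mean(|yhat - y| / y))`` — the
mean relative absolute error subtracted from one, as a percentage. It
is 100 at a perfect fit, scale-free, and requires strictly positive
targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR as _SKSVR

from .errors import InputError, MetricDomainError
from .preprocess import OmicsMatrix

logger = logging.getLogger(__name__)

FAMILIES = ("ANN", "RF", "SVR")


@dataclass(frozen=True)
class RegressorConfig:
    """Model family plus hyperparameters (defaults are the published ones)."""

    family: str
    hidden_layers: int = 12
    neurons_per_layer: int = 200
    max_iterations: int = 1000
    seed: int = 42
    n_estimators: int = 1000
    kernel: str = "rbf"
    C: float = 100.0
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InputError(f"family must be one of {FAMILIES}, got {self.family!r}")
        for name in ("hidden_layers", "neurons_per_layer", "max_iterations", "n_estimators"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be a positive integer")
        if self.C <= 0 or self.epsilon <= 0:
            raise InputError("C and epsilon must be positive")

    @classmethod
    def ann(cls, seed: int = 42, **kw) -> "RegressorConfig":
        return cls("ANN", seed=seed, **kw)

    @classmethod
    def rf(cls, seed: int = 42, **kw) -> "RegressorConfig":
        return cls("RF", seed=seed, **kw)

    @classmethod
    def svr(cls, **kw) -> "RegressorConfig":
        return cls("SVR", **kw)


def default_configs() -> list[RegressorConfig]:
    """The three benchmark configurations."""
    return [RegressorConfig.ann(), RegressorConfig.rf(), RegressorConfig.svr()]


@dataclass(frozen=True)
class FitMetrics:
    """MAE (rate units), MSE (rate units squared), accuracy (%)."""

    mae: float
    mse: float
    accuracy_pct: float | None = None


class LinearPredictor:
    """Deterministic linear model ``yhat = X @ coef + intercept``.

    A fixed, training-free predictor used as a transparent reference
    model in importance oracle work and tests.
    """

    def __init__(self, coef: Sequence[float], intercept: float = 0.0) -> None:
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept


def as_feature_array(X) -> np.ndarray:
    """Coerce OmicsMatrix / DataFrame / ndarray to a 2-D float array."""
    if isinstance(X, OmicsMatrix):
        if not X.standardized:
            logger.warning("fitting on a non-standardized %s matrix", X.layer)
        return X.values()
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise InputError(f"feature matrix must be 2-D, got shape {arr.shape}")
    return arr


def _build(config: RegressorConfig):
    if config.family == "ANN":
        # tol is dropped to 1e-12 so Adam actually consumes the stated
        # iteration budget instead of stopping on sklearn's loose default.
        return MLPRegressor(
            hidden_layer_sizes=(config.neurons_per_layer,) * config.hidden_layers,
            max_iter=config.max_iterations,
            random_state=config.seed,
            tol=1e-12,
        )
    if config.family == "RF":
        return RandomForestRegressor(
            n_estimators=config.n_estimators, random_state=config.seed
        )
    return _SKSVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon)


def fit_regressor(config: RegressorConfig, X, y):
    """Fit one regressor; returns the trained model handle.

    The handle supports ``predict``. An ANN that exhausts its iteration
    budget logs a warning but is still returned (by construction it
    almost always runs the full budget; see module docstring).
    """
    arr = as_feature_array(X)
    target = np.asarray(y, dtype=float).ravel()
    if arr.shape[0] != target.size:
        raise InputError(
            f"X has {arr.shape[0]} rows but y has {target.size} entries"
        )
    model = _build(config)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(arr, target)
    for w in caught:
        logger.warning("%s fit: %s", config.family, w.message)
    return model


def evaluate(model, X, y, accuracy: bool = True) -> FitMetrics:
    """MAE / MSE / accuracy of `model` on (X, y).

    Raises
    ------
    MetricDomainError
        If accuracy is requested with any non-positive target (the
        relative-error accuracy is undefined there).
    """
    arr = as_feature_array(X)
    target = np.asarray(y, dtype=float).ravel()
    if arr.shape[0] != target.size:
        raise InputError("X and y are misaligned")
    pred = np.asarray(model.predict(arr), dtype=float).ravel()
    resid = pred - target
    mae = float(np.abs(resid).mean())
    mse = float((resid**2).mean())
    acc = None
    if accuracy:
        if np.any(target <= 0):
            raise MetricDomainError("accuracy needs strictly positive targets")
        acc = float(100.0 * (1.0 - np.mean(np.abs(resid) / target)))
    return FitMetrics(mae=mae, mse=mse, accuracy_pct=acc)


def loo_metrics(config: RegressorConfig, X, y, accuracy: bool = True) -> FitMetrics:
    """Leave-one-out cross-validated metrics (honest generalization mode).

    This is NOT the published protocol (which evaluates in sample); it
    exists for users who want a generalization estimate at n this small.
    """
    arr = as_feature_array(X)
    target = np.asarray(y, dtype=float).ravel()
    preds = np.empty_like(target)
    for i in range(target.size):
        mask = np.ones(target.size, dtype=bool)
        mask[i] = False
        model = fit_regressor(config, arr[mask], target[mask])
        preds[i] = model.predict(arr[i : i + 1])[0]
    resid = preds - target
    acc = None
    if accuracy:
        if np.any(target <= 0):
            raise MetricDomainError("accuracy needs strictly positive targets")
        acc = float(100.0 * (1.0 - np.mean(np.abs(resid) / target)))
    return FitMetrics(float(np.abs(resid).mean()), float((resid**2).mean()), acc)


def benchmark(
    configs: Sequence[RegressorConfig], X_by_layer: Mapping[str, object], y
) -> pd.DataFrame:
    """Fit every config on every layer; return the complete metrics table.

    Rows are (layer, family) with mae, mse, accuracy_pct columns.
    Duplicate configurations are kept but flagged with a warning. The
    observed metric ordering across families is logged, not asserted —
    it is data-dependent.
    """
    if not configs or not X_by_layer:
        raise InputError("benchmark needs at least one config and one layer")
    if len(set(configs)) != len(configs):
        warnings.warn("duplicate regressor configurations in benchmark", stacklevel=2)
    rows = []
    for layer, X in X_by_layer.items():
        for config in configs:
            model = fit_regressor(config, X, y)
            m = evaluate(model, X, y)
            rows.append(
                {
                    "layer": layer,
                    "family": config.family,
                    "mae": m.mae,
                    "mse": m.mse,
                    "accuracy_pct": m.accuracy_pct,
                }
            )
    table = pd.DataFrame(rows)
    for layer, sub in table.groupby("layer"):
        order = sub.sort_values("mae")["family"].tolist()
        logger.info("benchmark %s: MAE ordering %s", layer, " <= ".join(order))
    return table
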