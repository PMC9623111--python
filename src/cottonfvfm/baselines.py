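"""Nine classical comparator regressors behind one uniform interface.

These are benchmarks for the 1D-CNN, not the contribution, so each is the
established library implementation: scikit-learn for DT, RF, GBDT, AdaBoost,
ET and KNN; xgboost and lightgbm for their namesakes; CatBoost when the
library is importable.  Unavailable optional libraries are skipped with a log
entry rather than failing the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cottonfvfm.metrics import evaluate, split_train_test
from cottonfvfm.spectra_io import STAGES, DesignMatrix

logger = logging.getLogger(__name__)

BASELINE_NAMES = (
    "CatBoost",
    "LightGBM",
    "XGBoost",
    "DT",
    "RF",
    "GBDT",
    "AdaBoost",
    "ET",
    "KNN",
)


class LibraryUnavailableError(ImportError):
    """The optional library backing a baseline is not installed."""


@dataclass(frozen=True)
class BaselineSpec:
    """One comparator: closed-set name, hyperparameter overrides, seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}")


def _build(spec: BaselineSpec):
    hp = dict(spec.hyperparameters)
    name, seed = spec.name, spec.seed
    if name == "DT":
        from sklearn.tree import DecisionTreeRegressor

        return DecisionTreeRegressor(random_state=seed, **hp)
    if name == "RF":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(random_state=seed, **hp)
    if name == "GBDT":
        from sklearn.ensemble import GradientBoostingRegressor

        return GradientBoostingRegressor(random_state=seed, **hp)
    if name == "AdaBoost":
        from sklearn.ensemble import AdaBoostRegressor

        return AdaBoostRegressor(random_state=seed, **hp)
    if name == "ET":
        from sklearn.ensemble import ExtraTreesRegressor

        return ExtraTreesRegressor(random_state=seed, **hp)
    if name == "KNN":
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor(**hp)
    if name == "XGBoost":
        try:
            from xgboost import XGBRegressor
        except ImportError as exc:
            raise LibraryUnavailableError("xgboost is not installed") from exc
        return XGBRegressor(random_state=seed, n_jobs=1, **hp)
    if name == "LightGBM":
        try:
            from lightgbm import LGBMRegressor
        except ImportError as exc:
            raise LibraryUnavailableError("lightgbm is not installed") from exc
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **hp)
    if name == "CatBoost":
        try:
            from catboost import CatBoostRegressor
        except ImportError as exc:
            raise LibraryUnavailableError("catboost is not installed") from exc
        return CatBoostRegressor(random_seed=seed, verbose=False, **hp)
    raise AssertionError("unreachable")


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray):
    """Fit one comparator; the returned estimator exposes ``predict(X)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    model = _build(spec)
    model.fit(X, y)
    return model


def compare_models(
    matrix: DesignMatrix,
    models: Sequence[BaselineSpec],
    fraction: float = 0.75,
    include_cnn: "object | None" = None,
) -> pd.DataFrame:
    """Benchmark the comparators per treatment x stage on held-out samples.

    For every treatment condition (CK/DS) and growth stage present in the
    design matrix, the subset is split 75/25 (sorted by sample id), each model
    is fitted on the training part, and RMSE/MAE/MAPE are reported on the test
    part.  ``include_cnn`` may carry a trained CNN model, which is then scored
    on the same held-out rows for a like-for-like row in the table.
    Unavailable libraries are skipped with a log entry; the table also echoes
    each estimator's effective hyperparameters for provenance.
    """
    rows = []
    for treatment in ("CK", "DS"):
        for stage in STAGES:
            idx = [
                i
                for i, m in enumerate(matrix.meta)
                if m.treatment == treatment and m.stage == stage
            ]
            if not idx:
                continue
            sub = DesignMatrix(
                X=matrix.X[idx],
                y=matrix.y[idx],
                meta=[matrix.meta[i] for i in idx],
                grid=matrix.grid,
            )
            train_m, test_m = split_train_test(sub, fraction=fraction)
            for spec in models:
                try:
                    fitted = fit_baseline(spec, train_m.X, train_m.y)
                except LibraryUnavailableError as exc:
                    logger.warning("skipping %s (%s)", spec.name, exc)
                    continue
                pred = np.asarray(fitted.predict(test_m.X), dtype=float)
                met = evaluate(test_m.y, pred)
                rows.append(
                    {
                        "model": spec.name,
                        "treatment": treatment,
                        "stage": stage,
                        "rmse": met.rmse,
                        "mae": met.mae,
                        "mape": met.mape,
                        "r2": met.r2,
                        "n_train": len(train_m),
                        "n_test": len(test_m),
                        "params": repr(getattr(fitted, "get_params", dict)()),
                    }
                )
            if include_cnn is not None:
                from cottonfvfm.cnn import predict as cnn_predict

                pred = cnn_predict(include_cnn, test_m.X)
                met = evaluate(test_m.y, pred)
                rows.append(
                    {
                        "model": "1D-CNN",
                        "treatment": treatment,
                        "stage": stage,
                        "rmse": met.rmse,
                        "mae": met.mae,
                        "mape": met.mape,
                        "r2": met.r2,
                        "n_train": len(train_m),
                        "n_test": len(test_m),
                        "params": repr(include_cnn.config),
                    }
                )
    return pd.DataFrame(rows)


def default_baselines(seed: int = 0) -> list[BaselineSpec]:
    """All nine comparators with library-default hyperparameters."""
    return [BaselineSpec(name=n, seed=seed) for n in BASELINE_NAMES]
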