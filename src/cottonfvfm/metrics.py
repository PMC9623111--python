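"""Regression evaluation metrics and the deterministic train/test split.

The four standard chemometric metrics: coefficient of determination R²,
root-mean-square error, mean absolute percentage error (reported in percent)
and mean absolute error.  The split mirrors a sorted 75/25 partition: rows are
ordered by sample id and the leading fraction becomes the training set, so the
split is reproducible without a random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cottonfvfm.spectra_io import DesignMatrix


@dataclass
class PredictionSet:
    """Paired true/predicted target values."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if self.y_true.size != self.y_pred.size:
            raise ValueError("y_true and y_pred must have equal lengths")
        if self.y_true.size < 1:
            raise ValueError("need at least one prediction")

    @property
    def n(self) -> int:
        return int(self.y_true.size)


@dataclass(frozen=True)
class EvalMetrics:
    """The four metrics; ``mape`` is in percent."""

    r2: float
    rmse: float
    mae: float
    mape: float


def _as_pred(p, y_pred=None) -> PredictionSet:
    if y_pred is not None:
        return PredictionSet(p, y_pred)
    return p


def r2(p, y_pred=None) -> float:
    """Coefficient of determination, 1 - SSres/SStot (undefined for constant y)."""
    p = _as_pred(p, y_pred)
    if p.n < 2:
        raise ValueError("R² needs at least two samples")
    sstot = float(np.sum((p.y_true - p.y_true.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("R² undefined for constant y_true")
    return 1.0 - float(np.sum((p.y_true - p.y_pred) ** 2)) / sstot


def rmse(p, y_pred=None) -> float:
    """Root-mean-square error."""
    p = _as_pred(p, y_pred)
    return float(np.sqrt(np.mean((p.y_true - p.y_pred) ** 2)))


def mae(p, y_pred=None) -> float:
    """Mean absolute error."""
    p = _as_pred(p, y_pred)
    return float(np.mean(np.abs(p.y_true - p.y_pred)))


def mape(p, y_pred=None) -> float:
    """Mean absolute percentage error, (100/n) * sum |(pred - true)/true|."""
    p = _as_pred(p, y_pred)
    if np.any(p.y_true == 0):
        raise ValueError("MAPE undefined when y_true contains zeros")
    return 100.0 * float(np.mean(np.abs((p.y_pred - p.y_true) / p.y_true)))


def evaluate(y_true, y_pred) -> EvalMetrics:
    """All four metrics at once."""
    p = PredictionSet(y_true, y_pred)
    return EvalMetrics(r2=r2(p), rmse=rmse(p), mae=mae(p), mape=mape(p))


def split_train_test(
    matrix: DesignMatrix, fraction: float = 0.75, shuffle_seed: int | None = None
) -> tuple[DesignMatrix, DesignMatrix]:
    """Deterministic sorted-prefix split: first floor(n*fraction) rows train.

    Rows are sorted by sample id first, so any input permutation yields the
    same split.  ``shuffle_seed`` replaces the sorted order with a seeded
    permutation for randomized robustness studies.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.argsort([m.sample_id for m in matrix.meta], kind="stable")
    if shuffle_seed is not None:
        order = order[np.random.default_rng(shuffle_seed).permutation(n)]
    n_train = int(np.floor(n * fraction))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"fraction {fraction} leaves an empty side for n={n}")
    tr, te = order[:n_train], order[n_train:]

    def _take(idx):
        return DesignMatrix(
            X=matrix.X[idx],
            y=matrix.y[idx],
            meta=[matrix.meta[i] for i in idx],
            grid=matrix.grid,
        )

    return _take(tr), _take(te)
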