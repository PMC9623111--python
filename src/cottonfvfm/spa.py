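"""Successive Projections Algorithm (SPA) wavelength selection.

SPA is a greedy forward selector that fights collinearity: starting from one
column, each step picks the column with the largest norm in the orthogonal
complement of the span of the columns already chosen.  Candidate subsets (all
start columns x all chain lengths) are scored by ordinary-least-squares
regression on a calibration set and RMSE on a validation set; the
Kennard-Stone algorithm provides the deterministic, maximally-spread
calibration/validation split conventionally paired with SPA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of an SPA sweep.

    ``validation_rmse`` maps each candidate chain length N to the best
    validation RMSE over all start columns at that N; ``indices`` is the
    winning chain (selection order preserved).
    """

    indices: list[int]
    validation_rmse: dict[int, float]
    best_rmse: float
    start: int

    @property
    def n_selected(self) -> int:
        return len(self.indices)


def spa_chain(X: np.ndarray, start: int, N: int, center: bool = True) -> list[int]:
    """Build an SPA projection chain of length ``N`` from column ``start``.

    At each step the next column maximizes the Euclidean norm of its component
    orthogonal to the span of the already-selected columns; ties break toward
    the lowest column index.  Columns are mean-centred first by default
    (standard SPA practice, removes offset dominance).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start column {start} out of range [0, {p})")
    if not 1 <= N <= min(n, p):
        raise ValueError(f"chain length {N} not in [1, min(n_rows, n_cols)={min(n, p)}]")
    R = X - X.mean(axis=0) if center else X.copy()
    chain = [start]
    for _ in range(N - 1):
        r = R[:, chain[-1]]
        nrm2 = float(r @ r)
        if nrm2 <= 1e-300:
            raise ValueError(
                f"chain length {N} exceeds the rank-feasible length at column {chain[-1]}"
            )
        # project every column onto the orthogonal complement of the last pick
        R = R - np.outer(r, (r @ R) / nrm2)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0  # already selected
        nxt = int(np.argmax(norms))  # argmax breaks ties by lowest index
        if norms[nxt] <= 1e-12:
            raise ValueError(f"chain length {N} exceeds the rank-feasible length")
        chain.append(nxt)
    return chain


def _ols_rmse(
    Xcal: np.ndarray, ycal: np.ndarray, Xval: np.ndarray, yval: np.ndarray, cols: list[int]
) -> float | None:
    """Validation RMSE of OLS on the selected columns, or None if rank-deficient."""
    A = np.column_stack([np.ones(Xcal.shape[0]), Xcal[:, cols]])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(A, ycal, rcond=None)
    pred = np.column_stack([np.ones(Xval.shape[0]), Xval[:, cols]]) @ beta
    return float(np.sqrt(np.mean((yval - pred) ** 2)))


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    Nmin: int = 1,
    Nmax: int = 10,
    max_starts: int | None = None,
) -> SelectionResult:
    """Sweep SPA chains over start columns and lengths; keep the best subset.

    For every start column and every N in [Nmin, Nmax] the SPA chain is built
    on the calibration matrix, an intercept-plus-selected-columns OLS model is
    fitted on calibration data and scored by RMSE on the validation set; the
    subset with minimal validation RMSE wins.  ``max_starts`` caps the start
    sweep by deterministic stride subsampling for very wide matrices.
    Rank-deficient candidates are skipped with a log entry.
    """
    Xcal = np.asarray(Xcal, dtype=float)
    Xval = np.asarray(Xval, dtype=float)
    ycal = np.asarray(ycal, dtype=float)
    yval = np.asarray(yval, dtype=float)
    n, p = Xcal.shape
    if not 1 <= Nmin <= Nmax <= min(n - 1, p):
        raise ValueError(f"need 1 <= Nmin <= Nmax <= min(n_rows-1, n_cols)={min(n - 1, p)}")
    starts = np.arange(p)
    if max_starts is not None and max_starts < p:
        starts = starts[:: max(1, p // max_starts)][:max_starts]
    best: tuple[float, list[int], int] | None = None
    trace: dict[int, float] = {}
    for start in starts:
        try:
            chain = spa_chain(Xcal, int(start), Nmax)
        except ValueError:
            # rank-limited: fall back to the shortest requested chain
            try:
                chain = spa_chain(Xcal, int(start), Nmin)
            except ValueError:
                logger.info("skipping rank-limited start column %d", start)
                continue
        for N in range(Nmin, min(Nmax, len(chain)) + 1):
            cols = chain[:N]
            score = _ols_rmse(Xcal, ycal, Xval, yval, cols)
            if score is None:
                logger.info("skipping rank-deficient candidate start=%d N=%d", start, N)
                continue
            if N not in trace or score < trace[N]:
                trace[N] = score
            if best is None or score < best[0]:
                best = (score, cols, int(start))
    if best is None:
        raise ValueError("no full-rank candidate subset found")
    return SelectionResult(
        indices=best[1], validation_rmse=trace, best_rmse=best[0], start=best[2]
    )


def kennard_stone_split(X: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone calibration/validation split.

    The first two calibration picks are the maximally distant sample pair
    (Euclidean); every subsequent pick maximizes its minimum distance to the
    already-picked set.  Deterministic; ties break toward the lowest index.
    Returns ``round(n * fraction)`` calibration indices (sorted) and the
    remaining validation indices.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_cal = int(round(n * fraction))
    n_cal = max(1, min(n - 1, n_cal))
    D = squareform(pdist(X))
    # farthest pair; np.argmax flattens row-major -> lowest index pair on ties
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    picked = [min(i, j), max(i, j)][:n_cal]
    remaining = [k for k in range(n) if k not in picked]
    min_d = D[picked].min(axis=0) if picked else None
    while len(picked) < n_cal:
        cand = max(remaining, key=lambda k: (min_d[k], -k))
        picked.append(cand)
        remaining.remove(cand)
        min_d = np.minimum(min_d, D[cand])
    cal = np.array(sorted(picked), dtype=int)
    val = np.array([k for k in range(n) if k not in set(picked)], dtype=int)
    return cal, val
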