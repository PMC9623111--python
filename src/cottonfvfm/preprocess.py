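"""Spectral preprocessing: Savitzky-Golay smoothing, reference-panel
reflectance calibration, grid resampling, replicate averaging, and reversible
standardization.

Savitzky-Golay is the workhorse of chemometric denoising: each point is
replaced by the value of a local least-squares polynomial fit, which preserves
peak shape and is exact on polynomials up to the fit degree.  Edges are handled
by evaluating the terminal window's polynomial at the edge positions, so the
output length always equals the input length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from cottonfvfm.spectra_io import SampleMeta, SpectraSet, Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay settings: odd window length (samples) and fit degree.

    ``deriv=0`` smooths; higher values return smoothed derivatives.
    """

    window: int = 11
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("polyorder must satisfy 0 <= polyorder < window")
        if self.deriv < 0:
            raise ValueError("deriv must be >= 0")


def savitzky_golay(values: np.ndarray, params: SGParams = SGParams()) -> np.ndarray:
    """Savitzky-Golay filter a 1-D series (or each row of a 2-D array)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] < params.window:
        raise ValueError(
            f"series length {arr.shape[-1]} shorter than window {params.window}"
        )
    return savgol_filter(
        arr, params.window, params.polyorder, deriv=params.deriv, axis=-1, mode="interp"
    )


def calibrate_reflectance(
    L: np.ndarray, Lr: np.ndarray, Rr: np.ndarray | float
) -> np.ndarray:
    """Convert target radiance to reflectance via a reference panel.

    ``Rt[i] = (L[i] / Lr[i]) * Rr[i]`` where ``L`` is the target radiance,
    ``Lr`` the reference-panel radiance and ``Rr`` the panel's (near-unity)
    reflectance.
    """
    L = np.asarray(L, dtype=float)
    Lr = np.asarray(Lr, dtype=float)
    Rr = np.broadcast_to(np.asarray(Rr, dtype=float), L.shape)
    if L.shape != Lr.shape:
        raise ValueError("L and Lr must have equal lengths")
    bad = np.nonzero(Lr <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive reference radiance at channel(s) {bad.tolist()}")
    return (L / Lr) * Rr


def resample_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a target wavelength grid.

    Extrapolation is refused: the target grid must lie within the source span.
    Coincident wavelengths reproduce the source values exactly.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] outside source span [{lo}, {hi}]"
        )
    f = interp1d(spectrum.wavelengths, spectrum.values, kind="linear", assume_sorted=True)
    return Spectrum(grid, f(grid), value_kind=spectrum.value_kind)


def average_replicates(
    spectra: SpectraSet, keys: tuple[str, ...] = ("genotype_id", "treatment", "stage")
) -> SpectraSet:
    """Average spectra over replicates, one output row per unique key tuple.

    Mirrors the field protocol of averaging repeated readings per leaf.  The
    replicate field is collapsed to 1; idempotent on already-averaged sets.
    """
    if len(spectra) == 0:
        raise ValueError("cannot average an empty SpectraSet")
    allowed = ("genotype_id", "treatment", "stage")
    if not keys or any(k not in allowed for k in keys):
        raise ValueError(f"keys must be a nonempty subset of {allowed}")
    groups: dict[tuple, list[int]] = {}
    for i, m in enumerate(spectra.meta):
        k = tuple(getattr(m, f) for f in keys)
        groups.setdefault(k, []).append(i)
    meta_out: list[SampleMeta] = []
    values_out = np.empty((len(groups), spectra.grid.size))
    for j, (k, idx) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
        values_out[j] = spectra.values[idx].mean(axis=0)
        first = spectra.meta[idx[0]]
        meta_out.append(
            SampleMeta(
                sample_id="|".join(str(v) for v in k),
                genotype_id=first.genotype_id,
                treatment=first.treatment if "treatment" in keys else "CK",
                stage=first.stage if "stage" in keys else "flowering",
                replicate=1,
            )
        )
    return SpectraSet(grid=spectra.grid.copy(), meta=meta_out, values=values_out)


@dataclass
class ScalerState:
    """Frozen centring/scaling parameters for features and target."""

    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    divide_by_variance: bool = False


class Standardizer:
    """Reversible z-scoring of the design matrix and target.

    Centres by the mean and divides by the population standard deviation
    (``divide_by_variance=True`` divides by the variance instead, the literal
    reading of "subtracting the mean and dividing by the variance"; the
    conventional z-score is the default).  Constant features get scale 1 so
    they standardize to zeros without a division error.  The fitted state is
    carried by trained models so predictions can be mapped back to raw Fv/Fm
    units ("anti-normalization").
    """

    def __init__(self, divide_by_variance: bool = False):
        self.divide_by_variance = divide_by_variance
        self.state: ScalerState | None = None

    @staticmethod
    def _scale(spread: np.ndarray) -> np.ndarray:
        spread = np.atleast_1d(spread).astype(float)
        const = spread == 0
        if const.any():
            logger.warning("constant feature(s) standardized with scale 1: %d", const.sum())
            spread = np.where(const, 1.0, spread)
        return spread

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        x_spread = X.var(axis=0) if self.divide_by_variance else X.std(axis=0)
        y_spread = y.var() if self.divide_by_variance else y.std()
        self.state = ScalerState(
            x_center=X.mean(axis=0),
            x_scale=self._scale(x_spread),
            y_center=float(y.mean()),
            y_scale=float(self._scale(np.array(y_spread))[0]),
            divide_by_variance=self.divide_by_variance,
        )
        return self

    def _require_state(self) -> ScalerState:
        if self.state is None:
            raise RuntimeError("Standardizer is not fitted")
        return self.state

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        s = self._require_state()
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != s.x_center.size:
            raise ValueError(
                f"feature count mismatch: expected {s.x_center.size}, got {X.shape[-1]}"
            )
        return (X - s.x_center) / s.x_scale

    def inverse_X(self, Xs: np.ndarray) -> np.ndarray:
        s = self._require_state()
        return np.asarray(Xs, dtype=float) * s.x_scale + s.x_center

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        s = self._require_state()
        return (np.asarray(y, dtype=float) - s.y_center) / s.y_scale

    def inverse_y(self, ys: np.ndarray) -> np.ndarray:
        s = self._require_state()
        return np.asarray(ys, dtype=float) * s.y_scale + s.y_center


def fit_standardizer(
    X: np.ndarray, y: np.ndarray, divide_by_variance: bool = False
) -> Standardizer:
    """Fit a :class:`Standardizer` on a design matrix and target vector."""
    return Standardizer(divide_by_variance=divide_by_variance).fit(X, y)
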