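"""Spectral containers and I/O.

The central carrier is :class:`SpectraSet`: a shared wavelength grid plus one
reflectance row per leaf sample, each row tagged with :class:`SampleMeta`
(genotype, water treatment, growth stage, replicate).  Two text dialects are
supported: a CSV table (metadata columns followed by one numeric-wavelength
column per channel) and the whitespace-delimited four-column ASCII records that
field spectroradiometers export (wavelength, reference radiance, target
radiance, percent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("CK", "DS")
STAGES = ("flowering", "boll_setting", "boll_opening")

#: columns that precede the per-wavelength columns in a spectra table
META_COLUMNS = ("sample_id", "genotype_id", "treatment", "stage", "replicate")

#: reflectance above 1.0 is tolerated (calibration overshoot near noise bands),
#: above this it is rejected as a gross error
REFLECTANCE_CEILING = 1.5


class SpectraIOError(ValueError):
    """Malformed spectral input."""


@dataclass
class Spectrum:
    """A single wavelength-indexed curve.

    ``value_kind`` is ``"reflectance"`` (dimensionless, expected in [0, 1]) or
    ``"radiance"`` (instrument units, unconstrained positive).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    value_kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise SpectraIOError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise SpectraIOError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraIOError("wavelengths must be strictly increasing")
        if self.value_kind not in ("reflectance", "radiance"):
            raise SpectraIOError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "reflectance" and self.values.size:
            top = float(np.max(self.values))
            if np.min(self.values) < 0 or top > REFLECTANCE_CEILING:
                raise SpectraIOError(
                    f"reflectance outside [0, {REFLECTANCE_CEILING}]"
                )
            if top > 1.0:
                logger.warning(
                    "reflectance up to %.3f exceeds 1.0 (calibration overshoot retained)",
                    top,
                )

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class SampleMeta:
    """Experimental identity of one leaf sample."""

    sample_id: str
    genotype_id: int
    treatment: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise SpectraIOError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.stage not in STAGES:
            raise SpectraIOError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if int(self.replicate) < 1:
            raise SpectraIOError("replicate must be a positive integer")

    @property
    def key(self) -> tuple:
        return (self.genotype_id, self.treatment, self.stage, self.replicate)


@dataclass
class SpectraSet:
    """Reflectance curves for many samples on one shared wavelength grid."""

    grid: np.ndarray
    meta: list[SampleMeta]
    values: np.ndarray  # (n_samples, n_wavelengths)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.meta) == 0:
            self.values = self.values.reshape(0, self.grid.size)
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise SpectraIOError("grid must be strictly increasing")
        if self.values.shape != (len(self.meta), self.grid.size):
            raise SpectraIOError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.meta)}, {self.grid.size})"
            )
        seen: dict[tuple, str] = {}
        for m in self.meta:
            if m.key in seen:
                raise SpectraIOError(f"duplicate sample key {m.key}")
            seen[m.key] = m.sample_id

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def to_frame(self) -> pd.DataFrame:
        meta_df = pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "genotype_id": [m.genotype_id for m in self.meta],
                "treatment": [m.treatment for m in self.meta],
                "stage": [m.stage for m in self.meta],
                "replicate": [m.replicate for m in self.meta],
            }
        )
        spec_df = pd.DataFrame(self.values, columns=[repr(float(w)) for w in self.grid])
        return pd.concat([meta_df, spec_df], axis=1)


@dataclass
class DesignMatrix:
    """Analysis-ready (X, y, meta) triple, rows sorted by sample id."""

    X: np.ndarray
    y: np.ndarray
    meta: list[SampleMeta]
    grid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.X.shape[0] == self.y.shape[0] == len(self.meta)):
            raise SpectraIOError("X, y and meta row counts differ")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise SpectraIOError("design matrix contains missing values")

    def __len__(self) -> int:
        return len(self.meta)


def read_svc_ascii(path: str | Path):
    """Read a field-spectroradiometer ASCII record.

    The format is whitespace-delimited with at least four numeric columns:
    wavelength (nm), reference radiance, target radiance, and percent
    (target/reference x 100).  Leading banner lines and ``#`` comments are
    skipped; once data has started every line must parse.

    Returns
    -------
    (reference, target, percent)
        Two radiance :class:`Spectrum` objects on the same wavelength axis and
        the percent column converted to a fraction.
    """
    path = Path(path)
    wavelengths: list[float] = []
    ref: list[float] = []
    tgt: list[float] = []
    pct: list[float] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                row = [float(f) for f in fields]
                ok = len(row) >= 4
            except ValueError:
                ok = False
            if not ok:
                if in_data:
                    raise SpectraIOError(
                        f"{path.name}: malformed data row at line {lineno}: {line!r}"
                    )
                continue  # header banner
            in_data = True
            wavelengths.append(row[0])
            ref.append(row[1])
            tgt.append(row[2])
            pct.append(row[3] / 100.0)
    if not wavelengths:
        raise SpectraIOError(f"{path.name}: no data rows found")
    wl = np.asarray(wavelengths)
    if np.any(np.diff(wl) <= 0):
        raise SpectraIOError(f"{path.name}: wavelengths are not strictly increasing")
    reference = Spectrum(wl, np.asarray(ref), value_kind="radiance")
    target = Spectrum(wl, np.asarray(tgt), value_kind="radiance")
    return reference, target, np.asarray(pct)


def read_spectra_table(path: str | Path) -> SpectraSet:
    """Read a CSV spectra table (metadata columns then wavelength columns)."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraIOError(f"missing metadata columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        grid = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraIOError(f"non-numeric wavelength header: {exc}") from exc
    values = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = np.nonzero(np.isnan(values).any(axis=1))[0][0]
        raise SpectraIOError(f"missing spectral values in row {bad} (ragged table?)")
    meta = [
        SampleMeta(
            sample_id=str(r.sample_id),
            genotype_id=int(r.genotype_id),
            treatment=str(r.treatment),
            stage=str(r.stage),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    return SpectraSet(grid=grid, meta=meta, values=values)


def write_spectra_table(spectra: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as CSV, re-readable by :func:`read_spectra_table`.

    Values are written with full float precision (repr round-trip).
    """
    df = spectra.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def to_design_matrix(
    spectra: SpectraSet, targets: Mapping[str, float] | pd.Series
) -> DesignMatrix:
    """Pair every spectrum with its Fv/Fm target, rows sorted by sample id."""
    if isinstance(targets, pd.Series):
        targets = targets.to_dict()
    missing = sorted(m.sample_id for m in spectra.meta if m.sample_id not in targets)
    if missing:
        raise SpectraIOError(f"missing targets for samples: {missing}")
    order = np.argsort([m.sample_id for m in spectra.meta], kind="stable")
    meta = [spectra.meta[i] for i in order]
    X = spectra.values[order]
    y = np.array([float(targets[m.sample_id]) for m in meta])
    return DesignMatrix(X=X, y=y, meta=meta, grid=spectra.grid.copy())
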