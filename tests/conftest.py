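"""Shared fixtures: small synthetic trials and helper constructors.

Everything is generated programmatically at test time; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from cottonfvfm.spectra_io import SampleMeta, SpectraSet
from cottonfvfm.synthetic import TrialParams, default_grid, make_genotypes, simulate_trial


def make_meta(sample_id="G001-CK-S0-R1", genotype=1, treatment="CK", stage="flowering", rep=1):
    return SampleMeta(
        sample_id=sample_id,
        genotype_id=genotype,
        treatment=treatment,
        stage=stage,
        replicate=rep,
    )


def small_spectra_set(n_samples=4, n_wavelengths=5, seed=0) -> SpectraSet:
    """Tiny hand-sized SpectraSet with distinct sample keys."""
    rng = np.random.default_rng(seed)
    grid = np.linspace(400.0, 800.0, n_wavelengths)
    meta = []
    for i in range(n_samples):
        meta.append(
            make_meta(
                sample_id=f"S{i:03d}",
                genotype=i + 1,
                treatment="CK" if i % 2 == 0 else "DS",
                rep=1,
            )
        )
    values = rng.uniform(0.05, 0.6, (n_samples, n_wavelengths))
    return SpectraSet(grid=grid, meta=meta, values=values)


@pytest.fixture(scope="session")
def small_trial():
    """G=6 full-factorial trial on a 128-channel grid (216 samples)."""
    panel = make_genotypes(6, seed=42)
    params = TrialParams(grid=default_grid(128))
    spectra, records = simulate_trial(panel, params, seed=42)
    return panel, params, spectra, records


@pytest.fixture(scope="session")
def noiseless_params():
    return TrialParams(
        fvfm_noise_sd=0.0, spectral_noise_sd=0.0, grid=default_grid(128)
    )
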