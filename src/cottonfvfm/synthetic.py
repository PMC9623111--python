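"""Synthetic multi-genotype cotton drought trials.

Emulates the structure of a factorial field screen: ``G`` genotypes x two
water treatments (CK well-watered at 75 +/- 5% soil relative water content, DS
drought stress at 45 +/- 5%) x three growth stages (flowering, boll setting,
boll opening) x replicate plots.  Each genotype carries a latent drought
tolerance ``tau`` in [0, 1]; drought reduces Fv/Fm by a stage-specific maximal
fraction scaled by ``1 - tau``, so a fully tolerant genotype (tau = 1) is
unaffected.  Leaf reflectance spectra are generated from each sample's realized
Fv/Fm and stress severity with the canonical vegetation features: absorption
valleys in 370-510 and 600-710 nm, a green peak in 520-580 nm, a red-edge ramp
onto a near-infrared plateau over 760-1250 nm, a short-wave-infrared decline,
and water absorption bands at 1450 and 1950 nm.  Drought raises the green peak
and lowers the NIR plateau; higher Fv/Fm raises the plateau.

The generator is the ground truth for every downstream test: with zero noise it
is an exact deterministic function of ``(tau, params)``, and the genotype
ranking recovered from drought-tolerance coefficients equals the ranking of
``tau`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cottonfvfm.spectra_io import STAGES, SampleMeta, SpectraSet, Spectrum

INSTRUMENT_RANGE = (350.0, 2500.0)


def default_grid(n_channels: int = 1024) -> np.ndarray:
    """Even wavelength grid spanning the spectroradiometer range (350-2500 nm)."""
    return np.linspace(INSTRUMENT_RANGE[0], INSTRUMENT_RANGE[1], n_channels)


@dataclass(frozen=True)
class GenotypePanel:
    """Latent drought tolerance per genotype (the quantity the screen ranks)."""

    G: int
    tau: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        if self.tau.shape != (self.G,):
            raise ValueError("tau must have one entry per genotype")
        if self.tau.size and (self.tau.min() < 0 or self.tau.max() > 1):
            raise ValueError("tau values must lie in [0, 1]")


@dataclass
class TrialParams:
    """Trial-level generator settings.

    ``stage_baseline_fvfm`` encodes the rise-then-fall of Fv/Fm across
    flowering, boll setting and boll opening under well-watered conditions;
    the values are generator defaults chosen to produce that pattern, not field
    measurements.  ``stage_max_drop`` is the fractional DS reduction at tau = 0
    per stage (2% / 12% / 3%, the stage pattern the screen is built around);
    genotype means over a uniform tau panel are about half these.
    """

    stage_baseline_fvfm: tuple[float, float, float] = (0.78, 0.83, 0.76)
    stage_max_drop: tuple[float, float, float] = (0.02, 0.12, 0.03)
    fvfm_noise_sd: float = 0.002
    genotype_effect_sd: float = 0.015
    spectral_noise_sd: float = 0.003
    n_replicates: int = 3
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not all(0 < b < 1 for b in self.stage_baseline_fvfm):
            raise ValueError("stage baselines must lie in (0, 1)")
        if not all(0 <= d < 1 for d in self.stage_max_drop):
            raise ValueError("stage_max_drop must lie in [0, 1)")
        if min(self.fvfm_noise_sd, self.genotype_effect_sd, self.spectral_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def stage_stress(self) -> np.ndarray:
        """Stage severities rescaled so the worst stage has stress 1 at tau=0."""
        drops = np.asarray(self.stage_max_drop, dtype=float)
        top = drops.max()
        return drops / top if top > 0 else np.zeros(3)


@dataclass(frozen=True)
class PhysiologyRecord:
    """Fluorescence and water-content measurements for one sample."""

    sample_id: str
    genotype_id: int
    treatment: str
    stage: str
    replicate: int
    Fo: float
    Fm: float
    fvfm_true: float
    rwc: float
    lwc: float

    def __post_init__(self) -> None:
        if not (0 < self.Fo < self.Fm):
            raise ValueError("require 0 < Fo < Fm")
        if abs(self.fvfm_true - (self.Fm - self.Fo) / self.Fm) > 1e-12:
            raise ValueError("fvfm_true inconsistent with (Fm - Fo)/Fm")
        if not (0 <= self.rwc <= 100 and 0 <= self.lwc <= 100):
            raise ValueError("water contents must lie in [0, 100]")

    @property
    def meta(self) -> SampleMeta:
        return SampleMeta(
            sample_id=self.sample_id,
            genotype_id=self.genotype_id,
            treatment=self.treatment,
            stage=self.stage,
            replicate=self.replicate,
        )


def make_genotypes(G: int, seed: int) -> GenotypePanel:
    """Draw a panel of ``G`` genotypes with uniform latent tolerance tau."""
    if G < 1:
        raise ValueError("G must be >= 1")
    rng = np.random.default_rng(seed)
    return GenotypePanel(G=G, tau=rng.uniform(0.0, 1.0, G), seed=seed)


def _sample_id(g: int, treatment: str, stage_idx: int, rep: int) -> str:
    return f"G{g:03d}-{treatment}-S{stage_idx}-R{rep}"


def simulate_fvfm(
    panel: GenotypePanel, params: TrialParams, seed: int
) -> list[PhysiologyRecord]:
    """Generate one physiology record per genotype x treatment x stage x replicate.

    The noiseless DS value is ``CK x (1 - stage_max_drop x (1 - tau_g))``; a
    multiplicative genotype baseline effect (common to both arms, hence exactly
    cancelled by the drought-tolerance coefficient) and additive replicate noise
    are layered on top.  Fo and Fm are drawn in instrument-like arbitrary units
    so that (Fm - Fo)/Fm reproduces the realized Fv/Fm exactly.  Root and leaf
    water content are affine in Fv/Fm plus noise, planting the positive
    Fv/Fm-water-content correlation the screen relies on.
    """
    rng = np.random.default_rng(seed)
    geno_effect = 1.0 + rng.normal(0.0, params.genotype_effect_sd, panel.G)
    records: list[PhysiologyRecord] = []
    for g in range(panel.G):
        tau_g = panel.tau[g]
        for s, stage in enumerate(STAGES):
            ck_latent = params.stage_baseline_fvfm[s] * geno_effect[g]
            ds_latent = ck_latent * (1.0 - params.stage_max_drop[s] * (1.0 - tau_g))
            for treatment, latent in (("CK", ck_latent), ("DS", ds_latent)):
                for rep in range(1, params.n_replicates + 1):
                    value = latent + rng.normal(0.0, params.fvfm_noise_sd)
                    value = float(np.clip(value, 1e-6, 1.0 - 1e-6))
                    Fm = float(rng.uniform(1500.0, 3000.0))
                    Fo = Fm * (1.0 - value)
                    rwc = float(np.clip(20.0 + 80.0 * value + rng.normal(0.0, 2.0), 0, 100))
                    lwc = float(np.clip(15.0 + 85.0 * value + rng.normal(0.0, 2.0), 0, 100))
                    records.append(
                        PhysiologyRecord(
                            sample_id=_sample_id(g + 1, treatment, s, rep),
                            genotype_id=g + 1,
                            treatment=treatment,
                            stage=stage,
                            replicate=rep,
                            Fo=Fo,
                            Fm=Fm,
                            fvfm_true=value,
                            rwc=rwc,
                            lwc=lwc,
                        )
                    )
    return records


# Fixed spectral-shape constants (centres/widths in nm, amplitudes in
# reflectance units).  One block so the whole base curve is auditable.
_SPECTRAL_SHAPE = {
    "visible_floor": 0.05,
    "uv_shoulder_amp": 0.035,  # lifts the 350 nm end -> local minimum near 450 nm
    "uv_shoulder_width": 45.0,
    "green_center": 550.0,
    "green_width": 32.0,
    "green_amp_base": 0.06,
    "green_amp_stress": 0.08,  # drought raises the green peak
    "red_edge_center": 716.0,
    "red_edge_width": 11.0,
    "plateau_ref": 0.48,  # plateau at Fv/Fm = 0.8, stress 0
    "plateau_fvfm_slope": 1.2,  # reflectance units per unit Fv/Fm
    "plateau_stress_drop": 0.06,  # drought lowers the NIR plateau
    "swir_knee": 1350.0,
    "swir_drop": 0.75,  # fractional decline by 2500 nm
    "water_1450_depth": 0.22,
    "water_1450_width": 38.0,
    "water_1950_depth": 0.26,
    "water_1950_width": 55.0,
}


def simulate_spectrum(
    fvfm: float, stress: float, params: TrialParams, seed: int
) -> Spectrum:
    """Generate one leaf reflectance spectrum from Fv/Fm and stress severity.

    ``stress`` in [0, 1] is the latent drought severity experienced by the
    sample (0 for well-watered).  The curve satisfies, by construction: a local
    maximum inside 520-580 nm whose amplitude rises with stress, local minima
    inside 370-510 and 600-710 nm, a broad 760-1250 nm plateau whose amplitude
    rises with Fv/Fm and falls with stress, Gaussian water-absorption dips at
    1450 and 1950 nm, and additive channel noise clipped into [0, 1].
    """
    wl = np.asarray(params.grid, dtype=float)
    if wl.min() < INSTRUMENT_RANGE[0] - 1e-9 or wl.max() > INSTRUMENT_RANGE[1] + 1e-9:
        raise ValueError("grid outside instrument range 350-2500 nm")
    if not 0.0 <= stress <= 1.0:
        raise ValueError("stress must lie in [0, 1]")
    c = _SPECTRAL_SHAPE

    visible = (
        c["visible_floor"]
        + c["uv_shoulder_amp"] * np.exp(-(((wl - INSTRUMENT_RANGE[0]) / c["uv_shoulder_width"]) ** 2))
        + (c["green_amp_base"] + c["green_amp_stress"] * stress)
        * np.exp(-(((wl - c["green_center"]) / c["green_width"]) ** 2))
    )

    plateau = (
        c["plateau_ref"]
        + c["plateau_fvfm_slope"] * (fvfm - 0.8)
        - c["plateau_stress_drop"] * stress
    )
    plateau = float(np.clip(plateau, 0.05, 0.95))

    # logistic red edge blends the visible curve into the NIR plateau
    edge = 1.0 / (1.0 + np.exp(-(wl - c["red_edge_center"]) / c["red_edge_width"]))
    base = visible * (1.0 - edge) + plateau * edge

    # short-wave-infrared decline beyond the knee
    swir = np.where(
        wl > c["swir_knee"],
        1.0 - c["swir_drop"] * (wl - c["swir_knee"]) / (INSTRUMENT_RANGE[1] - c["swir_knee"]),
        1.0,
    )
    base = base * swir

    base -= c["water_1450_depth"] * np.exp(-(((wl - 1450.0) / c["water_1450_width"]) ** 2))
    base -= c["water_1950_depth"] * np.exp(-(((wl - 1950.0) / c["water_1950_width"]) ** 2))

    rng = np.random.default_rng(seed)
    if params.spectral_noise_sd > 0:
        base = base + rng.normal(0.0, params.spectral_noise_sd, wl.size)
    return Spectrum(wl, np.clip(base, 0.0, 1.0), value_kind="reflectance")


def simulate_trial(
    panel: GenotypePanel, params: TrialParams, seed: int
) -> tuple[SpectraSet, list[PhysiologyRecord]]:
    """Generate the full factorial trial: one spectrum per physiology record.

    The spectrum for each sample is driven by that sample's realized Fv/Fm and
    by the treatment-derived stress level ``stage_stress x (1 - tau_g)`` (zero
    for CK), so physiology and optics share one latent severity.
    """
    ss = np.random.SeedSequence(seed)
    fvfm_seed, spectra_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    records = simulate_fvfm(panel, params, fvfm_seed)
    stage_stress = params.stage_stress
    stage_index = {stage: i for i, stage in enumerate(STAGES)}
    spectrum_seeds = np.random.SeedSequence(spectra_seed).generate_state(len(records)) % (2**31)
    values = np.empty((len(records), params.grid.size))
    meta = []
    for i, rec in enumerate(records):
        if rec.treatment == "DS":
            stress = float(stage_stress[stage_index[rec.stage]] * (1.0 - panel.tau[rec.genotype_id - 1]))
        else:
            stress = 0.0
        spec = simulate_spectrum(rec.fvfm_true, stress, params, int(spectrum_seeds[i]))
        values[i] = spec.values
        meta.append(rec.meta)
    return SpectraSet(grid=params.grid.copy(), meta=meta, values=values), records


def physiology_frame(records: list[PhysiologyRecord]):
    """Tidy DataFrame view of physiology records (one row per sample)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "genotype_id": [r.genotype_id for r in records],
            "treatment": [r.treatment for r in records],
            "stage": [r.stage for r in records],
            "replicate": [r.replicate for r in records],
            "Fo": [r.Fo for r in records],
            "Fm": [r.Fm for r in records],
            "fvfm": [r.fvfm_true for r in records],
            "rwc": [r.rwc for r in records],
            "lwc": [r.lwc for r in records],
        }
    )
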