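# Methods

## The screening problem

A drought-tolerance screen compares many genotypes under two water regimes —
well-watered control (CK, 75 ± 5% soil relative water content) and drought
stress (DS, 45 ± 5%) — across three reproductive stages (flowering, boll
setting, boll opening).  The trait of interest is Fv/Fm = (Fm − Fo)/Fm, the
maximum photochemical quantum yield of PSII measured on dark-adapted leaves.
Per genotype the drought tolerance coefficient is

    DTC = mean Fv/Fm (DS) / mean Fv/Fm (CK),

and genotypes are ranked by descending DTC.  The package's central claim to
test is structural: a 1D-CNN regression from leaf reflectance to Fv/Fm is
accurate enough that the DTC ranking computed from *predicted* values matches
the ranking from *measured* values.

## Synthetic trial generator

Field data of this kind is rarely shareable, so the generator is a first-class
module that plants known structure for every downstream stage to recover.

**Physiology.**  Each genotype g carries a latent tolerance tau_g ~ U(0, 1).
Control Fv/Fm at stage s is `baseline_s × (1 + b_g)` with stage baselines
(0.78, 0.83, 0.76) — generator defaults chosen to produce the rise-then-fall
pattern across stages, not field measurements — and a multiplicative genotype
baseline effect b_g ~ N(0, 0.015²).  Drought multiplies this by
`1 − drop_s × (1 − tau_g)` with maximal stage drops (2%, 12%, 3%).  The
reported stage reductions of that size are treatment means over a whole
panel; here they are treated as the worst-case (tau = 0) drops, so simulated
population means are about half — a deliberate, documented reading.  Replicate
noise is additive N(0, 0.002²): each replicate record stands for a plot mean
of several dark-adapted bench-fluorometer readings, and Fv/Fm is among the
most repeatable fluorescence parameters, so plot-mean noise well below 0.01
is realistic.  Fo and Fm are drawn in instrument-like arbitrary units such
that (Fm − Fo)/Fm equals the realized Fv/Fm exactly.  Root and leaf water
content are affine in Fv/Fm plus noise, clipped to [0, 100]; only their
positive correlation with Fv/Fm is meaningful.

Because the genotype baseline effect is multiplicative and common to both
arms, it cancels exactly in the DTC ratio; with noise off, DTC is a strictly
monotone function of tau, which is what the zero-noise ranking tests assert.

**Spectra.**  The base reflectance curve is a sum of fixed-shape components
(one auditable constant block in `synthetic.py`): a low visible floor with a
UV shoulder (giving a local minimum in 370–510 nm), a Gaussian green peak at
550 nm whose amplitude grows with stress, a logistic red edge at ~716 nm onto
a NIR plateau over 760–1250 nm, a linear short-wave-infrared decline beyond
1350 nm, and Gaussian water-absorption dips at 1450 and 1950 nm.  The plateau
amplitude is `0.48 + 1.2 × (Fv/Fm − 0.8) − 0.06 × stress`: a slope of 1.2
reflectance units per unit Fv/Fm makes the percent-level Fv/Fm differences in
a trial correspond to a few hundredths of NIR reflectance, the separation
visible between control and drought mean spectra in this kind of experiment.
Channel noise is additive N(0, 0.003²) (contact leaf-clip probes are
low-noise); values are clipped to [0, 1].  The stress level driving a DS
sample's spectrum is `(drop_s / max_s drop_s) × (1 − tau_g)`, so one latent
severity drives both physiology and optics.

**What the generator does not emulate:** radiative-transfer realism
(PROSPECT/SAIL-class leaf optics), canopy geometry and illumination effects,
instrument-specific band overlap, weather, or any trait other than Fv/Fm
moving the spectrum.  Passing tests therefore demonstrate that the pipeline
machinery is correct and that the method recovers a planted signal at
realistic noise levels — not that the field-scale accuracy numbers of any
particular experiment will be reproduced.

## Preprocessing

Savitzky–Golay smoothing defaults to window 11, polynomial order 2,
derivative 0.  The source protocol's phrase "first-order smoothing" is
ambiguous between a first-derivative filter and a first smoothing pass; since
downstream analyses use smoothed reflectance (not derivative spectra), the
default is smoothing, with `deriv` exposed.  Window and order are
configuration, not claims.  Edges are handled by evaluating the terminal
window's polynomial at the edge positions (scipy's `mode="interp"`), which
preserves length without padding artifacts.

Standardization subtracts the feature mean and divides by the population
(ddof = 0) standard deviation.  A `divide_by_variance` flag implements the
literal "dividing by the variance" reading, which changes units and is almost
certainly a wording slip; the z-score is the default.  Constant features get
scale 1 (standardize to zeros) with a logged warning.  The fitted scaler
travels with the trained model so predictions are inverted back to raw Fv/Fm
units.

Reflectance calibration follows `Rt = (L / Lr) · Rr`.  Reflectance above 1.0
is retained with a warning (calibration overshoot near noise bands is
physical); above 1.5 it is rejected as a gross error.  Resampling is linear
interpolation with extrapolation refused.

## SPA wavelength selection

The Successive Projections Algorithm deflates the (mean-centred) calibration
matrix: after selecting a column, every remaining column is projected onto
the orthogonal complement of the selection span, and the next pick maximizes
the residual norm (ties to the lowest index).  Candidate subsets over all
start columns and chain lengths [Nmin, Nmax] are scored by intercept-plus-OLS
on the calibration set and RMSE on the validation set; rank-deficient
candidates are skipped with a log entry.  Mean-centring before projection is
standard SPA practice (it removes offset dominance).  The Kennard–Stone
algorithm provides the deterministic maximally-spread calibration/validation
split conventionally paired with SPA.  On full-spectrum problems SPA
typically keeps only one or two wavelengths and underperforms the
full-spectrum CNN, so the pipeline treats it as an optional diagnostic stage
(`run_spa`), off by default; no post-selection variable elimination is
implemented.

## The 1D-CNN

Architecture: five valid-padding (no padding) conv layers of 16 filters,
kernel length 3, stride 1, each followed by ReLU; one max-pool (window 2,
stride 2); global average pooling to 16 features; one linear output neuron.
Length bookkeeping at 1024 input channels: 1024 → 1014 → 507 → 16 → 1.
"3 × 3" kernels and "2 × 2" pools in the reference description are read as
length-3 and length-2 — the data is one-dimensional.  Valid padding is the
common framework default and is fixed here as a documented constant.

Training: mean-absolute-error loss, RMSProp (accumulator decay rho = 0.9,
step lr / sqrt(accumulator + epsilon), lr = 0.001, lr decay 0), batch size 5,
shuffled mini-batches.  The reference configuration states a zero fuzzy
factor (epsilon), which would make the first update divide by zero; epsilon
defaults to 1e-7 — a documented deviation.  Weights use seeded He-style
uniform init scaled by fan-in; biases start at zero.  Everything is plain
float64 numpy: convolution is an im2col matrix product and gradients are
derived by hand, verified against central finite differences and, for the
forward operators, against brute-force triple-loop oracles at 1e-12.

The reference epoch budget is 5000 ("paper" profile).  The desk-scale ("test")
profile uses 300 epochs: on desk-scale trials the held-out error plateaus by
then, and longer constant-rate MAE training only adds optimizer wobble (the
sign gradient does not vanish at the optimum, so parameters jitter with step
size ~lr).  An optional validation pair is scored and logged during training
but never influences the fit.

## Evaluation and ranking

R² = 1 − SSres/SStot (can be negative for poor predictors; the occasional
printed claim that it lives in [0, 1] is a typo), RMSE, MAE, and MAPE in
percent.  MAPE errors on any zero truth value.  The train/test split sorts
rows by sample id and takes the leading 75% for training — deterministic with
no random state; a `shuffle_seed` option gives randomized splits for
robustness studies.  A reference flow chart elsewhere describes a 72/9
partition, which conflicts with the stated 75/25; the fraction is
configuration with 0.75 the default.

DTC tables require at least one record per genotype per arm at the filtered
stage.  Clustering is agglomerative with Ward linkage on the Euclidean
distance of the scalar DTC (linkage and distance were genuinely open choices;
Ward on 1-D values reproduces the familiar dendrogram style and is
configurable), cut into k clusters on request; k is exposed because no
canonical cut height exists.  The headline ranking stage defaults to
flowering, where the regression fit is strongest; ranking is by descending
DTC with genotype-id tie-breaks and is derived from the DTC ordering, not
from cluster membership.  Concordance between measured and predicted tables
reports top-k overlap (k = 10 default) and Spearman rho with average-rank
ties.

## Problem sizes and reproducibility

Desk-scale defaults, chosen as this package's test conditions: 256-channel
grids and 300 training epochs; library defaults remain 1024 channels and
5000 epochs.  The end-to-end recovery tests simulate 40 genotypes × 2
treatments × 3 replicates at flowering (240 samples, 180 train / 60 test)
across five recorded seeds and assert Spearman(tau, measured DTC) ≥ 0.8,
Spearman(measured, predicted DTC) ≥ 0.7, and top-10 overlap ≥ 8/10.  One
global seed expands through `numpy.random.SeedSequence` into per-stage seeds
(all < 2³¹); two runs with the same configuration are bit-identical.

## Known limitations

- The CNN is CPU-only, float64, and desk-scale by design; no regularization
  layers, early stopping, or hyperparameter search.
- The generator's spectral model is phenomenological; coefficients are
  plausible, not fitted to any instrument.
- DTC-based ranking uses a single trait; multi-trait tolerance indices
  (membership functions, PCA composites) are out of scope.
- SPA is implemented without the relevance-based elimination step of some
  variants; a flag is reserved.
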