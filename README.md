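# cottonfvfm

Hyperspectral screening of cotton genotypes for drought tolerance.

The chlorophyll-fluorescence parameter Fv/Fm — the maximum photochemical
quantum yield of photosystem II, computed from dark-adapted leaf fluorescence
as

    Fv/Fm = (Fm − Fo) / Fm

— is a sensitive, early indicator of drought stress, but measuring it requires
20–30 minutes of dark adaptation per plant, which rules it out for
high-throughput variety screening.  This package implements the alternative:
predict Fv/Fm directly from leaf hyperspectral reflectance (350–2500 nm) with
a one-dimensional convolutional neural network, then rank genotypes by the
drought tolerance coefficient

    DTC = mean(Fv/Fm under drought) / mean(Fv/Fm under control),

and check that the ranking from *predicted* Fv/Fm reproduces the ranking from
*measured* Fv/Fm.  It is aimed at plant-phenomics and chemometrics researchers
who want the full chain — spectral I/O, preprocessing, wavelength selection,
regression, evaluation, ranking — as tested, reusable parts.

## What is inside

| Module | Purpose |
| --- | --- |
| `spectra_io` | Spectrum/SpectraSet containers, SVC-style ASCII and CSV tables, design matrices |
| `synthetic` | Synthetic multi-genotype drought-trial generator (the test bed for every stage) |
| `preprocess` | Savitzky–Golay smoothing, reference-panel reflectance calibration `Rt = (L/Lr)·Rr`, grid resampling, replicate averaging, reversible z-scoring |
| `spa` | Successive Projections Algorithm wavelength selection + Kennard–Stone splitting |
| `cnn` | The 1D-CNN: 5 conv layers (16 filters, kernel 3) → ReLU → max pool (2/2) → global average pool → linear output; RMSProp/MAE training, hand-derived backprop in numpy |
| `baselines` | Nine classical comparators (CatBoost*, LightGBM, XGBoost, DT, RF, GBDT, AdaBoost, ET, KNN) behind one interface |
| `metrics` | R², RMSE, MAE, MAPE and the deterministic sorted 75/25 split |
| `ranking` | Fv/Fm and water-content formulas, DTC tables, Ward clustering, top-k concordance |
| `pipeline` / `cli` | One-command reproducible runs (`cottonfvfm run`) |

*CatBoost is used when its library is installed; otherwise it is skipped with
a log entry.

The synthetic generator plants a latent drought tolerance `tau` per genotype:
drought reduces Fv/Fm by a stage-specific fraction scaled by `1 − tau`, and
leaf spectra respond with the canonical vegetation features (green peak at
520–580 nm rising under stress, NIR plateau at 760–1250 nm rising with Fv/Fm
and falling under stress, water bands at 1450/1950 nm).  Because the ranking
signal is planted, end-to-end tests can check that the whole screen recovers
it.  See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```sh
cottonfvfm simulate -g 6 --channels 128 -s 3 --out trial.csv --physiology phys.csv
cottonfvfm preprocess --in trial.csv --out clean.csv
cottonfvfm train --in clean.csv --targets phys.csv --epochs 20 -s 1 --out model
cottonfvfm predict --model model --in clean.csv --out pred.csv
cottonfvfm evaluate --pred pred.csv --truth phys.csv --out metrics.json
```

prints

```
wrote 108 spectra to trial.csv and physiology to phys.csv
wrote smoothed spectra to clean.csv
trained on 81; test RMSE 0.00536, MAE 0.00460, MAPE 0.599%, R2 0.948
wrote 108 predictions to pred.csv
{
  "r2": 0.9563854963770723,
  "rmse": 0.006011293499066061,
  "mae": 0.005135861080263799,
  "mape_percent": 0.6619843813299718
}
```

The train step fits the CNN on the sorted 75% of the 108-sample trial (6
genotypes × 2 water treatments × 3 stages × 3 replicates) and reports held-out
error in raw Fv/Fm units: an RMSE of 0.005 against a target spread of roughly
0.76–0.85 means the spectra carry essentially all of the Fv/Fm signal the
generator planted.  The final `evaluate` scores predictions over all samples.
The same flow on measured field tables works by pointing `--in`/`--targets` at
your own CSVs (format in `spectra_io`).

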