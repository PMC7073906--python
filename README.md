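# meatspec

Hyperspectral image chemometrics for quantifying and visualizing the
adulteration of minced pork with minced jowl meat.

Jowl meat (the "sticking-piece") is a cheap cut commonly blended into minced
pork. Because it carries more myoglobin, fat and water than lean pork, its
admixture leaves a measurable imprint on visible/near-infrared (400–1000 nm)
reflectance spectra. `meatspec` implements the full analysis chain used to
exploit that imprint with a push-broom hyperspectral imager:

1. **Reflectance calibration** of raw hypercubes against white/dark
   references: `R_c = (R_o − D)/(W − D) × 100 %`.
2. **ROI masking** by band math — reflectance at 890 nm minus 450 nm,
   thresholded at 0.2 — and extraction of one mean spectrum per sample.
3. **Spectral pretreatments** (normalization, SNV, MSC, SNV+detrend,
   1st/2nd Savitzky–Golay derivatives) as scikit-learn transformers.
4. **PLSR** (NIPALS PLS1) with leave-one-out cross-validation for the
   latent-variable count, scored by `R²`, `RMSE` and the residual
   predictive deviation `RPD = SD(y_ref)/RMSE` (effective model:
   `R² ≥ 0.70`, `RPD ≥ 2.0`).
5. **Wavelength selection** by three routes: extrema of PC loading curves,
   autopeaks of the synchronous two-dimensional correlation spectrum
   (`Φ(ν₁,ν₂) = Σⱼ ỹⱼ(ν₁)ỹⱼ(ν₂)/(m−1)` with adulteration level as the
   perturbation), and regression-coefficient (RC) extrema above a cut-off.
6. **Simplified multispectral PLSR** on the selected bands, the blank-based
   **limit of detection** `LOD = 2·δ_b/S`, and **pixel-wise adulteration
   maps** on a linear black→red 0–100 % color scale, verified against
   control samples with known spatial layouts (100/80/40/20 % quadrants,
   0/50 % halves).

No public hyperspectral meat data exist for this problem, so the package
ships a first-class synthetic generator (`meatspec.phantom`) that emulates
the whole acquisition: disk-shaped "meat phantoms" on a dark background,
two endmember spectra with the known absorption features (411, 543, 570,
759, 842, 975 nm), per-pixel linear mixing at 11 adulteration levels with
16 replicates each (176 cubes, 132/44 calibration/prediction), scatter and
noise terms, and the two control layouts. Every stage of the pipeline is
tested end-to-end against this generator's ground truth.

## Worked example

```python
import meatspec as ms

result = ms.run_phantom_study(seed=1, max_lv=20, selection_pretreatment="snv")
print(result.pretreatment_table.round(4).to_string(index=False))
```

```
 pretreatment  n_lv   r2_c  rmsec  r2_cv  rmsecv   r2_p  rmsep    rpd
         none     2 0.9640 5.9978 0.9620  6.1645 0.9535 6.8225 4.6887
normalization     1 0.9631 6.0730 0.9620  6.1642 0.9534 6.8254 4.6867
          snv     1 0.9635 6.0417 0.9624  6.1321 0.9535 6.8161 4.6931
          msc     1 0.9635 6.0419 0.9624  6.1323 0.9535 6.8172 4.6923
  snv+detrend     1 0.9635 6.0442 0.9624  6.1346 0.9536 6.8143 4.6943
           d1     1 0.9635 6.0381 0.9624  6.1286 0.9539 6.7899 4.7112
           d2     1 0.9636 6.0322 0.9625  6.1228 0.9540 6.7858 4.7140
```

Every pretreatment supports an effective full-spectrum model on the default
phantoms (`R²_p ≈ 0.95`, `RMSEP ≈ 6.8 % w/w`, `RPD ≈ 4.7`): prediction
error is dominated by sample-composition variability, not by scatter, so
the chains differ only marginally — the expected behavior when the
multiplicative distortions they remove are small relative to composition
noise. The simplified multispectral models:

```python
print(result.refit_table[["method", "n_bands", "reduction_pct",
                          "n_lv", "r2_p", "rmsep", "rpd"]].round(4))
```

```
     method  n_bands  reduction_pct  n_lv   r2_p   rmsep    rpd
pc_loadings      100           64.8     1 0.9535  6.8155 4.6934
      2dcos        3           98.9     1 0.3222 26.0339 1.2287
         rc       10           96.5     1 0.9528  6.8679 4.6577
```

The 10 RC-selected bands (a 96.5 % variable reduction) lose almost no
prediction skill, while the 3 two-dimensional-correlation autopeaks are too
few to carry the signal — the characteristic ordering of the three
selection routes. The preferred RC model's detection limit and its
verification on the quadrant control sample:

```python
lod = result.lod
print(f"LOD = 2 x {lod.delta_b:.3f} / {lod.S:.3f} = {lod.lod:.2f} % w/w")
print(result.control_stats["quadrants"].round(2).to_string(index=False))
```

```
LOD = 2 x 1.730 / 0.963 = 3.59 % w/w
 true_level  n_pixels  pred_mean  pred_sd
       20.0       451      21.74     8.30
       40.0       451      39.66     8.82
       80.0       451      78.44     8.96
      100.0       451      99.79     9.00
```

Per-sector map means recover the known 100/80/40/20 % layout to within
~2 points; the per-pixel spread (~9 points) reflects detector noise pushed
through the multispectral model.

## Command line

```sh
meatspec all --config config.yaml --out run/        # full study, all reports
meatspec simulate --config config.yaml --out run/   # write raw ENVI cubes
meatspec calibrate --run-dir run/                   # reflectance calibration
meatspec extract   --run-dir run/                   # ROI masks + spectra.csv
meatspec fit|select|refit|lod|map|report --config config.yaml --out run/
```

The YAML config mirrors `PhantomConfig`/`DesignSpec` plus the modeling
knobs (pretreatments, `max_lv`, PC subset, autopeak count, RC threshold,
RGB composite bands, master seed); a run is fully reproducible from
(config, seed), and every report carries the config hash.

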