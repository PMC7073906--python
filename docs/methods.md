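# Methods

This note records the models implemented in `meatspec`, the assumptions
behind the synthetic meat phantoms, the defaults that matter, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement model

A push-broom visible/near-infrared imager records a hypercube of raw counts
over 400–1000 nm (284 bands by default). Relative reflectance is obtained
per pixel and band as

    R_c = (R_o − D) / (W − D) × 100 %

where `W` and `D` are white (~99.9 % target) and dark (~0 %) reference
cubes. The references are spatially averaged to one spectrum each before
the division: the per-pixel alternative mainly injects reference noise, and
averaging is the common practice. Bands where the averaged white does not
exceed the averaged dark raise an error naming the band. Reflectance
outside [0, 110] % is clipped and the clipped fraction logged.

The sample region (ROI) is found by band math: the image at 450 nm (low
reflectance for meat) subtracted from the image at 890 nm (high), then
thresholded. The threshold, 0.2 by default, is interpreted on the
fractional 0–1 reflectance scale (i.e. 20 percentage points); whether the
original procedure meant the percent or fractional scale is ambiguous, so
the value is a config knob, not a fact. Requested wavelengths map to the
nearest band, ties toward the lower index. No morphological cleanup is
applied by default; removal of small connected components is available
behind a flag. One mean spectrum per sample, averaged over the ROI,
represents that sample.

## Pretreatments

All chains operate row-wise on the (samples × bands) matrix:

| name | transform |
|---|---|
| `none` | identity |
| `normalization` | unit Euclidean norm (`area`/`max` modes available) |
| `snv` | per-spectrum centering and scaling (n−1 SD) |
| `msc` | affine regression on a reference spectrum, `(x−a)/b` |
| `snv+detrend` | SNV then removal of an order-2 polynomial in band index |
| `d1`, `d2` | Savitzky–Golay derivatives, window 15, fitting order 2 |

Choices made where the source procedure is underspecified: "normalization"
defaults to the unit-vector variant; the detrend order is 2 (targeting
curvilinearity); the SD denominator is n−1 throughout. Savitzky–Golay
derivatives are computed on the window interior; the 7 edge bands on each
side are filled with the nearest interior value — with 284 bands and a
15-point window this touches ~5 % of bands and none of the selected
wavelengths in practice, but it does mean first derivatives of curved
spectra are exact only on the interior.

No pretreatment statistic leaks across the calibration/prediction split:
the MSC reference is the column mean of the calibration rows and is frozen
for prediction rows. Inside leave-one-out cross-validation the chains are
applied once to the calibration set before the loop (the reference is a
133-sample-scale mean; refitting it per fold changes it by O(1/n) and
would couple fold models to each other's rows anyway through the shared
reference — the frozen-reference convention keeps the CV consistent with
how prediction rows are treated).

## PLSR and model selection

PLS1 via NIPALS with mean centering only (no autoscaling — the bands share
units). Per component: weight `w ∝ Xᵀy`, score `t = Xw`, loadings
`p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, then deflation of X and y. Because `PᵀW` is
unit upper triangular, one fit at `A` components yields the coefficient
vector of every nested truncation (`coef_path_`), which makes LOOCV cost
one fit per fold instead of one per fold per component count.

The LV count minimizes RMSECV under leave-one-out CV over the calibration
set only; ties go to the fewest LVs; an infeasible `max_lv` (default 20) is
clipped with a warning. Metrics follow the standard definitions:
`R² = 1 − SS_res/SS_tot`, `RMSE = √MSE`, `RPD = SD(y_ref, n−1)/RMSE` with
the evaluated set's own reference SD (the RPD formula is a convention
choice; the n−1 prediction-set SD is used here).

The estimator follows the scikit-learn contract and is cross-checked in
the tests against ordinary least squares (full-rank and single-band limits)
and against an independent PLS implementation.

## Wavelength selection

* **PC loadings** — PCA of the pretreated spectra of all samples; bands at
  peaks/valleys of the loading curves of PCs {1, 3} (configurable) with
  prominence above 10 % of that loading's range, deduplicated within one
  band. The 10 %-of-range default is a judgment call: no quantitative
  criterion for "pronounced" extrema exists in the source procedure.
* **2D-COS** — generalized two-dimensional correlation spectroscopy with
  adulteration level as the perturbation, applied to the per-level average
  spectra. The synchronous spectrum uses Noda's convention: dynamic
  spectra about the across-level mean, `Φ = ỸᵀỸ/(m−1)`; its diagonal is
  the per-band variance across levels. Autopeaks are local maxima of the
  diagonal, top-3 by default. Only the synchronous spectrum is computed.
* **RC** — local extrema of the regression-coefficient curve of the fitted
  full-spectrum model with |coefficient| above a cut-off (default 5). The
  fixed cut-off is only meaningful for a particular coefficient scale, so a
  scale-free alternative — the top-k extrema by absolute coefficient,
  default k = 10 — is provided and used by the phantom pipeline, whose
  coefficient scale differs from real-meat calibrations.

Variable-reduction bookkeeping reports `100·(B−s)/B` rounded to one
decimal: 284→10 bands is 96.5 %, 284→3 is 98.9 %.

## Simplified models, LOD, maps

Simplified "multispectral" PLSR models restrict the spectra to a selected
band set and rerun the full fit/LOOCV/evaluation cycle, so their report
rows are directly comparable to the full-spectrum ones. By default the
pretreatment is applied to the reduced spectra (what a filter-based
multispectral instrument would observe); pretreating the full spectra
before restriction is available as `pretreat_on="full"`.

The pipeline carries the RC model into the LOD and visualization stages by
default (configurable): it is the one selection route that uses both the
spectra and the reference levels, and the natural basis for a reduced-band
instrument.

Limit of detection uses the blank-based two-sigma convention
`LOD = 2·δ_b/S`: `δ_b` is the n−1 SD of the model's predictions on blank
(0 % adulteration) samples; `S` is the slope of predicted-vs-reference on
the calibration set. Blanks default to the independent prediction set;
calibration-set blanks are an option. "Background response" is read as
predictions on pure-pork samples — the conventional blank — since no more
operational definition is given in the source. LOD is invariant to a
constant bias in the blank predictions, and in the phantom's noise-free
limit it is exactly 0.

Distribution maps push every ROI pixel through the same pretreatment chain
and band subset as the model, on the percent-reflectance scale.
Predictions outside [0, 100] % are preserved in the data layer (their
fraction logged) and clipped only for display. The color scale is a linear
black → yellow → red map over 0–100 % with a color bar, chosen so that a
0/50 % control sample renders as a black and a yellow half. False-color
composites take the bands nearest 700.9/545.4/436.4 nm as R/G/B with a
1st–99th percentile stretch per channel.

## The phantom generator

The generator's defaults are the study conditions; they are not tuned per
experiment.

**Geometry.** A disk (radius 24 px in a 64×64 frame) of meat on a flat
dark background (reflectance 0.03, so the 890−450 nm difference stays well
below the 0.2 mask threshold).

**Endmembers.** Pure pork and pure jowl reflectance are a smooth sigmoid
baseline (≈0.17→0.59 over 400–1000 nm) minus Gaussian dips at 411 nm
(Soret band of haemoglobin), 543/570 nm (deoxy-/oxymyoglobin), 759 and
975 nm (third and second O–H water overtones) and 842 nm (aliphatic C–H).
Jowl sits at 92 % of the pork baseline with 1.3–1.8× deeper dips,
reflecting its higher myoglobin, water and fat content; pork therefore has
the slightly higher reflective intensity everywhere. Dip depths and widths
are perturbed ±10 % by the seed. The exact curve shapes are free
inventions (only their qualitative features are constrained); the contrast
magnitude was chosen so that full-spectrum PLSR on the default design
lands in the RPD ≈ 4–5 regime of an effective calibration.

**Per-pixel model.** `r(λ) = g·[(1−c)·pork(λ) + c·jowl(λ)] + b + ε` with
jowl fraction `c`, per-pixel gain `g ~ N(1, 0.05)` constant across bands
(exactly the distortion SNV/MSC remove, which keeps the pretreatment
comparison meaningful), offset `b ~ N(0, 0.01)`, and band noise
`ε ~ N(0, 0.004)` (fractional reflectance units, ~0.4 % of full scale —
a plausible figure for a 12-bit camera).

**Concentration noise.** Two terms, both in % w/w: within-sample spatial
jitter of `c` with SD 2 (a "roughly homogeneous paste" is not perfectly
homogeneous), and a between-sample composition error with SD 7 — each
sample's realized mean level is its nominal level plus this error, clipped
to [0, 100]. The second term is the generator's one load-bearing free
parameter: sample preparation, weighing and reference-method error in real
studies put several percent of irreducible spread between the nominal level
and what the spectra actually see, and SD 7 reproduces the reported
calibration regime (RMSEP ≈ 7 % w/w, RPD ≈ 4.5) rather than the
implausible near-zero error a noiseless mixing model would give. Both
terms belong to the "noise" family: scaling them to zero together with the
optical noise drives prediction error — and hence the LOD — to zero.

**Design.** 11 levels (0–100 % in 10 % steps) × 16 replicates = 176
samples; 12 per level to calibration (132), 4 to prediction (44), assigned
at random under the seed, stratified by level. Control samples: four
fan-shaped quadrants at 100/80/40/20 % and two semicircles at 0/50 %.
Control cubes carry the optical noise terms but no concentration noise —
their purpose is verifying the mapping stage against an exactly known
layout, so their truth maps hold the exact nominal values.

**Raw-count synthesis.** To exercise the calibration stage end-to-end, the
inverse of the reflectance equation converts a reflectance cube to counts
under a tungsten-halogen-shaped white reference (~3600 counts peak, dark
~120, reference noise SD 8).

**What the phantoms do not model.** Radiative transfer, specular
highlights, Petri-dish edge effects, spatially correlated texture,
wavelength-dependent scatter (the gain is flat across bands), camera
nonlinearity, or the biochemistry of specific tissues. Consequently,
passing tests demonstrate that the chain of algorithms is implemented
correctly and behaves as expected when its statistical assumptions hold —
not that any particular accuracy would be achieved on real meat. One
visible artifact of this simplicity: because a single mixing factor plus
flat scatter drives the spectra, LOOCV typically selects 1–2 latent
variables on phantoms, versus ~12–14 on real meat spectra whose chemistry
is higher-rank; and the per-level spectral differences after SNV are so
collinear that all pretreatment chains perform nearly identically.

## Numerical choices and degenerate inputs

* Reflectance is stored on the 0–100 % scale; the mask threshold on the
  0–1 scale; pixel predictions in % w/w.
* SNV/normalization reject zero-variance/zero-norm rows naming the sample;
  MSC rejects a constant reference or a zero slope.
* PLSR rejects constant responses, `n_components` beyond
  `min(n−1, bands)`, and stops early (with a warning) when a component
  extracts no covariance; LOOCV clips an infeasible `max_lv` with a
  warning; RMSECV ties resolve to the fewest LVs.
* Wavelength selectors return empty sets with a warning rather than
  failing when no extremum qualifies; empty sets are rejected at refit.
* An empty ROI (degenerate disk radius) warns at simulation and errors at
  spectrum extraction.
* PCA loading signs are fixed (largest-magnitude element positive) so
  selections are reproducible across BLAS implementations.
* All randomness flows from explicit integer seeds; a study derives its
  stage seeds deterministically from one master seed, so any stage can be
  re-run in isolation bit-identically.

## Problem sizes

Default study: 176 cubes of 64×64×284 (float64 in memory, generated
lazily and reduced to mean spectra one at a time), LOOCV over 132 samples
with up to 20 LVs, pixel maps over ~1800 ROI pixels per control sample.
The whole study runs in well under a minute on one CPU; the test suite
uses smaller frames (24–48 px) and reduced replication except where a
check is explicitly about the default conditions. With small calibration
sets (tens of samples) LOOCV occasionally admits an extra latent variable
whose small-variance direction carries large coefficients and amplifies
per-pixel noise in maps; at the default 132-sample calibration the
selected models are stable. This variance-amplification trade-off is
inherent to applying mean-spectrum-validated PLSR to single noisy pixels.

## Known limitations

* Only the synchronous 2D-COS spectrum is implemented (no asynchronous
  spectrum), matching its use for autopeak selection.
* The PC-loadings selector can return many bands on phantoms whose PC3 is
  noise-dominated; the prominence default is a heuristic, not a guarantee
  of a small set.
* The fixed RC cut-off of 5 presumes a particular coefficient scale;
  on other data use the top-k rule or adjust the threshold.
* ENVI support covers the dialect the package writes (BIL/BIP/BSQ,
  int16/int32/uint16/float32/float64, single text header) — not every
  header variant in the wild.
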