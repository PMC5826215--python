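# Methods

## Scope and model of the data

`lignotrack` analyses two kinds of time-lapse observations of enzymatic
lignocellulose degradation:

1. two-channel deep-UV autofluorescence image stacks (enzyme channel
   327–353 nm, cell-wall channel 420–480 nm; 16-bit counts; frames every
   6 min over roughly an hour);
2. per-point FT-IR absorbance series on a shared wavenumber axis
   (4000–800 cm⁻¹, 8 cm⁻¹ steps), where the 1180–950 cm⁻¹ region carries the
   polysaccharide fingerprint and 1800–1550 cm⁻¹ is unusable under an
   aqueous background.

Both branches assume fluorescence intensity is proportional to local enzyme
amount (the sections are deproteinised, so only added enzyme fluoresces in
the 327–353 nm channel) and absorbance is linear in polymer concentration
(Beer–Lambert; no scattering correction is attempted).

## Fluorescence branch

**Shading correction.** `IMC = (IM − BKG)/ILL`. BKG may be a scalar or a
dark-frame image; ILL is a strictly positive field normalised to mean 1
(scalar broadcasts are accepted unnormalised, e.g. in unit conversions).
Negative corrected values are floored at zero — counts are non-negative.

**Illumination estimation.** Gaussian attenuation of the 2-D Fourier
spectrum with `cutoff_sigma` in cycles per image (default 2.0), inverse
transform, clipping to a small positive floor, rescaling to mean 1. The
default keeps vignette-scale structure while rejecting the cell-lattice
frequencies; it is estimated from the first enzyme frame, which is least
affected by degradation. Lower cutoffs distort the vignette itself, higher
ones leak tissue structure into the field.

**Regions and kinetics.** Regions are boolean pixel masks tagged by
cell-type code and a cavity flag, drawn manually in practice and derived
from generator ground truth in tests (a few lattice cells per code,
mirroring the 2–5 regions per type of a real analysis). Polygon regions are
rasterized half-open — a pixel belongs to a polygon iff its center
(row + 0.5, col + 0.5) is inside — so polygons sharing an edge tile the
image without overlap, and region means are bit-reproducible. The region statistic
is the arithmetic mean; coordinates are 0-based (row, col). Kinetic curves
are normalised by the per-experiment free-enzyme (cavity) intensity so that
a pure-solution region sits at 1. `enhance_deviation` magnifies variations
from the initial value (default ×10) for display of shallow cavity curves;
it is never used in quantitative paths.

**Statistics.** `group_stats` reports per-type means of region means with
SE = SD/√n over regions (n = 1 reported as SE 0 and flagged). `anova` fits a
fixed-effects main-effects linear model with type-II sums of squares
(statsmodels OLS/anova_lm) over any subset of cell type, time and experiment,
all categorical; no interactions — the minimal model for the stated factors.

## FT-IR branch

The fixed preprocessing order is smooth → crop 1550–950 → anchored baseline
→ crop 1180–950 → normalise.

* **Smoothing**: centred moving average over 5 spectral points, window
  shrinking at the edges; a quadratic Savitzky–Golay option is exposed but
  not default (the plain average is the conservative reading of a "size-5
  smoothing").
* **Baseline**: piecewise-linear through anchors a priori at 950, 1180,
  1550 cm⁻¹. Each anchor moves to the nearest local minimum (sample strictly
  lower than both neighbours) within ±24 cm⁻¹ (three resolution steps);
  ties break toward the lower wavenumber; with no local minimum the nearest
  sample to the a priori anchor is kept. A `global_min` mode is available.
  The corrected spectrum is exactly zero at every adjusted anchor. Anchors
  may fall up to one search radius outside a grid-cropped axis (e.g. nominal
  950 on a 952-first grid) and snap to the nearest sample; anchors farther
  outside raise an error.
* **Normalisation**: unit absolute trapezoidal area on the current window
  (static, enzyme-free spectra), or division of a whole series by the
  maximum of its t = 0 spectrum (degradation series). The area window is
  whichever window is active at call time and is recorded by the caller.
* **Window guard**: analysis windows intersecting the open interval
  1550–1800 cm⁻¹ are refused unless forced.

**Kinetics.** `sum_absorbance` totals the window per time point.
`fit_decay` regresses log A on t by weighted least squares with weights
∝ A² — the delta-method variance of log A under additive noise of constant
magnitude — and excludes points below 20 % of the initial value: near the
noise/baseline floor the logarithm is biased low-signal noise, so the fit
uses the upper portion of the decay. Rates for a condition are best
estimated by averaging fits over replicate measurement points (experiments
typically acquire ~4 points). `linear_trend` gives the raw OLS slope and
95 % CI for no-trend checks on recalcitrant series.

**Differences.** `difference_spectrum` returns spectrum(0) − spectrum(t),
matching the requested time within half the median acquisition interval.
`aggregate_differences` area-normalises each difference and sums pointwise;
the pipeline runner includes only points whose lost area exceeds 5 % of the
initial area — a near-zero difference from an undegraded wall has no
meaningful area normalisation.

## Chemometrics

PCA is mean-centred only (no unit-variance scaling — the chemometrics
convention for absorbance/intensity data, keeping loadings interpretable as
spectra), computed by SVD; variance fractions are percentages of the total
centred variance; each loading's largest-magnitude element is made positive
so signs are deterministic. Kinetic curves on different acquisition grids
are linearly interpolated onto the coarsest grid over the common time range.
Spectral grouping is k-means (scikit-learn, 50 restarts, fixed seed) on the
first two PCA scores, with group ids renumbered by mean PC1 so labels are
deterministic; user labels bypass clustering. An automated surrogate was
chosen for what is visual grouping in practice.

## Synthetic generator

Scenes are rectangular lattices of cells (default 24 px cells, 3 px walls at
a ~1 µm pixel) — reproducible, parameterisable ground truth rather than
plant anatomy. Per cell type: wall survival s(t) = 1 up to a lag then
exponential; enzyme on walls
`affinity·S·(1 − e^(−b·t))·s(t) + S·(1 − s(t))` (S = solution counts), so
degradable walls overshoot the solution level and relax back to it as the
wall disappears while lignified walls stay dark; cavities carry
`S − (wall/cavity pixel ratio)·bound`, a per-cell mass balance that dips
during binding and recovers after degradation (no diffusion PDE). Frames are
`clip_round_16bit(ILL·signal + BKG + noise)` with a mean-1 Gaussian vignette,
constant background and Poisson noise on the expected counts plus optional
additive Gaussian — a photon-counting camera model. Default conditions
follow the study system: solution 50 counts (75 for a second experiment),
degradable-wall affinity ≈ 1.9 (the ~95 vs ~50-count contrast), phloem /
xylem-parenchyma ≈ 1.2, recalcitrant types (ppi, scl, xyl) zero, background
20 counts, 12 frames at 6 min, seed 7. Optional linear drift is not modelled;
bleaching and focus drift are out of scope.

Spectra are sums of Gaussian bands (SD 12 cm⁻¹, ≈28 cm⁻¹ FWHM at the 8 cm⁻¹
instrument resolution) per polymer with exponential pool decay; default
rates 0.06 /min (xylan), 0.02 /min (cellulose), 0 (lignin esters) encode
hemicellulose degrading three times faster than cellulose; recalcitrant
codes decay at 0 regardless. Optional linear + sinusoidal baseline drift and
white noise (default SD 0.005 absorbance against ~1 peak absorbance; 0.02 is
used as the stressed condition in rate-recovery checks). Default seed 11.

What the generator does **not** emulate: real plant morphology, enzyme
diffusion, scattering/saturation artefacts, water-vapour bands, sample
drift, detector nonlinearity. Passing tests therefore demonstrate the
correctness and calibration of the operators under the stated statistical
model, not robustness to those artefacts.

## Numerical choices and degenerate inputs

* Pixel values clip (never wrap) into [0, 65535] before uint16 cast.
* Wavenumber axes are canonicalised ascending in memory and written
  descending on disk (FT-IR convention); all cm⁻¹ bounds are inclusive.
* Noisy-recovery checks on region means use pixels with expected signal
  ≥ 30 counts (the solution scale): below that, Poisson shot noise dominates
  any estimator at realistic region sizes.
* PCA of a rank-deficient or constant matrix returns zero scores/fractions
  rather than failing; at most `n_obs − 1` components are meaningful.
* Empty regions, all-zero illumination frames, non-positive normalisation
  factors, single-level ANOVA factors, mismatched axes and absent time
  points all raise `ValueError` naming the offending input.

## Problem sizes

Test and acceptance runs use 120×120 px scenes (480×480 for the noisy
recovery check), 12 frames, 11-point spectral series, 100-spectrum baseline
oracles, and 1000/400 replicates for ANOVA calibration/power — sizes chosen
so the full suite runs in well under a minute per module on a laptop while
keeping Monte-Carlo margins comfortable.

## Known limitations

* The nearest-minimum anchor rule is slightly biased toward noise minima on
  low-SNR spectra; the decay-fit floor (20 % of initial) and replicate
  averaging mitigate the resulting flattening of log-kinetics.
* ANOVA assumes independent region means; temporal autocorrelation within a
  region's curve is ignored (as in the factorial analysis it mirrors).
* The JCAMP-DX reader handles uncompressed AFFN `(X++(Y..Y))` data only.
* `pca_kinetics` resampling interpolates linearly and refuses
  non-overlapping time ranges rather than extrapolating.
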