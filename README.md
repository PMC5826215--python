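# lignotrack

Label-free time-lapse analysis of lignocellulosic biomass hydrolysis.

When plant stem sections are degraded by cellulolytic enzymes under a deep-UV
fluorescence microscope and a microfluidic FT-IR microspectroscope, two data
streams arise without any staining or labelling:

* **two-channel autofluorescence image stacks** — protein autofluorescence
  (327–353 nm emission) images the enzymes themselves, phenolic
  autofluorescence (420–480 nm) images the cell walls — acquired every 6 min
  on 65536 gray levels;
* **time-lapse absorbance spectra** (4000–800 cm⁻¹ at 8 cm⁻¹ resolution) at
  selected points on cell walls, whose 1180–950 cm⁻¹ "sugar fingerprint"
  tracks the polysaccharides as they are hydrolysed.

`lignotrack` is for researchers quantifying which cell types bind enzymes,
how fast each wall type is degraded, and which polymer pools (hemicellulose
vs cellulose) go first. It implements both analysis branches end to end and
ships a synthetic-data generator that emulates the imagery and spectra with
full ground truth, so every operator is testable without a beamline.

## Core methods

**Flat-field (shading) correction.** Every raw frame IM is corrected as

    IMC = (IM − BKG) / ILL

where BKG is the additive dark background and ILL the multiplicative
illumination inhomogeneity, estimated from the enzyme image by Gaussian
low-pass filtering of its Fourier transform and normalised to mean 1.

**Region kinetics.** Mean corrected intensity per labelled region (cell-wall
or cell-cavity) per time point; curves are normalised by the free-enzyme
(cavity) intensity of their experiment so different enzyme loads are
comparable, and compared by mean-centered PCA and fixed-effects ANOVA
(type-II sums of squares; cell type, time, experiment as factors).

**FT-IR preprocessing.** 5-point smoothing → selection of 1550–950 cm⁻¹ →
piecewise-linear baseline through anchors a priori at 950, 1180 and
1550 cm⁻¹, each moved to the nearest local minimum → restriction to
1180–950 cm⁻¹ → unit-area normalisation (static spectra) or division by the
maximum of the t = 0 spectrum (time-lapse series). Degradation kinetics are
the summed absorbance over the window, with decay rates k from weighted
log-linear fits to A(t) ≈ A₀·e^(−kt); composition changes are difference
spectra (initial − degraded), area-normalised and summed across degraded
walls.

**Synthetic generator.** Scenes are rectangular cell lattices with per-type
wall survival s(t) = 1 for t ≤ lag, e^(−rate·(t−lag)) after, enzyme binding
at affinity·solution·(1 − e^(−b·t))·s(t), a Gaussian vignette, dark
background and Poisson (photon-counting) noise. Spectra are sums of Gaussian
band sets for cellulose (1035/1053 cm⁻¹), xylan (1045/1070/1000/980 cm⁻¹)
and lignin esters (1510/1250 cm⁻¹) with per-polymer exponential decay —
xylan three times faster than cellulose by default, lignin inert.

## Worked example

```python
import lignotrack as lt
from lignotrack import fluorescence as fl, chemometrics as cm, ftir

# --- fluorescence branch on a synthetic degradation scene -----------------
stack, truth = lt.generate_scene(lt.SceneConfig(seed=7))
ill = fl.estimate_illumination(fl.FluorescenceFrame(stack.enzyme[0].astype(float)))
model = fl.IlluminationModel(background=truth.background_image, illumination=ill)
corrected = fl.correct_stack(stack, model, channels=("enzyme",))
table = fl.measure_regions(corrected["enzyme"], fl.regions_from_truth(truth))

print(cm.group_stats(table, at_time=18.0).round(1).to_string(index=False))
res = cm.pca_kinetics(fl.normalize_kinetics(table, 50.0), n_components=2)
print(res.summary())
```

prints (abridged) the per-cell-type intensities 18 min into the reaction and
the kinetic PCA:

```
cell_type_code  mean_intensity  standard_error  n
           pri            69.2             4.5  4
           pnv            63.1             2.5  4
           ppi             2.3             0.1  4
           scl             2.1             0.1  4
          ipri            34.1             1.7  4
...
Principal component analysis
  observations: 50, variables: 12
  PC1:  87.19% of total variance
  PC2:  11.00% of total variance
```

Degradable parenchyma walls (`pri`, `pnv`) carry strong enzyme fluorescence,
lignified walls (`ppi`, `scl`, `xyl`) essentially none, and cavities (`i…`)
sit near the free-solution level (here 50 counts, dipping while enzyme is
bound on the walls). PC1 of the normalised curves separates degradable,
intermediate and recalcitrant cell types.

```python
# --- FT-IR branch: decay rate of one measurement point --------------------
series, rates = lt.generate_spectral_series(
    lt.SpectraConfig(noise_sd=0.005, seed=11), lt.default_band_library())
proc, audits = ftir.preprocess_series(series["pri"])
curve = ftir.sum_absorbance(proc)
print(ftir.fit_decay(curve["time_min"], curve["total_absorbance"]).summary())
```

```
Exponential decay fit (n=10)
  rate      0.02976 /min (SE 0.00065)
  95% CI    [0.02826, 0.03127] /min
  R^2       0.99616
```

The fitted 0.030/min sits between the cellulose (0.02/min) and xylan
(0.06/min) pool rates of this wall's mixed composition, as expected for a
summed-absorbance curve.

A CLI wraps the same pipelines:

```sh
lignotrack simulate-scene --out run1          # stack + regions + ground truth
lignotrack fluor --stack run1/stack --regions run1/regions --out run1/analysis
lignotrack ftir run1/spectra/*.csv --out run1/ftir
lignotrack movie --stack run1/stack --out run1/movie.gif
```

Every run writes a `manifest.json` (inputs, parameters, seeds, checksums)
sufficient to reproduce it exactly.

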