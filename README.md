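# octaquant

Semi-automated quantification of retinal microvasculature in en-face OCTA
(optical coherence tomography angiography) angiograms, for retina
researchers who need device-independent capillary metrics from 3 × 3 mm
macular scans — for example when following eyes after macula-off retinal
detachment repair, where the superficial (SCP) and deep (DCP) capillary
plexuses change subtly over months.

## What it computes

The working representation is an 8-bit en-face image, nominally 586 × 585
px over 3 × 3 mm (1 px ≈ 5.13 × 5.13 µm). The pipeline:

1. **Three-way binarization.** A pixel is vessel when it passes the
   multiscale Hessian **vesselness** filter *and* at least one intensity
   test — a global Otsu threshold or an adaptive local-mean threshold:
   `V = H ∩ (G ∪ A)`. The vesselness response at scale σ uses the Hessian
   eigenvalues λ₁, λ₂ (|λ₁| ≤ |λ₂|, scale-normalized by σ²):

       v = exp(−R_B² / 2β²) · (1 − exp(−S² / 2c²)),   R_B = λ₁/λ₂,  S = √(λ₁²+λ₂²)

   zeroed where λ₂ ≥ 0 (bright-tube sign test), maximized over
   σ ∈ {1, 1.5, 2, 2.5, 3} px.
2. **Skeletonization.** Iterative boundary-removal thinning peels the
   vessel map to unit-width, connectivity-preserving centerlines.
3. **Metrics**, per ETDRS region (foveal 1 mm disc, parafoveal 1–3 mm
   annulus, whole scan):
   - **VAD** (vessel area density) = vessel px / ROI px — perfused fraction;
   - **VSD** (vessel skeleton density) = skeleton px / ROI px — total
     vessel length, independent of caliber;
   - **VDI** (vessel diameter index) = vessel px / skeleton px — mean
     vascular caliber, reported in px and µm;
   - **FAZ area** (mm²) by the shoelace formula from a manually traced
     foveal avascular zone contour.

A synthetic-vasculature generator grows branching capillary trees with
exact ground truth (centerline length, caliber, avascular disc) and renders
them with illumination shading and speckle-like noise, so every metric is
testable without patient data. A cohort module adds the longitudinal
statistics used in paired-eye studies: Mann–Whitney U, repeated-measures
ANOVA, chi-square/Fisher, Spearman correlation, and univariate + backward
multivariate logistic regression for predictors of functional success
(BCVA improvement ≥ 0.3 logMAR).

## Worked example

`python examples/quantify_scene.py` generates a synthetic scan, quantifies
it, and prints:

```
VAD  measured 0.323   true 0.353   (fraction of the scan showing perfusion)
VSD  measured 0.072   true 0.060   (skeleton-pixel fraction: vessel length, caliber-independent)
VDI  measured 4.51 px = 23.1 um   true mean caliber 5.89 px
A VAD near 0.35-0.43 and VDI near 19 um match healthy macular plexuses.
```

Measured VAD sits within 0.03 of the generator's truth under the default
noisy, shaded rendering; VSD and VDI carry the expected thinning and blur
biases, both bounded in the test suite. `examples/faz_measurement.py` and
`examples/cohort_analysis.py` walk the FAZ and statistics layers the same
way.

From a shell, the same pipeline runs on real image files:

```sh
octaquant quantify --image scan.png --meta scan.json --out metrics.csv
octaquant binarize --image scan.png --meta scan.json --out mask.png
octaquant simulate --seed 7 --out scene.png --truth truth.json
octaquant cohort  --records records.csv --out report/
```

`scan.json` supplies the scan extent in mm, the plexus label (SCP/DCP) and
the device quality score; scans scoring below 45 should be excluded
(`octaquant.quality_filter`).

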