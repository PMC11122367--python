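# Methods

## Working representation and scan geometry

All processing happens on an 8-bit single-channel en-face angiogram with
known physical extent. The nominal macular protocol is a 3 × 3 mm
fovea-centered scan sampled at 586 × 585 px, i.e. about 5.13 µm per pixel.
Because the two axes differ by one pixel over the same 3 mm, pitches are
kept per-axis (5.12 µm rows, 5.13 µm columns) and a geometric-mean pitch is
used wherever a single number is needed (µm-scaled VDI, px→mm contour
conversion). Raw deeper-bit-depth exports are rescaled linearly
(min–max to [0, 255], half-up rounding); a constant image has no dynamic
range and maps to zero by convention. Scans with a device quality index
below 45 (on the 0–100 scale) are excluded, as is standard for this
instrument class; records without a score are excluded with a logged
reason rather than silently kept.

Regions of interest follow the ETDRS convention: a 1 mm-diameter foveal
disc, a 1–3 mm parafoveal annulus, and the whole scan. The specific
diameters are a design choice — the field convention — since region names
alone do not fix them. The fovea is taken at the image center (scans are
fovea-centered), with an explicit override for decentered acquisitions.
Distances are measured from pixel centers with per-axis mm pitches, so
regions stay circular on slightly anisotropic grids. A region falling
outside a small field of view yields a flagged row, not a silent zero.

## Three-way binarization

The vessel map combines three detectors with complementary failure modes:

* **Global threshold** (default Otsu on the 8-bit histogram): optimal when
  the intensity histogram is bimodal, blind to illumination drift.
* **Hessian vesselness**: the 2D tubularity filter with blob suppression
  β = 0.5, structureness cut-off c = "auto" (half the maximum Hessian
  Frobenius norm at each scale), scales σ ∈ {1, 1.5, 2, 2.5, 3} px —
  covering capillary calibers of roughly 5–40 µm at the 5.13 µm pitch.
  Scale normalization multiplies Hessian eigenvalues by σ²; the bright-tube
  sign test zeroes the response where λ₂ ≥ 0. The per-pixel maximum over
  scales is rescaled to [0, 1]. Derivatives use reflective boundary
  handling; zero padding would fabricate edge ridges.
* **Adaptive local-mean threshold**: window 51 px (~260 µm), offset 0,
  reflective padding; keeps vessels visible where the background level
  drifts across the scan.

Default fusion is `vesselness ∩ (global ∪ adaptive)`: the vesselness
response gates on shape, the thresholds on intensity. Majority-2-of-3,
intersection and union are selectable, and the rule plus all parameters are
recorded in the output provenance, because the combination is an
engineering choice, not a published constant.

The vesselness gate threshold defaults to a fixed 0.02 on the normalized
response. The response distribution is extremely right-skewed (background
≈ 0, tubes ≫ 0), so a small fixed cut separates the two; data-driven
Otsu-on-nonzero-response is selectable but sits far up the tube lobe and
discards vessel interiors, which measurably degrades overlap with ground
truth on synthetic trees. The fixed default was tuned, together with the
other binarization defaults, to the package's own goal of Dice ≥ 0.9
against synthetic ground truth on clean scenes.

## Skeletonization and metrics

The vessel map is thinned by iterative boundary removal until every vessel
is one pixel wide (Guo–Hall thinning). This variant was chosen over the
classic two-subiteration alternative because it never leaves a fully-set
2 × 2 block — the unit-width property the metrics rely on — while
preserving 8-connected component counts. The algorithm name is recorded in
provenance.

* VAD = vessel px / ROI px.
* VSD = skeleton px / ROI px. Skeleton length is a *pixel count*, not a
  Euclidean polyline length with √2 diagonal steps, matching how skeleton
  density is defined in the quantification literature this follows; pixel
  counting is also what makes VAD/VSD/VDI mutually consistent
  (VDI = VAD/VSD within an ROI).
* VDI = vessel px / skeleton px, the area-per-unit-length mean caliber; in
  µm it is VDI·pitch. Cohort-scale values near 19 are consistent with µm
  (≈3.7 px), so µm is the default reporting unit; the px value is always
  reported alongside. An ROI with no skeleton raises an error rather than
  reporting 0 — a silent 0 would bias cohort means.
* FAZ area: absolute shoelace area of the traced polygon (closing edge
  implied, orientation-free). Self-intersecting outlines are rejected.
  Contours may come in mm or in px with a stated pitch.

## Synthetic scenes and what they do (not) show

The generator grows random-walk-with-momentum vessel trees from border and
interior seeds, branching at ~0.02/px (scaled down for thicker vessels, as
in real vascular trees), curving with 0.15 rad/step jitter, and stopping at
the rim of a central avascular disc (default radius 0.276 mm, area
≈ 0.24 mm², a typical FAZ). Walkers steer around, and keep a ≥3 px
clearance from, existing vessels, so distinct tubes never fuse after
blurring — capillary meshes anastomose rather than overlap. Branches launch
from the parent's edge so child centerlines do not run inside the parent
tube. Growth stops when the true vessel-area fraction reaches its target
(default 0.4, the healthy-macula scale). Tiny 1–2 px background pinholes
left by unioning per-segment discs are filled: real vessels are solid, and
such pinholes are topological obstructions no thinning can reduce to unit
width.

Rendering: per-segment intensity (uniform 100–230 on a background of 80),
σ = 0.5 px Gaussian anti-aliasing of tube edges, a linear illumination
falloff of up to 35% across the scan in a random direction (vignetting),
and additive Gaussian noise (σ = 12) or multiplicative speckle. One seeded
generator stream drives layout and rendering, so a seed fully determines
the scene bit-for-bit.

Ground truth reports the rasterized vessel mask, the Bresenham centerline
count, and two mean calibers: area/length (the VDI analog; the default) and
the area-weighted mean (wider vessels weighted more); tests pin both
definitions.

These scenes establish that the pipeline recovers known geometry under
controlled degradation. They do not model OCT speckle statistics, flow
signal dropout, projection artifacts, segmentation errors between plexuses,
or motion — so passing tests bound algorithmic error, not device error, and
absolute values on real scans still depend on acquisition quality.

## Cohort statistics

Functional success is a BCVA improvement (pre − post in logMAR; lower is
better, so positive = improvement) of at least 0.3 at month 6, boundary
inclusive. The toolkit mirrors standard retinal-cohort practice, with
exact/approximate switch points fixed and logged:

* Mann–Whitney U, two-sided, midrank ties; exact enumeration when the
  combined n ≤ 12 and tie-free, else normal approximation with tie and
  continuity corrections.
* One-way repeated-measures ANOVA, F = MS_visit/MS_error with
  (v−1), (v−1)(n−1) df; complete cases only, no imputation; a
  variation-free matrix returns F = 0, p = 1.
* 2 × 2 tables: Fisher's exact (two-sided, sum of ≤-probable tables) when
  any expected cell is ≤ 5, else chi-square with 1 df (no Yates
  correction); odds ratio ad/bc with Haldane–Anscombe 0.5 correction when
  a zero cell exists.
* Spearman rho by midranks; exact permutation p for n ≤ 8, else the t
  approximation.
* Logistic regression by maximum likelihood; Wald CIs and p-values.
  Perfect separation is detected and flagged instead of reporting a
  divergent OR. Backward selection seeds with univariate p < 0.1,
  repeatedly drops the largest-p term ≥ 0.05 and refits, breaking ties
  toward the later-listed column for determinism.
* Descriptives: mean ± SD, median with linearly interpolated quartiles,
  counts with percentages. No multiple-testing correction is applied,
  matching exploratory practice; the output notes this.

### Simulated cohort

`simulate_cohort` builds 44 paired eyes under macula-off-detachment
conditions. Presenting acuity is strongly skewed — about half the eyes at
the 1.0 logMAR ceiling and the rest spread below it (overall mean ≈ 0.83,
SD ≈ 0.29) — rather than normal, since a normal model contradicts the
observed median = upper quartile = 1.0 shape of such cohorts. Improvement
is 0.32 + 0.6·(pre − 0.83) + N(0, 0.15) logMAR, floored so post-op vision
never exceeds 20/20 (logMAR 0). The floor makes the success–acuity link
near-mechanical: eyes presenting well *cannot* gain 0.3, eyes at the
ceiling usually can — the clinically real reason presenting BCVA dominates
prediction. A consequence worth stating: the *fitted* per-unit odds ratio
under this mechanism is far larger than the moderate ORs such studies
print, because a smooth logistic curve fit to a near-threshold mechanism
is steep; the simulated cohorts instead match the reproducible anchors
(success rate ≈ 57%, presenting-BCVA distribution, association p of order
10⁻³). The six vascular metrics (VDI/VAD/VSD × SCP/DCP) are drawn from a
correlated normal model — density measures correlate at 0.8 within a
plexus, plexuses at 0.6, VDI with densities at 0.5 — *independent of
outcome*, so any selection of a metric is a false positive by
construction.

## Numerical conventions

* 0-based (row, col) pixel coordinates; distances from pixel centers.
* Reflective padding for every windowed operation.
* Thresholds are strict (`intensity > t`).
* Half-up rounding in the 8-bit conversion, with multiplication before
  division so exact midpoints stay exact in floating point.
* Degenerate inputs fail loudly: empty ROI, empty skeleton (VDI),
  constant outcome (logistic), missing ANOVA cells, < 3 polygon vertices.
* Test and acceptance runs use scaled-down grids (128–256 px at the same
  5.13 µm pitch, with the FAZ disc scaled to keep its area fraction) so
  the suite stays fast; full-scale 586 × 585 runs use identical code
  paths.

## Known limitations

* The fusion rule, filter scales and thresholds are defensible defaults,
  not a reconstruction of any particular proprietary implementation;
  absolute metric values are comparable only within a fixed configuration
  (the provenance hash in the output CSV guards this).
* VSD carries a small negative bias (thinning retracts free vessel ends by
  ~caliber/2) and VDI a small positive one at the thinnest calibers (edge
  anti-aliasing); both are bounded by the recovery tests rather than
  corrected, since a correction would be generator-specific.
* FAZ tracing itself is manual; only the area computation is provided.
* The cohort simulator is a nulls-plus-one-real-effect harness for the
  analysis chain, not a disease model; it makes no claim about real
  vascular–outcome relationships.
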