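# Methods

This note documents the models, conventions and design choices behind
`hyperleaf`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were settled.

## Data model and conventions

A hypercube is a 3-D array with fixed axis order **(band, column, frame)**:
*column* indexes pixels across the spectrograph slit, *frame* the scan
lines along the translation stage. On disk, raw cubes use the
band-interleaved-by-line (BIL) layout — per frame, one full line per band
in band order — with a plain-text sidecar header carrying
ENVI-compatible field names (`samples`, `lines`, `bands`, `data type`,
`interleave`, `wavelength`). The default raw sample type is little-endian
unsigned 16-bit; calibrated cubes are 32/64-bit float. The instrument grid
is 188 evenly spaced band centers over 400–1000 nm (≈3.2 nm spacing);
requested wavelengths always resolve to the nearest band center, and the
resolved center is what descriptor names report.

Reflectance calibration is `(raw − dark)/(white − dark)` with per-band or
full-cube references, clipped to `[1e-6, 1]` so every downstream logarithm
is finite. Calibration is monotone in raw counts per band.

## Spectral index engine

Nine transforms are defined over a reflectance spectrum: R, lg R, lg(1/R),
their first derivatives and their second derivatives (`lg` = log₁₀).
Derivatives are central differences divided by the local wavelength
spacing, one-sided at the grid ends, so each transform preserves the band
count n — this is what makes the family counts exact (e.g. 3n first
derivative indices). The derivative therefore has units nm⁻¹; Pearson
screening is invariant to that constant scaling. For two-log ratios such
as lg(R₇₁₅)/lg(R₅₀₀) the log base cancels; base choice affects only the
fitted coefficients of single-log indices, never a correlation.

The seven families and their censuses for an n-band grid:

| family | count |
|---|---|
| original R_i | n |
| pseudo-absorption lg(R_i), lg(1/R_i) | 2n |
| first derivative (3 transforms) | 3n |
| second derivative (3 transforms) | 3n |
| ratio T_i/T_j (9 transforms, ordered pairs) | 9·n·(n−1) |
| normalized (T_i−T_j)/(T_i+T_j) (ordered pairs) | 9·n·(n−1) |
| registry (position/area + published) | configurable, default 20 + 95 |

At n = 188 the total is 634,615. The full ratio/normalized families use
**ordered** pairs — this is required for the 316,404 = 9·188·187 family
counts. The *primary* red-edge subset (families R, dR, ddR, plain-R ratio
and normalized, all band centers in 700–760 nm) instead counts
**unordered** pairs, giving 3m + m(m−1) for m window bands; with 21
window bands that is 483. On the package's default evenly spaced grid only
19 centers fall inside 700–760 nm, so the 21-band figure depends on the
instrument's band-center convention; the window and grid are both
configurable and the census formula is exposed directly
(`primary_census`).

Evaluation is guarded: any combiner denominator with magnitude below
1e-12 yields NaN ("flagged"), never an infinity, and flagged columns are
excluded from rankings. The vectorized table evaluator
(`evaluate_all`) and the scalar per-index evaluator are independent code
paths kept equivalent by test.

The registry is pluggable. The default position/area group holds red-edge
position (linear-interpolation and max-dR variants), red-edge
amplitude/area, green-peak and red-well descriptors, and 50 nm band-area
integrals; the published group holds classic two-band vegetation indices
(NDVI, PSSR a/b, PSND, SIPI, PRI, Vogelmann, Gitelson, Datt, MCARI/TCARI,
OSAVI, MTCI, mND705/mSR705, red-edge chlorophyll indices, …) topped up
with simple-ratio/normalized-difference variants against an 800 nm NIR
reference so the group sizes match the declared 20 + 95 defaults.

## Screening

Every index is scored by Pearson's product-moment r against each pigment.
The exhaustive screen (`screen_exhaustive`) walks the enumeration family
by family, evaluating one transform's n × n pair tensor at a time, so peak
memory is O(samples · n²) — independent of the 634,615-column census —
and a full 150-sample screen runs in a few seconds. Rankings order by
|r| with a deterministic tie-break: canonical enumeration order (family
order of the table above, then smaller i, then smaller j). Reported r is
always signed. The summed heat map adds |r| across the 18 two-band maps
(9 ratio + 9 normalized); absolute values are used because the normalized
family is antisymmetric in (i, j), and the map's purpose is localization
of the informative band region, not sign recovery. Heat-map rendering is
cosmetic and never feeds back into computation.

## Pigment chemistry

Reference pigments come from ethanol-extract absorbances via the
Arnon-type system

    Ca  = 13.95·A665 − 6.88·A649
    Cb  = 24.96·A649 − 7.32·A665
    Cxc = (1000·A470 − 2.05·Ca − 114.8·Cb)/245,   C = Ca + Cb.

Negative computed pigments are *flagged, not clamped*: clamping would
silently bias model fits. The equations give solution concentrations;
conversion to mg/m² needs extract volume and leaf area, which enter as an
explicit user-supplied scale factor. The algebraic inverse
(`invert_arnon`) solves the 2×2 chlorophyll system (nonsingular for these
coefficients) and back-substitutes for A470; the forward/inverse round
trip is identity to better than 1e-9 and is exercised by test.

## Segmentation

Defaults: numerator 800 nm / denominator 680 nm (NIR/red vegetation
contrast; the band pair is configurable), Otsu threshold, horizontal
opening length 5 px, area floor 64 px, area ceiling 30 % of the image,
region-growing tolerance 0.2. Two choices deserve note:

* The float-to-8-bit conversion saturates at a configurable display range
  (default ratio 0–2). A flat background sits at ratio ≈ 1 while any
  vegetation exceeds 2, so the gray histogram is cleanly bimodal and Otsu
  lands between background and foliage rather than between leaves of
  different pigment level. Without saturation, Otsu can split the
  leaf-to-leaf spread instead of the leaf/background gap.
* "Removal of large areas" is read as discarding connected components
  above the area ceiling (calibration panels, stage edges). The ceiling is
  configurable for setups where large components should be retained.

Region growing accepts 4-connected neighbors within the tolerance of the
seed region's running mean, recomputed each accretion sweep; tolerance 0
is an exact fixed point, and grown regions that overlap are merged with a
logged warning. Because within-leaf intensity variation is multiplicative,
growing from strongly eroded seeds works best on the log-ratio raster —
the `ratio` argument of `extract_rois` accepts any intensity image. ROIs
are relabeled 1..k ordered by bounding-box position.

## Model fitting and validation

Linear and quadratic forms are ordinary least squares. Power
(y = a₀·x^a₁) and exponential (y = a₀·e^(a₁x)) are fit by true nonlinear
least squares in original units, initialized from the log-linearized OLS
solution — NLS matches the error structure of the form as reported rather
than of its log transform. The logarithmic form y = a₀·ln(a₁·x) is
recovered from OLS of y on ln x as a₀ = slope, a₁ = exp(intercept/a₀); a
near-zero slope is rejected as degenerate.

Metrics: R² = 1 − SS_res/SS_tot; MAPE = (100/n)·Σ|y−ŷ|/|y|;
RMSE = √(mean squared error); SD_APE = sample (n−1) standard deviation of
the individual absolute percentage errors. Zero-valued observations are
excluded from the percentage errors with a logged count.

Cross-validation shuffles with a recorded seed into k = 5 near-equal folds
(no stratification); each fold reports modeling (train) and validation
(held-out) metrics, plus means. Stepwise regression is classic
forward-entry/backward-removal on partial-F p-values with the conventional
0.05-in / 0.10-out defaults; when nothing passes entry an intercept-only
model is returned with an explicit note. Eight published linear pigment
models ship as presets (`PUBLISHED_MODELS`), keyed by growth stage and
pigment, each carrying its predictor index (e.g. x = lg(R₇₁₅)/lg(R₅₀₀)
for tillering chlorophyll a).

## Digitization

`predict_pixelwise` evaluates the predictor index on each ROI pixel's
spectrum (same spectral-axis conventions as ROI-level evaluation; no
spatial smoothing by default, optional 3×3 median) and applies the model.
Out-of-domain pixels become NaN no-data and are excluded from stretch
computation and summaries. For a descriptor and model both linear in
reflectance, the ROI-mean of the map equals the ROI-level prediction
exactly; for nonlinear descriptors the two agree up to within-ROI spectral
variance (Jensen gap). Rendering maps values linearly onto a perceptually
uniform colormap (grayscale mode available) between a (vmin, vmax)
stretch; a shared stretch across maps makes renderings comparable, and
rendering never alters stored values. The default pixel pitch metadata is
0.11 mm/pixel.

## Synthetic scenes

The generator emulates the study conditions, not leaf optics in full:

    R(λ) = B(λ)·exp(−(k_a·Ca + k_b·Cb + k_x·Cxc)/K₀) + η

with a logistic red-edge baseline B (0.44 visible shoulder → 0.50 NIR
plateau, inflection 710 nm, scale 10 nm), Gaussian specific-absorption
profiles centered at 665 (σ = 30 nm), 649 and 470 nm (σ = 25 nm), and
i.i.d. Gaussian sensor noise (default sd 0.005 reflectance units). K₀ =
335 mg/m² makes the 665 nm reflectance span ≈[0.05, 0.35] over the
default chlorophyll-a range 61.24–573.63 mg/m² — the tillering-stage range
of rice leaves — reproducing the qualitative inversion between reflectance
and chlorophyll. The visible-shoulder height follows from that span
constraint together with the ≈0.5 NIR plateau; the red edge of a rendered
leaf spectrum comes mostly from the pigment absorption term, not from B.

Leaves are elongated super-ellipses (nearly horizontal, disjoint rows)
with a central low-pigment vein stripe (×0.8) for vein/pulp contrast.
Per-leaf mean Ca is drawn stratified across the configured range so a
multi-leaf scene spans it; the per-pixel field multiplies the mean by a
smooth (Gaussian-blurred) random field with 6 % relative sd. Chlorophyll b
and carotenoid track chlorophyll a (Cb = Ca/3, Cxc = Ca/5, plus small
leaf-level noise), which reproduces the high inter-pigment correlations
of real leaves (r > 0.88; the generator achieves ≳0.99 at defaults). The
background is dark (reflectance 0.03) and spectrally flat so the
segmentation ratio has signal. Ground truth records per-leaf means,
per-pixel rasters, masks and the absorbance triples obtained by inverting
the Arnon system, so simulated spectrophotometry is exactly consistent
with the pigment fields. A scene is fully determined by its seed.

What the generator deliberately omits: radiative-transfer realism
(PROSPECT-class leaf structure, specular effects), sensor PSF/smile,
canopy geometry, and illumination gradients. Consequently the
near-perfect correlations and sub-percent MAPE the tests obtain on
synthetic data demonstrate the *machinery* (enumeration, screening,
fitting, digitization) rather than field-attainable accuracy; the
generative law is log-linear in pigment load by construction, so a
red-edge log index recovers it almost exactly.

## Problem sizes and numerical choices

Test and acceptance runs use 128 × 96-pixel scenes, 150 leaf samples and
the full 188-band grid — large enough to exercise the complete
634,615-index census (a full screen takes a few seconds thanks to the
blockwise evaluator) while keeping the whole suite fast. Reflectance is
floored at 1e-6 before logs; combiner denominators below 1e-12 flag NaN;
stepwise refits use exact OLS rather than incremental updates for
simplicity. Random processes (scene generation, CV folds, stepwise null
tests) all consume explicit seeds, and scene batches derive per-scene
seeds from a single SeedSequence so batches are reproducible and
non-overlapping.

## Known limitations

* The pluggable registry's position/published groups are
  representative, not a canonical published list; censuses are exact by
  construction but individual registry definitions are package defaults.
* The primary-subset size (483) depends on how many band centers an
  instrument places inside 700–760 nm (21 under some conventions, 19 on
  this package's evenly spaced default grid); both are supported.
* Stepwise selection inherits the usual caveats of p-value-driven
  selection (post-selection inference is not corrected).
* Per-pixel digitization assumes the leaf-level model transfers to pixel
  scale; on real data, within-leaf structure (veins, specularities) can
  bias pixel predictions in ways the synthetic scenes only partially
  emulate.
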