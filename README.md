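# hyperleaf

Hyperspectral image analysis for quantifying and digitizing pigment
distribution — chlorophyll a (Ca), chlorophyll b (Cb), total chlorophyll
(C = Ca + Cb) and carotenoid (Cxc) — in individual leaves, aimed at plant
phenotyping with line-scan (push-broom) hyperspectral cameras.

The package covers the whole chain from a raw band-interleaved-by-line
(BIL) binary stream to a per-pixel pigment map:

1. **Cube I/O & calibration** — read/write BIL streams with ENVI-style
   sidecar headers (188 bands, 400–1000 nm by default); calibrate counts to
   reflectance R = (raw − dark)/(white − dark).
2. **Leaf segmentation** — NIR/red band division, 8-bit conversion, Otsu
   thresholding, horizontal morphological opening, area filtering and
   region growing isolate each leaf as a region of interest (ROI).
3. **Exhaustive index search** — from every ROI-mean spectrum, seven index
   families are enumerated: original reflectance R_i, pseudo-absorption
   lg(R_i) and lg(1/R_i), first and second derivatives of each, the
   two-band ratio T_i/T_j and normalized difference (T_i−T_j)/(T_i+T_j)
   over all 9 transforms T and ordered band pairs, plus a pluggable
   registry of spectral-position/area and published vegetation indices.
   On the 188-band grid with the default 20 + 95 registry this is exactly
   **634,615 indices per sample** (9n + 18·n·(n−1) + 115).
4. **Screening** — Pearson r of every index against every pigment; band ×
   band heat matrices and their |r| sum localize the informative red-edge
   region (700–760 nm); the best index maximizes |r|. A restricted
   "primary" subset (R, dR, ddR and plain two-band combiners inside
   700–760 nm) reduces the search to a few hundred indices.
5. **Model fitting** — linear, power, exponential, logarithmic and
   quadratic forms with R², MAPE, RMSE and SD_APE; seeded 5-fold
   cross-validation; forward/backward stepwise multivariable regression.
   Eight published linear pigment models (e.g. Ca = 1217.948·x − 301.306
   with x = lg(R715)/lg(R500)) ship as ready-to-use presets.
6. **Digitization** — the chosen model applied to every ROI pixel yields a
   pigment map at the native 0.11 mm/pixel pitch, rendered with shared
   gray/pseudo-color stretches for cross-sample comparison.

A synthetic scene generator (`hyperleaf.synthetic`) renders leaf-shaped
scenes with known per-pixel pigment fields through a Beer–Lambert-style
reflectance law, so the entire pipeline is testable without instrument
data.

## Worked example

Simulate 60 single-leaf scenes, screen all 634,615 indices against
chlorophyll a, and fit the best one:

```python
import numpy as np
from hyperleaf import SpectralGrid, default_registry, fit_form, kfold_cv
from hyperleaf.indices import evaluate_all
from hyperleaf.screening import best_index, screen_exhaustive
from hyperleaf.synthetic import simulate_samples

grid = SpectralGrid.default()
registry = default_registry()

spectra, pigments = simulate_samples(60, seed=0, leaves_per_scene=1)
y = pigments["Ca"].to_numpy()

result = screen_exhaustive(spectra, y, grid, registry, target="Ca")
winner, r = best_index(result)
print(f"best index: {winner.name(grid)}  (r = {r:+.4f})")

x = evaluate_all(spectra, grid, descriptors=[winner], registry=registry).values[:, 0]
model = fit_form(x, y, "linear", predictor=winner, target="Ca")
a0, a1 = model.coefficients
print(f"linear model: Ca = {a1:.2f} * x + {a0:.2f}")
print(f"R^2 = {model.metrics.r2:.4f}, MAPE = {model.metrics.mape:.2f}%, "
      f"RMSE = {model.metrics.rmse:.2f} mg/m^2")

cv = kfold_cv(x, y, "linear", k=5, seed=0)
print(f"5-fold CV validation: MAPE = {cv.mean_validation.mape:.2f}%, "
      f"RMSE = {cv.mean_validation.rmse:.2f} mg/m^2")
```

Output:

```
best index: pseudo_absorption:lgR:717.6  (r = -1.0000)
linear model: Ca = -3479.78 * x + -1106.57
R^2 = 1.0000, MAPE = 0.13%, RMSE = 0.37 mg/m^2
5-fold CV validation: MAPE = 0.13%, RMSE = 0.36 mg/m^2
```

The winning index sits at 717.6 nm on the red edge — the spectral region
where reflectance responds most strongly to chlorophyll — and the negative
r reflects the absorption physics: more chlorophyll, lower reflectance,
lower lg(R). On synthetic scenes the generative reflectance law is exactly
log-linear in pigment load, so the fit is near-perfect; real leaves add
structural scattering and biochemical variability that these numbers do
not include.

A `hyperleaf` console command wraps the same stages
(`simulate`, `segment`, `indices`, `screen`, `fit`, `map`, `run-all`);
`hyperleaf run-all config.yaml` executes the full pipeline and writes a
machine-readable `manifest.json`.

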