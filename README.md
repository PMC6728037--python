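# bladdervol

Automated estimation of bladder urine volume from paired two-dimensional
ultrasound images.

Accurate knowledge of the post-void residual (PVR) — the urine left in the
bladder after voiding — drives the clinical typing of lower urinary tract
symptoms, with decision thresholds at roughly 50 ml (elderly) and 100 ml
(adults). The standard bedside method images the bladder in two orthogonal
planes, has an operator place calipers on three axial diameters, and applies
the prolate-ellipsoid formula. `bladdervol` automates that workflow:

1. **Segmentation** — the anechoic (dark) bladder lumen is extracted from each
   frame, either by a deterministic classical baseline (smoothing, Otsu
   thresholding of the dark class, morphology, largest component) or by a
   fully convolutional network: a VGG16-style encoder at one-quarter channel
   width (16, 32, 64, 128, 128 per block) with an FCN-8s decoder fusing
   stride-8/16/32 features, implemented in numpy and trainable on one CPU.
2. **Measurement** — the three diameters follow caliper practice on the mask
   contour: *a* is the longest near-horizontal chord of the transverse
   section, *b* the longest chord of the longitudinal section, *c* the longest
   chord orthogonal to *b*. A least-squares ellipse fit is available as an
   alternative measurement mode.
3. **Volume** — V = π/6 · a · b · c (cm → ml), classified against the 50/100 ml
   thresholds (≥ threshold counts as "above").
4. **Evaluation** — regression of estimated on actual volume forced through
   the origin (slope β, uncentered R²), confusion matrices and
   sensitivity/specificity per threshold, and Dice overlap for masks.

Because clinical images cannot ship with the package, a **phantom generator**
produces ultrasound-like test data with exact analytic ground truth: a
triaxial ellipsoid bladder with unit-mean multiplicative speckle, Gaussian
point-spread blur, optional field-of-view truncation, and known diameters and
volume.

## Worked example

```python
from bladdervol import PhantomSpec, classify, estimate_pair, generate_phantom

pair = generate_phantom(PhantomSpec(semi_axes=(3.0, 2.5, 4.0), seed=7))
est = estimate_pair(pair.transverse_frame, pair.longitudinal_frame)
print(est.diameters, est.volume_ml)
```

prints (see `examples/02_estimate_volume.py`):

```
measured diameters (cm): a=6.00  b=7.97  c=4.97
estimated volume (ml):   124.4   (truth 125.7)
relative error:          1.0%
classification at 50 ml: above
classification at 100 ml: above
```

The phantom's true diameters are twice its semi-axes (6, 8, 5 cm), so the
chord measurements are within a pixel or two of truth and the volume lands
within about 1 % of the analytic 125.66 ml. The `examples/` directory holds
one short script per capability: phantom generation, single-pair estimation,
agreement evaluation, network training, and chord/ellipse measurement.

## Command line

```sh
bladdervol simulate --n 50 --seed 1 --out phantoms/      # synthetic dataset
bladdervol run --manifest phantoms/manifest.csv --out results/
bladdervol train --manifest phantoms/manifest.csv --epochs 10 --out model.npz
bladdervol evaluate --results volumes.csv                # estimated vs actual
```

Manifests are CSV with `id, transverse_path, longitudinal_path,
spacing_mm_per_px[, actual_volume_ml]`; section labels always come from the
manifest, never from image content. Missing pixel spacing is an error, never a
silent default.

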