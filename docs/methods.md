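# Methods

## The estimation model

The bladder is treated as a prolate ellipsoid. From one transverse and one
longitudinal ultrasound section the pipeline extracts three orthogonal
diameters and computes

    V [ml] = k · a · b · c,   k = π/6 ≈ 0.5236,  a, b, c in cm

The coefficient is the exact ellipsoid constant and the standard clinical
choice; it is exposed in the API (`ellipsoid_volume(..., coefficient=...)` and
`PipelineConfig.ellipsoid_coefficient`) because some devices apply empirical
correction factors instead. Volumes are classified against clinical post-void
residual thresholds with an inclusive boundary: volume ≥ threshold counts as
"above", matching the ≥/< row convention of published PVR tables.

## Diameter measurement

Measurements are made on the binary mask contour, defined as the mask pixels
with at least one 8-neighbour outside the mask, after keeping the largest
connected component and filling interior holes. Chord endpoints are pixel
centres, 0-based (row, col), origin top-left; "horizontal" is the image width
axis; lengths are Euclidean distances in physical mm (row and column spacing
may differ).

* **a (transverse width)** — the longest chord whose orientation lies within
  ±10° of horizontal. The tolerance quantifies the caliper convention of a
  line "parallel to, or at small slope against" the horizontal axis and is
  configurable (`horizontal_tolerance_deg`).
* **b (longitudinal maximal)** — the longest chord, unconstrained.
* **c (orthogonal)** — the longest chord within ±2° of perpendicular to *b*,
  widened automatically to ±5° when the rasterized contour contains no pair
  that close to perpendicular. If even the widened band is empty (essentially
  one-dimensional masks), *c* falls back to the perpendicular Feret extent:
  the contour's projection span onto the perpendicular direction plus one
  pixel footprint. `c` is clamped to `b` so the invariant b ≥ c always holds.

The chord search is an exact maximisation over **all** contour point pairs
(chunked vectorised computation; no sampling), with a deterministic tie-break:
largest length, then smallest orientation angle in [0, 180), then
lexicographically smallest endpoint pair. Results are therefore
bit-reproducible, and the test suite checks exact agreement with an
independent brute-force double-loop oracle on a library of fixture masks
(circles, rotated and truncated ellipses, degenerate lines).

An alternative measurement mode fits a least-squares ellipse to the contour
(in physical coordinates, so anisotropic spacing is handled) and uses its axis
lengths as diameters. On clean convex masks the two modes agree within a few
percent; chord mode is the default because it mirrors the caliper definitions
directly. Both modes are kept because caliper rules and ellipse fitting are
both defensible readings of bedside practice; the discrepancy on non-elliptic
masks is a known ambiguity rather than a bug.

## Segmentation backends

Both backends satisfy the same contract — `UltrasoundFrame` in, boolean mask
out — so the full pipeline is testable with the deterministic backend alone.

**Classical baseline.** Gaussian smoothing (σ = 2 px), Otsu threshold
selecting the dark class, morphological closing (disk radius 3), hole
filling, then the largest dark component; frames with less than 0.05 dynamic
range or no dark component of ≥ 100 px raise "no bladder detected". All
structuring elements are symmetric, so the baseline is exactly equivariant
under horizontal flips.

**Network.** A VGG16-style encoder with channel counts at one quarter of
VGG16 — blocks (16, 16), (32, 32), (64, 64, 64), (128, 128, 128),
(128, 128, 128), each followed by 2×2 max pooling — and an FCN-8s decoder:
1×1 score layers on the stride-8, stride-16 and stride-32 feature maps, fused
by successive 2× bilinear upsampling and addition, then upsampled 8× to a
two-class per-pixel map. The implementation is plain numpy (im2col
convolutions over BLAS, separable bilinear resampling with its exact adjoint
as the backward pass). Design choices where the architecture description is
silent:

* activation: leaky rectifier (slope 0.05). With strict ReLU, short
  from-scratch training collapses for some seeds: entire encoder blocks die
  and the output degenerates into an input-independent "average mask" carried
  by padding-induced bias patterns. The leak lets dead units recover and made
  every tested seed converge.
* score and skip 1×1 convolutions are zero-initialised (standard FCN
  practice); all other layers use He initialisation.
* upsampling is fixed bilinear (not learned); the head uses a 3×3, 256-channel
  convolution pair in place of the original fc6/fc7.
* pretrained encoder weights are an optional injection point
  (`SegmentationModelSpec.pretrained_encoder`); the default is random
  initialisation, since phantom training needs no transfer learning and no
  reproducible source of such weights exists.

**Training.** Pixel-wise softmax cross-entropy (optionally class-weighted),
stochastic gradient descent with momentum 0.9, batch size 4, and the step
schedule lr(e) = initial_lr / 10^⌊e/step⌋ with step = 50 epochs; the
full-scale defaults are 200 epochs at initial 1e-4. Gradients are clipped at
global norm 10, which protects the short schedules from occasional unstable
batches. Augmentation applies brightness (±0.08) and contrast (0.85–1.15)
jitter to the image only, horizontal flips (p = 0.5) to image and mask
jointly, and a final resize to the network input (512×384 by default; pixel
spacing is rescaled accordingly). Probability maps are thresholded at 0.5 and
resized back to the frame resolution.

The repeatable scaled-down exercise used by the tests and the acceptance
script trains on 200 frame/mask pairs (100 two-section phantoms) at 96×64 for
10 epochs with initial lr 0.1 and class weights (1, 3) against the
background/foreground imbalance — about two minutes on one CPU, reaching
validation Dice ≥ 0.95 for every seed tried. The raised learning rate and
class weights are choices for the short schedule only; the schedule form is
unchanged.

## The phantom generator

The generator emulates the study inputs the pipeline expects: paired
transverse/longitudinal B-mode-like frames of a urine-filled bladder.

* Geometry: a triaxial ellipsoid with semi-axes along the transverse,
  anteroposterior (AP) and superoinferior (SI) anatomical directions. The
  transverse section shows the (transverse, AP) plane, the longitudinal
  section the (SI, AP) plane — so the transverse width is 2·ax and the
  longitudinal section carries 2·max(ay, az) and 2·min(ay, az), matching the
  chord definitions. Per-section in-plane rotation and centre offsets model
  probe placement; an offset large enough to clip the ellipse marks the pair
  as truncated (ground-truth masks are the untruncated ellipse clipped to the
  frame).
* Intensities: anechoic lumen (mean 0.08) in brighter tissue (mean 0.55),
  multiplied by unit-mean gamma speckle (sd 0.35, i.e. gamma shape ≈ 8) and
  blurred with a Gaussian point-spread (σ = 1 px), clipped to [0, 1]. The
  speckle affects intensities only; masks are seed-independent.
* Defaults: 512×384 px frames at 0.35 mm/px (≈ 13 cm depth of view); random
  datasets sample semi-axes uniformly in 1.0–3.3 cm with rejection above
  150 ml (emulating a below-150 ml voiding population), rotations ±20°,
  centre jitter ±0.8 cm.

What the phantoms do **not** model: beamforming geometry (sector fan),
depth-dependent attenuation and focus, acoustic shadowing and enhancement,
other pelvic structures, probe pressure deformation, or non-ellipsoidal
bladder shapes. Passing the phantom suite therefore demonstrates that the
measurement and evaluation machinery is correct and that the network can
learn the anechoic-region concept — not that clinical-grade segmentation
accuracy has been achieved on patient images.

## Parameter-recovery conditions

The noiseless recovery sweep (semi-axes 1–5 cm, pixel spacings
0.2–0.6 mm/px, estimate within 5 % of analytic truth in every case) applies
rotations of 0–45° to the longitudinal section but keeps the transverse
section within ±5° of aligned. This is deliberate: chord *a* is *defined* as
the near-horizontal width, which equals the transverse diameter only when the
probe is approximately aligned — exactly the assumption the ±10° caliper
tolerance encodes. A transverse section rotated 45° changes the quantity the
rule measures (the horizontal extent of a tilted ellipse), not the accuracy
of the search; longitudinal rotation is harmless because *b* is unconstrained
and *c* is measured relative to *b*. Combinations whose bladder cannot fit
the 512×384 view untruncated are skipped.

## Numerical and degenerate-input conventions

* Chord-length comparisons happen in exact arithmetic where possible (integer
  pixel offsets scaled by spacing, `hypot` applied identically in library and
  oracle), so oracle equivalence is tested with `==`, not a tolerance.
* Uncentered R² (1 − Σresid²/Σy²) is reported for the through-origin
  regression; the centered variant can be negative for origin-forced fits and
  is carried alongside for reference (`r_squared_centered`).
* Percentages are rounded half-up to one decimal via decimal arithmetic (so
  0.8845 → 88.5 %, not banker's 88.4 %).
* Dice of two empty masks is defined as 1.0.
* Empty masks, uniform frames, undersized dark components, impossible angle
  constraints and missing pixel spacing all raise typed, descriptive errors;
  the batch pipeline flags per-row failures and continues.
* Problem sizes in the test suite (phantom counts, 96×64 training resolution,
  10-epoch schedules, fixture mask sizes) are chosen so the whole suite runs
  in minutes on a single CPU while still exercising every code path at
  realistic geometry.

## Known limitations

* The ellipsoid coefficient of the original bedside tools is not always π/6;
  absolute volumes scale linearly with it, so agreement slopes would shift by
  a constant factor under a different convention.
* Chord measurements are pixel-centre based with no sub-pixel contour
  refinement; accuracy is bounded by ~2 px · spacing.
* The network is trained and validated on phantoms only; no claim is made
  about clinical images, device integration, or the behaviour of pretrained
  encoders.
* Evaluation treats every frame pair as an independent observation.
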