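# Methods

## The problem and the protocol

Dermatopathological assessment of atypical melanocytic lesions hinges on
spotting regions with anomalous architectural or cytological features in
H&E photomicrographs. `frfseg` implements a trainable pixel-classification
protocol for this setting: the pathologist circles a few small clusters of
pixels per "defect" class **on the image to be analyzed**, a random forest
learns to recognize those classes from a multi-scale filter-bank
description of every pixel, and the resulting per-class probability maps
are thresholded and converted to physical defect coverage. There is
deliberately no held-out image: training and testing happen on the same
field, so the method needs no historical dataset and its quality indicators
(precision, recall, ROC) are training-set quantities.

The pipeline is: grayscale conversion → feature stack → forest training on
sparse labels → per-pixel probability maps → threshold filtering → coverage
percent and extension in mm².

## Image model and calibration

Images are 2-D intensity grids in [0, 1]. RGB inputs are collapsed with
BT.601 luma weights (0.299, 0.587, 0.114) — the conversion choice is ours;
any fixed luma convention would do, and an already-gray image passes
through unchanged. Physical calibration is pixels per millimetre,
defaulting to 1000 px/mm so that the canonical 1000 × 2000 px analysis
field spans 1 mm × 2 mm and

```
extension_mm2 = (coverage_percent / 100) · H·W / (px_per_mm)²
```

holds as exact arithmetic, not a measurement.

## Feature bank

Every enabled filter is evaluated at Gaussian scales σ ∈ {σ_min·2^k ≤
σ_max}; with the default σ_min = 1, σ_max = 16 that is {1, 2, 4, 8, 16}
(only the endpoints are protocol-level parameters; the doubling ladder is
our convention). The default bank — raw intensity, Gaussian blur, the
Hessian family and membrane projections, with membrane thickness 1 and
patch size 19 — reflects the protocol's optimized training configuration;
nine further filter families (difference of Gaussians, local statistics,
Perona–Malik diffusion, bilateral, Lipschitz top-hats, Gabor energy,
higher-order Gaussian derivatives, structure-tensor eigenvalues, axis
shifts) can be enabled per configuration. All convolutions reflect at the
border; even-order Gaussian-derivative kernels are DC-corrected so
constants are annihilated exactly.

Hessian family at scale σ, from h1 = I_xx, h2 = h3 = I_xy, h4 = I_yy:
trace = h1 + h4; eigenvalues fe, se = trace/2 ± √(4h2² + (h1−h4)²)/2;
orientation = ½·arctan2(2h2, h1−h4); γ = t⁴(h1−h4)²((h1−h4)² + 4h2²) and
√γ-companion t²((h1−h4)² + 4h2²) with t = 13/4. Two determinant variants
are kept: the algebraic `det_standard = h1·h4 − h2·h3`, which satisfies
fe·se = det and feeds all invariants, and a legacy variant
`det_printed = h1² + h2·h3 + h4²`, retained as the default stack feature
for continuity with the original tool chain. A legacy arccos orientation
form is likewise selectable; its argument is clamped to [−1, 1] because it
is undefined otherwise. The reading of "t = 13/4" as the constant 3.25 is
a documented choice (the notation could also denote an exponent); it is
configurable and, being a monotone per-plane rescaling, does not affect
tree splits.

Membrane projections rotate a normalized line kernel (length = patch size,
width = thickness) through 30 orientations in 6° steps and aggregate the
30 response planes per pixel by sum, mean, std, median, max and min. Each
rotated kernel is renormalized to unit sum so a constant image yields a
exactly-zero std plane.

## Forest

CART-style trees grown to purity on bootstrap resamples of the labeled
pixels; at each node `features_per_split` features (default ⌊√F⌋) are
drawn without replacement and the Gini-optimal axis-aligned split is
taken. Defaults: 200 trees, minimum leaf 1 — unspecified at the protocol
level, chosen as the field's standard forest settings. Per-pixel
probability is the mean of leaf class-frequency vectors over trees, hence
the ensemble map is exactly the mean of its single-tree maps; the master
seed derives one sub-seed per tree so any single tree is reproducible in
isolation. All ties (split gain, threshold, argmax class) break toward the
lowest index: reproducibility over arbitrariness.

Precision and recall are micro-averaged over classes and evaluated on the
training annotations (the protocol's own notion of performance); for
single-label prediction micro-precision and micro-recall coincide with
accuracy, so per-class values are reported alongside. The learning curve
re-trains on the first *n* samples of a seeded random ordering of the
annotations, restoring canonical order before fitting so that *n* = total
reproduces `train()` exactly; "instances" therefore means annotated
training samples. A class absent from the first *n* samples is flagged and
scored 0. ROC sweeps the unique probability values at annotated pixels and
integrates by the trapezoid rule.

## Quantification

Masks use `probability ≥ threshold` (≥, not >, documented for
bit-exactness), default threshold 0.5 per class and configurable, since
the enhancement threshold is operator-tuned in practice. Coverage percent
is pixel counting; extension is the closed-form rescaling above.
Human-readable tables round percent to one decimal and mm² to three;
JSON/CSV keep full precision. No morphological post-processing is applied.

## Synthetic scenes

The generator stands in for the non-deposited specimen images. Background
and defect textures are stationary Gaussian fields (smoothed white noise,
renormalized, clipped to [0, 1]) with controllable mean, sd, correlation
length and orientation; defect classes are elliptical blobs whose pixel
areas are **exact by construction** (pixels are ranked by the ellipse
quadratic form and the requested count taken), so ground-truth coverage is
known without error. Defaults mirror the study conditions: 1000 × 2000 px
at 1000 px/mm, a light background (mean 0.78, sd 0.05) and two defect
classes at means 0.35 and 0.55 covering 5.3% and 4.1% of the field — the
first two coverages of the published analysis. The |Δmean| ≥ 4·sd
separation makes classes learnable from ~10² labels; tests use smaller
fields (e.g. 160 × 320, 512 × 512) with the same fractional areas, a
problem-size choice only.

What the scenes do **not** emulate: nuclei and cellular morphology, stain
variation, focus gradients, spatially varying illumination, or boundary
ambiguity between lesion and normal tissue. Passing tests therefore
demonstrate that the machinery is correct and that texture-separable
classes are recovered quantitatively — not that real H&E defect classes
are separable at these accuracies. The published 17% discordance against
the dermatopathologist, and the ~300-instance precision saturation curve,
depend on the original 125-image cohort and are out of reach of synthetic
fixtures; the package reports the same indicators but makes no claim to
reproduce those cohort-level numbers.

## Numerical choices and degenerate inputs

- Feature planes are stored float32 (memory), split search in float64.
- Bootstrap may present a node with duplicate points of different classes;
  the leaf then keeps the mixed frequency vector.
- A node whose drawn features are all constant becomes a leaf even if
  impure.
- Probability maps validate per-pixel sums to 1 within 1e−6.
- Thresholds, coverage and extension are exact arithmetic; the only
  stochastic quantities are forest-dependent.
- Training with < 2 classes or an empty class is an error; the learning
  curve tolerates single-class subsets (degenerate schedules) by design.

## Known limitations

- Same-image evaluation measures memorization capacity as much as
  generalization; that is faithful to the protocol but should not be read
  as segmentation accuracy on unseen fields.
- The pure-Python/numpy forest is vectorized per tree; full-frame
  prediction on 2-megapixel images with 200 trees takes on the order of a
  minute, fine for interactive single-field use but not for slide-scale
  batches.
- Gabor/bilateral parameterizations follow common defaults rather than a
  protocol specification; they are off in the default bank.
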