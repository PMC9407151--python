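# frfseg

Trainable pixel classification and defect quantification for calibrated
histopathology photomicrographs.

Dermatopathologists assessing atypical melanocytic lesions must judge
scattered regions of architectural or cytological atypia in H&E fields —
a task with notoriously high interobserver variability. `frfseg`
implements a fast-random-forest (FRF) image-vision protocol for this
setting: the specialist circles a few clusters of pixels per "defect"
class **on the very image to be analyzed**, a random forest learns those
classes from a multi-scale filter-bank description of every pixel, and the
thresholded per-class probability maps quantify how much of the field each
defect type covers — as a percentage and as mm², via the pixels-per-mm
calibration. No historical training set is needed.

## Method

Each pixel *i* gets a feature vector **x**ᵢ from a filter bank evaluated
at scales σ ∈ {1, 2, 4, 8, 16}: Gaussian blur, the Hessian family
(trace h₁+h₄, determinant, eigenvalues Fe, Se = (h₁+h₄)/2 ±
√(4h₂²+(h₁−h₄)²)/2, orientation ½·arctan2(2h₂, h₁−h₄), γ-features), and
membrane projections (a 19 × 1 line kernel rotated through 30
orientations, responses aggregated per pixel); nine further filter
families are available. An ensemble of T CART trees (default T = 200,
⌊√F⌋ features per split, grown to purity on bootstrap resamples of the
labeled pixels) yields

  P(class k | pixel i) = (1/T) Σₜ fₜₖ(**x**ᵢ),

the mean of the leaf class-frequency vectors. For each defect class the
mask {P ≥ θ} (default θ = 0.5) gives

  coverage % = 100 · |mask| / (H·W),  extension mm² = coverage · H·W / s²,

with s the calibration in px/mm. Training precision/recall and ROC curves
(trapezoid AUC) report classifier quality under the same-image protocol.

## Worked example

`examples/02_train_classify_quantify.py` builds a 160 × 320 px calibrated
scene (1000 px/mm) with two defect textures of known, exact coverage,
trains on 80 labels per class and quantifies:

```
feature stack: 47 planes
training precision = 1.000, recall = 1.000
Class         Coverage %  Extension mm^2
C1                   5.2           0.003
C2                   4.8           0.002
  C1: measured 5.23 % vs truth 5.30 %
  C2: measured 4.84 % vs truth 4.10 %
```

Training precision 1.0 means every annotated pixel is classified as its
own class; the measured coverages sit within about one percentage point of
the constructed ground truth (0.003 mm² of a 0.051 mm² field for C1). The
other examples show scene generation and the learning-curve/ROC
indicators (`AUC(defect) = 1.000` on a separable fixture — the ideal
classifier curve).

## Command line

```
frfseg simulate --out scene/ --height 320 --width 640 --seed 7
frfseg run --image scene/image.png --labels scene/labels_mask.png \
           --classes scene/labels_classes.json --out results/ \
           --n-trees 100 --seed 1 --threshold C1=0.5
```

`run` executes the full protocol (stack → train → classify → threshold →
report) and writes probability maps (float32 TIFF), the class map, the
model (JSON), performance indicators and the coverage report (JSON + CSV),
each stamped with the seed and a configuration hash; identical runs are
byte-identical. Exit codes distinguish configuration (2), I/O (3),
annotation (4), training (5) and evaluation (6) failures.

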