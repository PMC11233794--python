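# Methods

This note records the models, conventions, parameters and design
decisions behind `tumorgrade`, and what the synthetic experiments do and
do not establish.

## 1. Problem setting

The pipeline grades a 2-D grayscale brain MRI slice into one of five
classes — Grade I–IV tumor or Healthy — in two phases: (1) classical
preprocessing that reduces the image to a binary candidate-tumor mask,
and (2) a small convolutional classifier with 1-bit convolution weights
that maps the mask to a grade. Grade is treated throughout as a
*size-ordered* label: larger blob, higher grade. That is an
operationalization, not a clinical claim; the WHO scale orders tumors by
severity, and size is the single image feature this method uses.

## 2. Synthetic phantoms

Because the pipeline is validated without clinical data, a generator
produces phantoms that emulate the gross structure of an axial slice:

- a bright **skull ring** (annulus, default outer radius 0.45·side,
  thickness 10 px, intensity 255),
- a noisy **tissue interior** (default intensity 120, additive Gaussian
  noise with σ = 8, clipped to [0, 255]),
- zero or one bright elliptical **tumor blob** (default intensity 230,
  axis-aligned, aspect ratio drawn in [0.75, 1], uniformly placed inside
  the ring).

Intensities were fixed so that tumor/tissue/background are separated by
large margins relative to the noise (tumor−tissue = 110 ≈ 14σ).

**Grade bins.** At the 600×600 working size the default area bins are
(0, 1500] / (1500, 3000] / (3000, 5500] / (5500, 9000] pixels for Grades
I–IV, with per-class *sampling* ranges (1000–1400, 1800–2800, 3400–5200,
6000–8500) sitting inside the bins. Two geometric constraints fixed
these numbers: the ranges must be pairwise disjoint with margins that
absorb pixel-discretization error, and every blob must survive a
morphological opening by a 22×22 square — which erases any blob that
cannot contain a 22×22 square (area ≲ 760 px for near-circular blobs), so
Grade I starts at 1000 px. The bins are calibration knobs of the
generator, not measurements.

**Determinism.** Per-image seeds derive from the master seed through a
stable counter (`SeedSequence([master, counter])`); the noise field is
the only stochastic term in a rendered image, and identical spec + seed
reproduce the dataset bit for bit. Rendered masks are checked for label
consistency (`grade_from_area(rendered area) == folder label`) at
generation time.

**What the phantoms do not model:** anatomy (ventricles, gray/white
matter, folding), intensity inhomogeneity fields, partial-volume edges,
multi-slice geometry, multiple or non-elliptical lesions, and
non-Gaussian (speckle, salt-and-pepper) noise. Passing on phantoms shows
the pipeline is a correct implementation of the stated method and that it
solves the idealized size-grading problem; it says nothing about accuracy
on clinical MRI.

## 3. Phase 1 conventions

**Nearest-neighbor resize.** Source index = ⌊(i + 0.5)·in/out⌋ per axis.
This reproduces block replication for integer upscaling (each pixel
becomes a k×k block) and, composed with the odd-index decimation rule
(`decimate_halve` keeps 1-based odd rows/columns), round-trips exactly:
upscale-by-2 then decimate is the identity. No new intensity values are
ever created.

**Wiener filter.** Local mean and variance use zero padding and the full
N·M normalizer (window sums divided by N·M even at borders). Default
window 3×3. Degeneracies are guarded: the gain (σ²−ν²)/σ² is clamped at
0 (never amplify away from the local mean) and σ² = 0 returns μ. With
ν² = 0 the filter is exactly the identity. When ν² is not supplied it is
the mean of all local variance estimates; note this estimate includes
variance contributed by true structure (edges), so on structured images
it overestimates pure noise power — the conventional behavior of this
filter. Internal arithmetic is float64; quantization to 0–255
(round-half-up, clip) happens only at file I/O.

**Adaptive threshold.** Foreground iff pixel > (window mean) ∓ C, strict
inequality, same zero-padded mean as above. The literal mean−C rule is
the default of the standalone operation; note that it marks any
near-constant region as foreground (v > v − C), so it relies entirely on
the subsequent opening for cleanup. The pipeline default is the
practical mean+C mode.

Two pipeline defaults differ deliberately from a naive reading:

- *window 201* (not image-scale ~35): a neighborhood mean computed over a
  window smaller than a blob converges to the blob's own intensity in its
  interior, so mean±C thresholding cannot segment uniform blobs larger
  than the window. Grade IV blobs reach ~100 px diameter; the 201 window
  keeps the local mean dominated by tissue.
- *C = 50* (not ~10): just inside the skull ring the 201-window mean is
  deflated ~30 intensity units by the dark exterior, which would promote
  an annulus of plain tissue to foreground at small C. C must exceed that
  deflation while staying well below the tumor–tissue contrast (110);
  50 sits between with margin. Verified against ground truth: phase-1
  mask areas track true blob areas within ~15% and Healthy phantoms give
  empty masks.

**Morphology.** Erosion and dilation are defined by the fit/hit probes
(fits = every 1-pixel of the element lands on an image 1; hits = at least
one does), with out-of-image pixels counting as 0 — so erosion strips the
image border. Dilation places the element's origin at the output pixel
*without reflection* (hit convention). Consequences worth knowing:

- the complement duality holds with the *same* element,
  ¬erode(f, s) = dilate(¬f, s), away from border effects;
- for an even-sided all-ones element (origin 11,11 of 22×22 — no central
  pixel exists) erosion-then-dilation equals a true opening *composed
  with a one-pixel translation*; area and shape of the cleanup are those
  of the opening, but exact idempotence holds only for odd symmetric
  elements.

Internally the probe counts are computed by C-level correlation
(`scipy.ndimage`), with a separable fast path for all-ones rectangles;
both are tested against exhaustive loop oracles.

## 4. The binary CNN

**Architecture.** Input: mask nearest-neighbor-resized to 64×64, values
mapped to {−1,+1}. Three blocks of [binarized conv 7×7, 8 kernels,
stride 1, pad 3 → max pool 2×2 → min–max normalization], flatten
(8×8×8 = 512), one fully connected layer to 5 logits, softmax,
cross-entropy loss. Only convolution weights are binarized; activations
and the FC layer stay real.

**Weight binarization.** Deterministic mode: w_b = sign(w), with
sign(0) = +1. Stochastic mode (training only): P(w_b = +1) =
hard-sigmoid(w) = clip((w+1)/2, 0, 1). Backward: straight-through
estimator, gradient passed where |w| ≤ 1 and zeroed outside.

**Why 7×7 kernels and a positive init.** On a ±1 mask the all-plus
kernel is a local foreground-occupancy counter; a blob smaller than the
kernel produces a peak response proportional to its area, and a *wide*
quasi-uniform kernel makes the subsequent max-subsampling approximately
area-preserving (adjacent responses are nearly equal, so the window max
approximates the window value). Latent weights are therefore initialized
as Glorot-uniform shifted by +2× the Glorot limit: every initial sign
kernel is all-+1 (a counting kernel) while the latent magnitudes stay
diverse so the straight-through gradients can reshape them. With a
zero-centered init the pooled features of random ±1 kernels lose most of
the area information and held-out accuracy saturates far below 100% —
measured directly during development via linear probes on the flatten
features.

**Normalization statistics.** x ↦ (x − m)/(x_max − x_min) per channel
(output in [−1,1]; a (x − x_min)/(x_max − x_min) mode is available). The
statistics are *dataset-level* quantities: they are recomputed exactly
over the full training set after every epoch and held fixed in between
(and at inference). Per-mini-batch extrema were tried first and are a
poor choice here: the max/min of 32 samples are heavy-tailed estimates of
the dataset extrema, which made the head's effective inputs jitter from
batch to batch and the evaluation-time running averages systematically
biased — observable as smooth training-mode accuracy with intermittent
eval-mode collapses. Backward treats the statistics as constants
(dx = dy/range).

**Optimization.** Per epoch: (1) one shuffled mini-batch SGD pass
(batch 32, lr 0.05, momentum 0.9) through the whole stack, with the
latent conv weights on a 0.02× step — a sign flip changes the forward
network discontinuously, so the 1-bit layers are refined slowly;
(2) statistics recalibration; (3) a near-complete solve of the final
layer's convex softmax-regression subproblem on the cached 512-d features
(600 full-batch Adam steps, lr 0.05, ridge penalty 4·10⁻⁴ on the weight
matrix). The ridge term selects, among the many heads that separate the
training set, the small-norm one that spreads weight evenly over the
redundant counting channels — empirically the area-reading head that
generalizes. Training stops when training accuracy reaches 100% *and*
the training loss is ≤ 0.25 (accuracy alone can be reached with logits
barely past the boundary), with a hard cap at 50 epochs. Fixed seed ⇒
bit-identical model and report.

**Evaluation.** Accuracy and macro-averaged precision/recall/F1 from the
5×5 confusion matrix, percent scale; a class absent from both truth and
prediction contributes 0 to the macro averages and triggers a warning.
Cross-checked against scikit-learn in the test suite.

## 5. Pipeline and reproducibility

Stratified split: per class, round(0.9·n) images to train (clamped so
both sides are non-empty), seeded shuffle. A full run writes masks,
checkpoint, per-epoch report, metrics and a run manifest with a config
hash; two runs from identical (dataset, config, seed) are byte-identical.
Model checkpoints store latent weights, normalization statistics and the
config in a single `.npz`.

## 6. Problem sizes and observed behavior

The standard experiment — 50 phantoms per class, 90/10 split, 64×64 input
— trains in seconds to a few minutes on one CPU core. Under these
conditions training accuracy reaches 100% (typically in 1–3 epochs
thanks to the convex head solve), and held-out accuracy is 96–100% over
the seeds tried during development. Residual held-out errors, when they
occur, are single blobs whose area falls inside the gap between two
classes' training areas after the 600→64 downscale; where the decision
boundary lies inside that gap is not identifiable from the training data,
so occasional one-off errors on 25 test images are expected rather than a
defect.

## 7. Known limitations

- Phantom realism (see §2): results bound implementation correctness,
  not clinical performance.
- The literal mean−C threshold is kept for fidelity but is not usable as
  a segmentation rule on its own (it foregrounds constant regions).
- Max pooling discards foreground counts; the area information reaching
  the classifier head is approximate, which is the binding constraint on
  held-out accuracy at 64×64 input.
- The 22×22 opening erases blobs below ~760 px at 600×600, bounding the
  smallest gradable lesion; the Grade I sampling range respects this.
- Stochastic weight binarization is provided and tested but the default
  preset trains with deterministic signs; stochastic mode increases
  gradient variance markedly at this data scale.
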