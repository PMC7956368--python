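# Methods

## The model

The package classifies labeled 2D grayscale images by projecting them into
a *dissimilarity space*. Three learned components define that space:

1. **A pair scorer.** A Siamese network — two CNN branches sharing one set
   of weights — embeds each image of a pair into `R^E` (E = 4096, or 2048
   for topology 2 at full scale). The subtract block `Y = |F1 − F2|`
   combines the embeddings; because of the absolute value the score is
   invariant to swapping the inputs, which is asserted rather than assumed
   in the tests. A single dense unit plus sigmoid maps `Y` to `(0,1)` and
   is trained with binary cross-entropy against the pair label
   (1 = same class). The learned score is deliberately *not* a metric: it
   satisfies symmetry and continuity but neither identity (`d(x,x)` is not
   0 — an untrained head with zero bias gives exactly 0.5) nor the triangle
   inequality.

2. **Prototypes.** Supervised k-means: Lloyd's algorithm with k-means++
   seeding run *independently inside each class* on a vector rendering of
   the images (32×32 downsampled pixels by default; the HASC-image pixels
   when that representation is selected), giving kc centroids per class and
   k = kc·c axes. Centroids are reshaped back into synthetic prototype
   images and scored against real samples — the alternative (snapping each
   centroid to its nearest real training image) was considered and
   rejected as it discards the averaging that makes centroids robust.

3. **A one-vs-all linear SVM** (C = 1) on the dissimilarity vectors, with
   the signed margin as the confidence and argmax decisions. A linear
   kernel is the deliberate default: the dissimilarity vector is already a
   learned, low-dimensional representation. Design-matrix columns are
   standardized on the training fold before the fit — a strongly trained
   pair scorer saturates most scores toward 0, leaving the discriminative
   signal on a tiny scale where unscaled one-vs-all margins calibrate
   poorly against each other (near-perfect per-class AUC but depressed
   argmax accuracy).

Ensembles fuse the per-member test score matrices by the elementwise sum
rule. Plain Siamese ensembles sum raw margins (z-normalization before the
plain sum is available but off by default); heterogeneous fusions (e.g.
with external CNN score matrices ingested from CSV) z-normalize each member
to mean 0, sd 1 — population convention, statistics pooled over the
member's training-fold scores to keep the test fold untouched — and apply
positive weights, such as 4:1 for a four-CNN ensemble against one Siamese
ensemble.

## Backbone catalog

Eight topologies are cataloged with exact arithmetic under valid
(unpadded) convolution, `out = floor((in − f)/stride) + 1`, single-channel
224×224 input. Strides are part of the catalog: every convolution is
stride 1 except topology 3's first (stride 4) and topology 5's second
(stride 4) and third (stride 2); pool stride equals pool size. The grouped
convolutions of topology 8 use 2 groups — the only count consistent with
its published parameter numbers (50,240 and 147,712). Two published
inconsistencies are tracked in `dissimspace/reference.py` and excluded
from the oracles: topology 5's 26→9 transition (no integer stride exists;
stride 2 is used and shapes tracked as computed) and topology 7's FC count
(implies a 4096-dim input where the predecessor activation is 9×9×256).

The leaky-ReLU slope defaults to 0.01; the published value a = 1 would
make the activation the identity and is treated as a misprint (the slope is
configurable). Topology 7's dropout probability is unstated; 0.5 is used.

## Training

ADAM with the full-scale defaults: learning rate 1e-4, gradient decay 0.9,
squared-gradient decay 0.99, 3000 iterations, no stopping criterion, batch
size 32, a fresh balanced (50/50 same/different in expectation) pair batch
every iteration, no augmentation (an optional reflection + [1,2]-rescale
augmentation exists but is off by default). Weights initialize from a
narrow Gaussian (σ = 0.01) under the run seed; every random draw funnels
through seeds derived from one root seed via `numpy.random.SeedSequence`,
so loss traces are bitwise reproducible.

The CNN engine is written in NumPy (im2col convolution with analytic
backprop, verified against central-difference numerical gradients in the
test suite). It is CPU-oriented, so tests and the acceptance script run
*scaled* topologies produced by `scale_architecture`: 64×64 input,
quarter-width channels, 64-dim embeddings; layers that no longer fit the
shrunken activations are dropped while the layer pattern is preserved.
Scaled runs train 200 iterations at learning rate 1e-3 — the standard
compensation for cutting the iteration budget 15-fold; the full-scale
defaults in `TrainOptions` are unchanged.

## HASC

Six low-level maps per pixel: intensity, |∂x|, |∂y|, |∂xx|, |∂yy|, and
gradient magnitude (central differences). The published description fixes
only the depth d = 6, not the map set; this is the conventional
HASC-style choice. EMI entries are plug-in estimates from joint 2D
histograms — 28 equal-width bins by default, exactly as printed (the
figure may be a typeset 2⁸; the bin count is configurable), natural
logarithm, empty bins contributing zero, degenerate (constant) vectors
assigned to the first bin. COV uses the unbiased n−1 denominator. The
descriptor is the concatenation of vectorized EMI and COV (2d² = 72
numbers); the HASC *image* tiles the maps as a 3-row × 2-column mosaic
and bilinearly resizes it to the network input (224 default). HASC is
always extracted from the whole image; patch-wise extraction is out of
scope.

## Synthetic data

The generator emulates the band/harmonic structure of audio spectrograms:
each class owns a fundamental frequency (2 + 3·label cycles/image) and an
orientation (label·π/8); an image is a 3-harmonic stack at that
fundamental with per-image random phases, amplitude-modulated by a slow
random envelope, scaled by `separation`, plus i.i.d. Gaussian noise
(`noise_sd`). Defaults: 3 classes × 40 images, 64×64, separation 2.0,
noise 0.3. At separation 0 the class-conditional distributions coincide
exactly, giving a built-in negative control. What the generator does *not*
emulate: nonstationary noise, class-dependent duration/energy envelopes,
inter-recording variability, or the label noise of real bioacoustic
archives — passing tests demonstrate that the pipeline recovers planted
texture structure, not field performance on real spectrograms.

## Numerical choices and degenerate inputs

- Sigmoid outputs are clamped into the open interval (0,1) so projection
  vectors honor their range contract even at saturated logits; BCE clips
  scores 1e-12 from the boundaries.
- Max pooling uses stride = pool size and crops the remainder (215 → 107
  under a 2×2 pool), matching the published activation tables.
- k-means: squared-Euclidean distances; empty clusters re-seeded from the
  point farthest from its centroid; convergence on stable assignments or
  300 iterations; the objective trace is asserted non-increasing on every
  run (tolerance 1e-8 relative).
- z-normalization uses the population sd (ddof = 0); a zero-sd reference
  yields all-zero scores with a warning rather than an error.
- One-vs-all AUC gives ties half credit; classes absent from the truth
  vector are skipped with a warning. Wilcoxon comparisons drop zero
  differences by default (Pratt variant available); an all-zero difference
  vector returns a flagged degenerate result.

## Problem sizes

The test suite and acceptance script use: 2–3 classes × 40 images at
64×64 for training runs (200 iterations, scaled topology 3), kc = 3
prototypes per class, 300 held-out pairs for AUC, and 100-point two-blob
sets for k-means recovery. These sizes were chosen as the smallest at
which the qualitative claims (pair AUC, class recovery, chance-level
control) are stable across seeds.

## Known limitations

- Full-scale (224×224, 3000-iteration, 24–32 member) ensemble training is
  out of reach of the NumPy engine in reasonable time; published
  benchmark accuracies on the real datasets are therefore not reproduced
  here, only the architecture/ensemble arithmetic and the behavioral
  properties of each stage.
- Fine-tuned CNN baselines (GoogleNet/VGG variants) are not
  re-implemented; their score matrices can be ingested from CSV for
  weighted fusion.
- A ResNet50 backbone is deliberately absent (reported non-convergent for
  this task).
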