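# Methods

## The problem and the model

A micro-CT scan of a fossil still embedded in rock is a stack of
grayscale slices in which fossilized bone and matrix differ only subtly
in attenuation.  The goal is a binary mask per slice (1 = fossil,
0 = matrix/air).  `paleoseg` treats this as 2-D semantic segmentation
with a UNet: a convolutional encoder downsamples the slice through a
ladder of channel widths, a decoder upsamples back through a configured
channel ladder with skip connections from each encoder resolution, and a
1×1 head produces a per-pixel fossil logit.  Inputs are either the single
slice (1 channel) or the slice plus its two axial neighbours ("2.5D",
3 channels), which gives the 2-D model limited through-plane context; at
stack ends the missing neighbour is edge-replicated.

The central economy of the workflow is annotation sparsity.  Training
data are the masks of every *N*-th slice across the visible fossil
extent, plus declared fossil-free slice ranges.  Each training epoch is a
complete pass through the sample universe: one random crop per annotated
training slice, constructed so it contains at least one fossil pixel
(pick a fossil pixel uniformly, then a crop origin uniformly among the
in-bounds origins covering it — every fossil pixel has nonzero sampling
mass), plus a fixed number (default 2) of crops from the fossil-free
ranges whose target masks are all-zero by construction.  The fixed
negative count is deliberate: it balances exposure to bare matrix without
letting the huge number of fossil-free slices swamp the positives.

## Training

* **Loss** — mean binary cross-entropy on the per-pixel probabilities
  (computed from logits in a numerically stable form).
* **Optimizer** — AdamW (decoupled weight decay 0.01, β = 0.9/0.999).
  Encoder parameters train at 0.1× the scheduled rate; this mirrors the
  reference protocol, where the factor protects a pretrained encoder.
* **Schedule** — the linear-scaling heuristic `lr₀ = 0.01·batch/256`
  (0.0003125 at the reference batch of 8), a linear warmup from zero over
  the first 10 epochs, then cosine annealing to zero:
  `lr(e) = lr₀·(1 + cos(π(e−W)/(E−W)))/2`.
* **Augmentation** — each crop gets a random rotation in [0°, 360°) and
  independent horizontal/vertical flips, applied identically to image and
  mask.  Quarter-turn angles are exact index permutations; other angles
  use bilinear resampling for the image, nearest-neighbour for the mask
  (masks stay binary), and fill rotated-in corners with the matrix
  intensity level rather than black, which a scanner never produces.
  Augmentation applies to training crops only.
* **Validation** — after every epoch the single held-out annotated slice
  (by default the "simplest" ROI: fewest positive pixels, ties to the
  lowest index) is predicted in full, without TTA, and thresholded; the
  weights with the best validation Dice are kept.  Two empty masks score
  Dice 1 — an empty prediction of an empty slice is perfect, which
  matters for fossil-free slices.
* **Determinism** — all randomness (init, sampling, shuffling,
  augmentation) derives from one seed; with `mixed_precision` off the
  whole train/predict path is bitwise reproducible on one device.

### Engine

The network, backpropagation and optimizer are implemented directly on
NumPy (`paleoseg.nn`): im2col convolutions executed as BLAS matrix
products, GroupNorm, ReLU, 2× max-pool / nearest-upsample, with
hand-derived gradients (verified against finite differences in the test
suite).  `mixed_precision` selects float32 compute instead of float64.
This keeps the package free of accelerator dependencies and makes the
desk-scale problem train in about a minute per run on one CPU core.

Two output-layer choices matter at small step budgets.  The head is
zero-initialized with a bias at the sparse-target base rate, so the model
starts as a base-rate predictor instead of a randomly confident one.  And
the head logits carry a fixed gain (16): decoder features are
group-normalized to O(1), so raw head logits can only grow as fast as the
head weights move, and a short cosine schedule at `lr₀ = 3.125e-4` moves
each coordinate by at most Σ lr ≈ 0.06 — far too little for confident
predictions.  The gain is part of the architecture (the same device as
the scale factor in cosine-margin classifiers); reference-scale runs with
thousands of epochs do not need it but are not hurt by it.

## Inference

Full slices are predicted at once (no tiling at desk scale; an
overlap-tiling mode exists for memory-bound volumes).  Test-time
augmentation enumerates the 8-element dihedral group of the square as
exact index permutations, predicts each variant, realigns each
probability map through the inverse permutation, and averages **in
probability space before thresholding** (threshold 0.5, ≥ convention);
soft averaging uses the full information in the eight maps, where
majority voting would discard calibration.  Non-square slices are
symmetrically zero-padded to a square for the symmetry transforms and
cropped back.

## Refinement (iteration 2)

The midpoints of consecutive annotated slices are added — in practice by
hand-correcting the model's own predictions, which is much faster than
painting from scratch — plus the trailing half-step indices, so the
refined plan equals an every-(*N*/2)-th selection over the same extent
(9 slices become 18 in the reference protocol).  Refinement never removes
indices and preserves the validation holdout; a fresh model is trained on
the denser plan.  On phantoms, ground truth plays the human corrector.

## The phantom generator

`paleoseg.phantom` renders the features that make real fossil CT hard,
with exact ground truth:

| parameter | default | meaning |
| --- | --- | --- |
| `n_slices, height, width` | 96, 192, 192 | desk-scale volume |
| `matrix_level` | 0.40 | mean matrix intensity (normalized units) |
| `contrast` | 0.25 | fossil − matrix intensity difference |
| `noise_sigma` | 0.05 | additive Gaussian noise σ |
| `n_tubes`, `n_plates` | 2, 2 | hollow tubes (long bones), thin tilted plates |
| `strut_density` | 0.15 | chord-like struts crossing tube interiors |
| `foramen_width_vox` | 13 | channel through one tube wall (130 µm at 10 µm voxels) |
| `empty_margin` | 10 | fossil-free slices at each stack end |
| `ring/streak_artefact` | off | concentric sinusoidal bands / bright lines |

Structures are analytic solids voxelized on the grid, so masks are exact
and Dice accounting has no annotation noise.  Noise is added after
rendering; artefacts perturb intensities only, never masks.  One shared
generator seeded per volume draws in a fixed order (tubes, plates,
struts, noise, artefact phases), making a (params, seed) pair a pure
function of its output.  The defaults put per-slice fossil fractions in
the sparse band (0.5–20 %) and set contrast at 5× the noise σ, where a
global threshold already recovers ≥ 90 % of fossil voxels — the learning
problem is solvable by construction, so a failing model indicts the
pipeline, not the data.

What the phantom does **not** emulate: beam hardening, partial-volume
blur at structure boundaries, texture inside bone and matrix,
eroded-cortex trabecular surfaces, and annotation disagreement.  Passing
desk-scale tests therefore demonstrates that the pipeline's mechanics
(sampling, training, TTA, refinement bookkeeping) work and that the model
can learn a low-contrast boundary under noise; it does not certify
performance on real synchrotron data.

## Desk-scale configuration

The reference protocol (crop 512, batch 8, 5000 epochs, decoder channels
[512, 256, 128, 64, 32], EfficientNet-V2 encoders, ~10 h GPU training) is
scaled to a laptop-sized analogue that exercises the identical code path:
crop 64, batch 8, 200 epochs, a 3-level "tiny" encoder (widths 8/16/32),
decoder channels [32, 16].  With the default phantom, every-10th-slice
plans and three seeds, iteration-1 held-out Dice lands around 0.92–0.97
and midpoint refinement does not reduce it — the desk analogue of the
reference workflow's improvement from 0.93 to 0.96.

Aggregate stack scores are reported two ways: the mean of per-slice Dice
values (harsh on slices whose truth is a handful of plate pixels, where
one missed pixel swings the slice score) and pooled-counts Dice over all
pixels (dominated by the large structures).  Both are logged; neither is
"the" number alone.

## Numerical choices and edge cases

* Intensity normalization is fixed per bit depth (v / (2^depth − 1)), not
  per-slice min-max, so contrast is stationary along the stack axis.
* Slice indexing is 0-based; filename numbers map to indices at read
  time; masks may cover any subset of slices.
* Written masks are 8-bit, 1 → 255 (white fossil on black), and
  round-trip bit-exactly.
* Probabilities are clamped by ε = 1e-7 in the probability-space BCE;
  the training path works on logits and needs no clamp.
* Pooling ties split the gradient evenly among tied maxima.
* Inputs not divisible by the UNet's stride are edge-padded and cropped
  back.
* Empty negative ranges: the epoch schedule still lists negative items,
  but the trainer drops them and trains positives-only.
* Divergence (non-finite loss) raises with epoch context rather than
  being clipped away.

## Known limitations

* 2-D (or 2.5D) only; no native 3-D context beyond neighbour slices.
* The CPU engine is two dtypes and one device; no multi-GPU, no true
  automatic mixed-precision loss scaling.
* The encoder registry holds small scratch-trained backbones; encoder
  names are pluggable but pretrained weights are out of scope.
* The phantom's artefact models are stylized (sinusoidal rings, straight
  streaks), intended to exercise failure modes, not to simulate physics.
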