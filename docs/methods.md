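# Methods

## Problem and model

`lesionfusion` implements a seven-class dermoscopic skin-lesion classifier
(actinic keratosis/intraepithelial carcinoma, basal cell carcinoma, benign
keratosis, dermatofibroma, melanoma, melanocytic nevus, vascular lesion;
class indices 0–6 in that fixed order) built from two parallel
convolutional feature streams whose outputs are fused and pooled before a
softmax head:

- **DenseNet-121 stream.** The canonical densely connected trunk: a 7×7
  stride-2 stem (64 channels), 3×3 stride-2 max pool, four dense blocks of
  6/12/24/16 bottleneck layers (1×1 to 4·growth, then 3×3 to growth = 32
  channels), and 1×1 transitions with 0.5 compression followed by 2×2
  average pooling.  The trunk ends at 7×7×1024; a 1×1 projection + ReLU
  brings it to the 768-channel interface shared with the other stream.
  Keeping the canonical trunk and projecting, rather than re-deriving a
  non-standard block-4 that lands on 768 directly, preserves a
  well-understood architecture; the projection is the only non-canonical
  element and is visible in the stage table.
- **Residual VGG-16 stream.** Five blocks of same-padded 3×3 convolutions
  (2, 2, 3, 3, 3 convs; 64-128-256-512-768 channels), each block wrapped
  in a skip path — identity when channel counts match, otherwise a 1×1
  projection — merged by elementwise addition, then ReLU and 2×2 max
  pooling.  One wrap-around skip per block is used; an extra pre-block
  skip adds nothing structurally and is omitted.  No batch normalisation
  by default (canonical VGG has none); the dense stream keeps its
  canonical batch norms.
- **Fusion head.** The two 7×7×768 maps are concatenated (1536 channels)
  and passed through a multireceptive-field block: parallel same-padded
  3×3, 5×5 and 7×7 convolutions of 512 channels each, concatenated back to
  1536 channels and integrated by a 1×1 convolution + ReLU.  Generalized-mean
  (GeM) pooling then reduces the map to a 1536-vector, and a dense layer +
  softmax yields class probabilities.

### GeM pooling

For channel k with spatial activation set X_k,

    H_k = ( (1/|X_k|) · Σ_{x∈X_k} (x + ε)^p )^(1/p)

with a single exponent `p` shared across channels (default **p = 4**, the
value selected by the upstream hyperparameter sweep) and ε = 1e-6 added
before exponentiation so gradients stay finite at exact zeros.  `p = 1`
is average pooling and `p → ∞` approaches max pooling, so for non-negative
inputs the pooled value is sandwiched between the two and is nondecreasing
in `p` (both properties are tested).  The activations entering the pool are
post-ReLU, which the implementation enforces as a contract.  `p` is a fixed
hyperparameter, not learned; a per-channel exponent would be a
straightforward extension but is not implemented.

### Parameter budget

At the published configuration the assembly has **97.75 M** trainable
parameters (7.74 M dense stream, 22.36 M residual VGG stream, 67.65 M
fusion head — the 7×7 convolution over 1536 input channels dominates).
`count_parameters` reports the exact figure, and the acceptance script
re-measures it at run time.

## Numerical engine

No deep-learning framework is assumed: the package carries a small
reverse-mode autodiff engine (`lesionfusion.nn`) over float32 numpy
arrays with exactly the operations the model needs — convolution, max and
average pooling, batch normalisation, ReLU, concatenation, GeM pooling,
dense layers, softmax cross-entropy and Adam.  Convolutions decompose
into one GEMM per kernel row over an overlapping strided view of the
channels-last padded input, which keeps all heavy arithmetic inside BLAS
on a single CPU; 1×1 convolutions use a dedicated batched-GEMM path, and
stride-1 input gradients are computed as a correlation with the flipped,
channel-transposed kernel.  Activations are freed eagerly as the backward
sweep retires graph nodes, which bounds peak memory near the forward-pass
footprint (the full model trains on 8-image batches of 224×224 inputs in
under 3 GB at batch size 4).  Every operation is verified against central
finite differences in the test suite.

Batch-normalisation running statistics are warm-started: the first
training batch sets them outright, later batches blend in with momentum
0.9.  Without the warm start, short runs (tens of updates) leave the
statistics biased toward their zero-mean/unit-variance initialisation,
and eval-mode predictions lag the train-mode fit.

## Preprocessing

- **Resize**: bilinear, no aspect-ratio padding, to 224×224.
- **Hair removal**: ITU-R 601 luminance → morphological black-hat
  (closing − image) with a 17×17 rectangular structuring element → mask at
  threshold 10/255 → inpainting.  The element size targets hairs thinner
  than ~8 px at 224² resolution; broad lesion structure survives the
  closing and is not flagged.  All three values are configuration, not
  constants.
- **Inpainting**: masked pixels are filled in increasing distance from
  the known region (the fast-marching front order, obtained from a
  Euclidean distance transform) with the inverse-distance weighted
  average of already-known neighbours within a (radius+1)-Chebyshev
  window, radius 1 by default.  Unmasked pixels are returned
  bit-identical; an all-ones mask is rejected as degenerate.
- **Augmentation**: rotation (±180°), shift (±10%), zoom (0.9–1.1),
  shear (±10°, the "random transforming" of the six-operation family),
  horizontal/vertical flips (probability 0.5), then resize — applied in
  that fixed order about the image centre with reflect padding, fully
  seeded.
- **Split**: stratified per class at 7:2:1 with largest-remainder
  rounding, seeded shuffling, and an optional per-class override table.
  The override exists because the reference dataset division this package
  reproduces is not an exact 70/20/10 split of each class and its rounding
  rule is unrecoverable; with the override the published per-class counts
  (train/test/val totals 7020/1998/997 over 10 015 images) are reproduced
  verbatim.
- **Balancing**: each minority class of the training split is raised to a
  target (by default the majority-class count; optionally the published
  augmented totals, 34 946 training rows) by appending augmented copies
  round-robin over the class's originals, so original usage differs by at
  most one.  Only train rows are added, always flagged `is_augmented`.

## Synthetic dermoscopy generator

The generator exists so every stage is testable without any download.  It
emulates, per image: a sampled skin-tone background with a soft
illumination gradient and fine noise; one elliptical lesion whose boundary
radius is modulated by a sum of low-order sinusoids scaled by a per-class
*border irregularity*, filled with a class-dependent HSV colour and
multiplied by smooth value-noise mottling scaled by a per-class *texture
amplitude*; and, with configurable probability, 2–6 dark quadratic-Bézier
hair strokes of width 1–3 px and intensity 30–80.  Class palettes follow
dermatological appearance (melanoma dark and irregular, nevus uniform tan,
vascular lesions red-purple, keratoses textured, …), which gives a colour/
texture signal a classifier can genuinely learn: a nearest-centroid
classifier on mean lesion RGB reaches ~92% on held-out generated images.
Everything is a pure function of (class, config seed, image seed).

What the generator does **not** model: rulers, gel bubbles, ink markings,
vignetting, specular highlights, multi-lesion fields, or the true
morphological taxonomy of lesions.  Consequently, passing tests show the
pipeline's machinery is correct (shapes, gradients, bookkeeping, hair
recovery, learnability, localisation), not that the model reaches any
particular accuracy on real dermoscopy.  A genuinely realistic note: hair
detection degrades on the darkest (melanoma-like) lesions because dark
hair loses contrast there — pooled coverage over a mixed-class batch stays
well above the acceptance floor, but per-image coverage on dark lesions
can drop below it, exactly as with real black-hat dehairing.

## Training protocol

Adam (the optimiser is configuration; the upstream protocol names none),
categorical cross-entropy, batch size 16, initial learning rate 1e-4,
multiplied by 0.1 when validation loss fails to improve for `lr_patience`
(3) epochs — "reduce on plateau"; a fixed-epoch schedule can be emulated by
setting the patience accordingly — early stop after 5 non-improving
epochs, 28-epoch cap, best-validation weights restored on return.  The
28 epochs are treated as a cap with early stopping active, since both
readings of the protocol are defensible; either behaviour is reachable
through the config.  Class weighting is deliberately absent: imbalance is
handled upstream by augmentation-based balancing.

Desk-scale problem sizes used by the tests and the acceptance script:
the end-to-end smoke run trains the **full 224-input architecture** on 8
synthetic images (4 nevus, 4 vascular) at batch size 4 and learning rate
1e-4 with patience disabled, stopping when training accuracy reaches 100%
(typically ~10 epochs, ≈10 CPU-minutes); unit tests of the training loop
use a structurally identical reduced model (32-px input, slim channels)
that trains in seconds.  Grad-CAM on the memorised images is computed at
the fused (multireceptive-field output) layer by differentiating the class
score with respect to that layer only — the head is replayed on a detached
copy of the activations, so no backward pass through the streams is
needed.

## Classification service

A stateless flow: read RGB image (non-RGB input is an error, not silently
converted), resize to the model input, forward pass, softmax.  If the
maximum probability is **strictly below 0.9** the result status is
`reupload_requested`; at or exactly on the threshold it is `accepted`.
The threshold is global across classes (a per-class override can be
passed), and elapsed time covers the forward pass only.  Batch mode
summarises per-group success rates and the most-confused lesion class
from the off-diagonal of the batch confusion tally.

## Known limitations

- The engine is single-CPU numpy; it is fast enough for desk-scale runs
  (one full-model training step at batch 4 ≈ 30 s) but not for training on
  a real dermoscopy corpus.
- Max-pool backward routes gradient to every window position tied at the
  maximum; exact ties occur essentially only on zero plateaus, where the
  preceding ReLU's gradient mask annihilates the duplicates.
- `inpaint_hair` is O(masked pixels × window); fine for hair masks (a few
  thousand pixels), not meant for large occlusions.
- Determinism is guaranteed for a fixed platform/BLAS; bit-identical
  results across different BLAS builds are not promised.
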