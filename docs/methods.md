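# Methods

## Architecture

The segmentation model is a nested, densely skip-connected
encoder-decoder.  Blocks live on a triangular grid $X^{(m,n)}$ with
pyramid level $m \in [0, d]$ and pathway column $n \in [0, d-m]$
($d$ = 4 by default, base filters $[32, 64, 128, 256, 512]$, one filter
count per level).  Column 0 is the encoder; the input image feeds
$X^{(0,0)}$ and each deeper encoder block convolves the 2×2/stride-2
max-pool of the block above.  A block $X^{(m,n)}$, $n>0$, convolves the
channel concatenation of all same-level predecessors plus one up-sampled
input from $X^{(m+1,n-1)}$, concatenated in column order with the
up-sampled tensor last.  The up edge is a 2×2/stride-2 transposed
convolution that maps $f_{m+1} \to f_m$ channels (halving the feature
count, as in the classic U-shaped decoder); a parameter-light
nearest-neighbour-upsample + 1×1-conv alternative can be selected per
configuration.  All 3×3 convolutions are stride 1 with symmetric
padding; down-sampling happens *only* in the max-pool edges, since
stride-2 convolutions combined with stride-2 pooling would collapse the
pyramid geometry.

### Recurrent-residual blocks

Each block is an RRCL: two stacked RCLs with an additive shortcut from
the block input, projected by a learned 1×1 convolution exactly when the
input and output channel counts differ (they always differ in the nested
graph, where concatenated inputs are wider than the block output).  The
RCL unfolding is taken literally from its recurrence: step 1 is the
feed-forward convolution of the block input; step $k>1$ adds a recurrent
convolution of the previous step's output to the *same* feed-forward
response.  The feed-forward kernel is shared across steps; each
recurrent step owns fresh weights, giving $t$ convolution weight sets
per RCL.  This unfolding is the one consistent with the published
parameter table, where moving from $t=1$ to $t=2$ roughly doubles the
3×3 kernel count (9.7 M → 18 M for the full model); sharing all weights
across the unroll, or giving the unroll $t+1$ kernels, would not
reproduce that ratio.  Order of operations is convolution → batch
normalization → ReLU, with one normalization per unfolded step.

Batch normalization uses per-channel statistics with train/eval mode
switching, stabilizer $\epsilon = 10^{-5}$ and running-statistics
retention factor 0.9 (i.e. `running = 0.9*running + 0.1*batch`).  The
relatively fast retention is chosen so that short CPU-scale trainings
produce usable inference-mode statistics; both constants live in
`BatchNorm2d` and are part of the documented configuration.

### Heads, deep supervision, pruning, ensembling

With deep supervision, a 1×1 convolution + sigmoid head is attached at
every $X^{(0,q)}$, $q = 1..d$ (softmax over $C$ filters when $C>1$);
without it, a single head sits at $X^{(0,d)}$ — in that variant no
decoder weight is orphaned, because the full triangular graph feeds the
deepest head.  The depth-$q$ sub-model is the node set
$\{(m,n): m+n \le q\}$; `extract_pruned` returns a view sharing the
parent's weight tensors, so its output is bit-for-bit the parent's head
$q$ in eval mode (asserted in the tests).  `ensemble_predict` averages
the supervised heads' probability maps; averaging is order-invariant by
construction.

### Baselines

U-Net and R2U-Net share a straight U-shaped topology (encoder chain,
single skip concatenation per level, one head); U-Net++ shares the
nested topology.  Plain blocks are two conv+BN+ReLU stages; R2U-Net
uses the RRCL blocks.  Under these choices the exact trainable-scalar
counts at full size are:

* U-Net 7,765,409; R2U-Net(t=2) 15,975,937; U-Net++ 9,048,996;
  R2U++(t=1) 9,489,124; R2U++(t=2) 17,849,764.

U-Net++ (9.0 M) and R2U++ at $t=2$ (18 M at two significant figures)
match the published architecture table exactly; the remaining three
entries (published as 7.0, 16.7 and 9.7 M) are not reproduced by any
decoder variant provided here (transposed-conv, or upsample + 1×1 conv,
which gives 7.24 M for U-Net), and we report the per-component
breakdown (`summary_text`, `r2upp count-params --summary`) alongside the
measured totals.  The enumerated counts are themselves cross-checked in
the tests against an independent closed-form sum over the graph.

## Loss

The per-head loss sums a pixel-wise cross-entropy and a *per-pixel* soft
Dice reward over classes and pixels, normalized by the pixel count.  Two
deliberate choices:

* **Cross-entropy completion.** For a single sigmoid class the
  cross-entropy term is the full binary form
  $y\log p + (1-y)\log(1-p)$.  The one-sided form $y \log p$ (the
  literal one-hot sum at $C=1$) assigns zero loss to every background
  pixel, making "everything foreground" a global optimum — we verified
  empirically that training then collapses to the all-ones mask.  The
  completion changes none of the loss's anchor values: a perfect
  all-foreground prediction scores $-1$ per class, a perfect
  all-background prediction $0$ (up to the probability floor), and the
  single-pixel case $y=1, p=0.5$ scores $-(\ln 0.5 + 0.8) = -0.1069$.
  With $C>1$ one-hot classes the categorical sum is kept as-is, since
  the background is then covered by its own class.
* **Per-pixel dice summand.** The Dice term is evaluated inside the
  double sum, $2yp/(y^2+p^2)$ per pixel and class, with the $y=p=0$
  singularity defined as 0 by continuity.  This differs from the
  conventional per-image ratio of sums; that variant is available via
  `LossConfig(dice_mode="per_image")` but the per-pixel form is the
  default.

Numerics: probabilities are clamped to $[10^{-7}, 1-10^{-7}]$ inside the
logs only; the dice summand uses the raw probability.  The total loss is
linear in the head weights $\eta$ (all 1 by default).

## Metrics

Dice, IoU, accuracy, sensitivity and specificity are computed from the
pixel confusion counts of binarized predictions (threshold 0.5,
`>=` on the boundary).  Conventions for empty denominators: two empty
masks give Dice = IoU = 1; sensitivity with a positive-free ground truth
(and symmetrically specificity) is 1 — this rewards correct all-negative
predictions, matching common segmentation tooling.  Dice and IoU obey
$\mathrm{Dice} = 2\,\mathrm{IoU}/(1+\mathrm{IoU})$, which the tests
assert to machine precision on randomized masks.  Multi-class inputs are
scored per class and macro-averaged.

## Patch pipeline

Coordinates are 0-based and half-open everywhere; under this convention
the retinal-protocol crop rows $[19, 554)$ × cols $[29, 564)$ of a
584×565 image yields exactly 535×535 (a 1-based inclusive reading would
give 536).  Sliding-window grids use the floor rule
$\lfloor (H-\text{patch})/\text{stride} \rfloor + 1$ positions per axis
with no end-anchored extra window — the rule forced by the published
patch total $154{,}880 = 20 \times 88^2$ at patch 96 / stride 5 on
535×535 images.  That rule leaves a 4-pixel uncovered margin in this
geometry, which `coverage_report` quantifies.  Full-image inference is
handled separately from the counting rule: the image is reflect-padded
so the grid covers every pixel, per-patch predictions are averaged over
overlaps, and the padding is cut off.  Masks binarize as nonzero →
foreground on load (datasets of this kind store 0/255); intensities
scale to $[0,1]$ by dtype range.

## Synthetic data

The generator emulates the *structural* regimes of four biomedical
segmentation settings at toy scale: Voronoi cell interiors with thin
dark boundaries (electron-microscopy-like), thresholded correlated
Gaussian fields (diffuse CT-lesion-like), two wobbled elliptical lobes
(chest-radiograph-like), and biased-random-walk strokes of 1–4 px width
(retinal-vessel-like).  Images are rendered from the mask by
distance-transform shading plus a 1 px Gaussian blur (so the image is
not trivially thresholdable at 0.5) and corrupted with Gaussian noise of
configurable sd.  Foreground fractions are controlled per style
(defaults: membranes 0.55–0.97, blobs 0.08–0.45, lobes 0.2–0.6, vessels
0.01–0.2) with bounded resampling; an unsatisfiable range raises an
error naming the constraint.  Each record draws from
`default_rng([seed, index])`, so datasets are bit-reproducible and
records are stable under dataset growth.  The multiscale variant places
at least one disjoint object per scale bin (default: three equal-width
bins spanning the object-scale range) and returns per-record
connected-component size histograms; object scale is measured as the
component bounding-box long side over the image size.

What the generator does **not** model: modality physics (CT attenuation,
fundus color), anatomical shape priors, annotation noise, or class
co-occurrence structure.  Passing tests on these tasks demonstrates
that the architecture, loss, optimization and pipeline are implemented
correctly and can fit coherent structure — not that the model reaches
any particular accuracy on real clinical data.

## Training protocol

Adam (lr 3e-4, β = 0.9/0.999), batch size 16 by default, early stopping
on the validation total loss with patience 10 and min-delta 0, restoring
the best-validation weights.  The learning rate is allowed to be 0 so a
frozen optimizer is expressible (useful for pinning early-stop
semantics: with nothing changing, patience 1 halts after exactly two
epochs).  Weight initialization is He-uniform over the fan-in for
convolutions, zero biases, unit/zero normalization scale/shift —
documented because identity- and parameter-recovery tests depend on it.
`run_trials` re-initializes weights with seed = base + trial index while
holding the dataset and its record-level split fixed, and reports each
metric as mean ± sample sd (ddof 1; sd = 0 for a single trial by
convention).

Problem sizes used by the shipped experiments were chosen for
single-CPU execution: the end-to-end property trains a depth-4 network
with base filters $[8, 16, 32, 64, 128]$ on 200 noise-free 64×64 blob
images for up to 8 epochs (batch 8), which reaches a mean held-out Dice
of ≈ 0.97, and the remaining tests use depth-2 networks on 16–32 px
images.

## Autodiff engine

Absent any deep-learning framework dependency, the package ships a
minimal reverse-mode autodiff engine on NCHW numpy arrays implementing
exactly the operations the networks need: stride-1 'same' convolution
(im2col + BLAS matmul; columns recomputed in the backward pass instead
of cached, to bound peak memory), 2×2/stride-2 transposed convolution,
2×2 max-pooling (argmax scatter), batch normalization (with full
backprop through the batch statistics in train mode), ReLU, sigmoid,
channel-softmax, nearest-neighbour upsampling, channel concatenation and
addition, plus the hybrid loss with an analytic gradient.  Every
backward pass is verified against central finite differences in
`tests/test_autodiff.py`.  Inference runs under a no-grad context that
skips graph construction.

## Known limitations

* CPU-only and numpy-bound: full-size (18 M parameter) training is not
  practical here; the full-size network is used for parameter accounting
  and structural checks, scaled-down variants for training.
* Single-channel input is the tested path; the multi-class (softmax)
  head and per-image dice variant are implemented but exercised only at
  unit level.
* The per-pixel dice summand (the default, matching the printed loss)
  has a weaker class-imbalance correction than the per-image soft Dice.
* No data augmentation, atrous/attention variants, or 3-D convolutions.
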