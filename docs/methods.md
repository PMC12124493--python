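# Methods

## The model

`kaizen` segments fluorescence micrographs into individual cells by
*decomposition* rather than pixel classification. The idea borrows from
predictive coding: the system maintains an **internal image** `P` — its
current reconstruction of the scene as a composite of single-cell
hypotheses — next to the external input `I`, and works only on the
**error image** `E = I − P`.

Two components implement this:

1. **A single-cell generative predictor.** A vector-quantized autoencoder
   is trained on square patches cut from annotated micrographs. The target
   for a patch is the input multiplied by the mask of the instance touching
   the patch's central pixel; 20% of training patches are sampled with a
   background center and an all-zero target, so the model learns *not* to
   hallucinate a cell where there is none. After training, the network maps
   any patch to an image of just its central cell.

2. **An error-driven acceptance loop.** Starting from `P = 0`, each
   iteration (i) convolves `E` with a 7×7 kernel of ones and proposes up to
   `N` locations by repeatedly taking the maximum of that map and zeroing a
   32×32 window around it; (ii) asks the predictor for a single-cell image
   at each location; (iii) merges each candidate into `P` (pointwise max)
   and keeps it only if the global mean absolute error strictly decreases.
   The loop ends when an iteration accepts nothing or after `max_iter`
   iterations. Inference then repeats in **passes**: the residual error
   (clamped at zero, re-padded) becomes the predictor's input for the next
   pass, while acceptance is still judged against the original image, so
   cells hidden behind early mistakes get re-proposed and the global loss
   is non-increasing by construction.

Accepted objects are converted to an instance segmentation by thresholding
at 10% of the input image's mean intensity, removing masks smaller than
20 pixels (for two-channel cytoplasm+nucleus data: fewer than 20 nucleus
pixels or fewer than 1 cytoplasm pixel), and assigning contested pixels to
the mask with the highest predicted intensity. Evaluation uses per-image
`AP_τ = TP/(TP+FN+FP)` with one-to-one greedy matching at IoU strictly
above τ, averaged over images.

## Network architecture and shape choices

Encoder: three 4×4 stride-2 convolutions, a 4×4 stride-1 convolution, a
3×3 stride-1 convolution, two residual blocks (ReLU → 3×3 conv → ReLU →
1×1 conv with identity skip), and a 1×1 projection to the embedding
dimension `D`. Decoder: a 1×1 expansion from `D`, a 4×4 stride-1
convolution, two residual blocks, three 4×4 stride-2 transposed
convolutions, and a 3×3 stride-1 transposed convolution emitting a linear
single-channel output (clamped to ≥ 0 only at predict time). The codebook
holds `K` vectors of dimension `D`, updated by exponential moving averages
of the assigned encoder outputs (decay 0.99, Laplace smoothing 1e−5,
dead codes with usage below 1e−3 reseeded from batch latents); the encoder
receives the straight-through gradient plus a commitment pull with weight
β = 0.25.

A 4×4 stride-1 window cannot preserve its input size with symmetric
integer padding, and three stride-2 transposed 4×4 convolutions only
invert three stride-2 convolutions for particular paddings. We keep all
stated strides, window sizes and unit counts and fix per-layer paddings so
that encode→decode is exactly shape-preserving for every patch size
divisible by 8: stride-2 (transposed) convolutions use padding 1, 4×4
stride-1 layers use asymmetric padding (1, 2), 3×3 stride-1 layers use
padding 1. A 40-pixel patch yields a 5×5 latent grid; 32 → 4×4;
120 → 15×15.

Inter-layer activations are LeakyReLU with slope 0.01; the residual
blocks' internal activations are plain ReLU. The leak matters: with hard
ReLUs between layers, sign-gradient L1 training on sparse targets can
permanently kill every decoder unit (see below).

The layers themselves are a compact NumPy implementation (channels-last
im2col + BLAS matrix products; the transposed convolution is the exact
adjoint of the convolution, which the test suite verifies both by inner
products and by finite differences). Training runs in float32; the default
float64 is used wherever gradients are checked numerically.

## Optimization schedule

The reconstruction objective is the L1 loss, minimized with Adam
(full-scale default learning rate 1e−4, batch 32, 500,000 steps). Pure L1
training from a cold start is fragile on this task: targets are ~85% zeros,
so the pixelwise L1 median of an uninformed model is the all-zero image,
and Adam turns the constant-magnitude sign gradients into aggressive
uniform parameter steps that reach that degenerate optimum before the
latent bottleneck becomes informative — after which no gradient
distinguishes inputs. We therefore train the first `warmup_steps`
(default 300) batches with a quadratic penalty, whose error-proportional
gradients keep the informative initialization alive, and switch to the L1
objective for all remaining steps. At full scale this warm-up covers 0.06%
of training; at toy scale (3,000 steps) it is the difference between a
held-out L1 of ~0.1× and 1.0× the zero-predictor baseline.

The toy configuration used throughout the tests is patch 32, K = 32,
channels (32, 32, 64) / decoder (32, 32, 32), residual width 16, learning
rate 1e−3, 3,000 steps — it trains in a few minutes on one CPU core. The
full-scale configuration (patch 40 or 120, K = 128, channels 64/64/128,
learning rate 1e−4, 500,000 steps) remains the default of `VQVAEConfig`.

## Synthetic scenes: what they emulate and what they do not

`fixtures.generate_scene` renders nuclei-style micrographs: `n_cells`
rotated ellipses (radius 4.5–9 px, axis ratio 0.6–1.0) with a radially
decaying intensity profile — peak 0.5–1.0 at the center, 50% of peak at
the rim — on a dark background with additive Gaussian noise (σ = 0.02 by
default), clipped to [0, 1]. The decaying profile makes the 10%-of-mean
binarization threshold a nontrivial operation rather than a mask copy.
Cell centers are rejection-sampled with a minimum pairwise separation
(default `2·r_max + 2`, guaranteeing disjoint cells; `touching=True`
allows near-adjacent cells) and a radius range chosen so that the densest
default scenes (15 cells in 128×128) remain reliably placeable. A
two-channel mode adds a concentric dimmer cytoplasm ellipse at 1.6× the
nucleus radius for the per-channel filter rule.

Cells are additionally kept `border_clearance = 9` px clear of the frame
edge. The engine's loss is defined over the *padded* image, and reflect
padding (which excludes the edge pixel, hence 9 not 8) would duplicate the
mass of any cell lying in the 8-px mirror band; that duplicated mass is
not claimable by any feasible patch anchor, so the exact-completeness
property (final loss → 0 under the ground-truth oracle) holds only for
scenes clear of the band. Set `border_clearance=0` to study border cells.

What passing tests on these scenes does **not** show: robustness to real
microscopy nuisance (point-spread blur, shot noise, uneven illumination,
debris), to strongly overlapping or irregularly shaped cells, or to
annotation noise. The generator is a test harness for the *machinery* —
training-target construction, the acceptance loop, the mask pipeline, the
metric — not a claim about biological realism.

The `OraclePredictor` returns the exact ground-truth central cell (the
image masked by the instance under the patch center). It isolates the
engine from model quality: with it, the loop must recover every cell of a
noiseless scene to machine precision, and the whole pipeline must score
AP 1.0.

## Numerical and procedural choices

* **Normalization**: percentile clip (0.1, 99.9) then min-max to [0, 1],
  per image; robust to hot pixels. Constant images map to zeros.
* **Center convention**: the "central pixel" of an even patch is index
  `(ps/2, ps/2)`, used consistently by sampling, oracle and engine.
  "Touching the center" means `labels[center] != 0`, with no dilation.
* **Padding**: each side is padded by `ps/2` — 8 px mirrored, the rest
  zeros (20 px total for patch 40, 60 for patch 120).
* **Proposals**: the 7×7 box-sum is computed with zero boundary; ties
  break to the smallest row-major index; scores ≤ 0 are never proposed; a
  maximum inside the padded border is served by the nearest anchor whose
  window fits (the 32-px window still covers the maximum). Suppression
  zeroes `[p − 16, p + 16)` and is rebuilt from the current error each
  iteration.
* **Acceptance**: Δloss is evaluated over the candidate's footprint only
  (exactly equal to the full-image difference, cheap) and must be strictly
  negative (`min_improvement = 0` by default). The merge is pointwise max:
  idempotent, so re-predicting an explained cell can never help; an
  additive merge is available for overlap-heavy data.
* **Multipass**: pass inputs are `max(E, 0)` re-padded; acceptance always
  against the original input; stop on an empty pass or after
  `max_passes = 10`.
* **Binarization**: comparison is `≥ t`; the image mean is taken on the
  normalized, unpadded image. The pipeline thresholds each object's
  *contribution* — the intensity it newly added to the internal image,
  replayed in acceptance order — rather than its raw patch. With an
  imperfect predictor, a cell is often accepted a second time to fill the
  thin residual ring the first prediction under-covered; the raw patch of
  that second acceptance is a full-size duplicate mask that fragments the
  cell during assignment, while its contribution is just the ring, which
  the standard < 20 px filter removes. For first predictions the two
  definitions coincide (`binarize_objects(mode="patch")` gives the literal
  raw-patch rule).
* **Assignment**: contested pixels go to the highest predicted intensity
  (ties to the lower mask index); the minimum-size rule is re-applied after
  overlap resolution, since a mask can shrink below it by losing pixels.
* **Matching**: IoU strictly greater than τ; greedy in descending IoU
  (ties by label pair), one-to-one. At τ ≥ 0.5 greedy matching is provably
  optimal (no two truths can both overlap one prediction at IoU > 0.5);
  the suite also checks agreement with exhaustive optimal matching on
  random maps. `AP = 1` by convention when TP = FP = FN = 0.

## Problem sizes used by the test suite and acceptance script

Oracle studies use 20 noiseless + 10 noisy 128×128 scenes with 5–15
cells. Brute-force equivalences use 50 random 64×64 error maps, 1,000
random latents against 32 codes, and 100 random instance maps with ≤ 6
objects. The training study uses 30 training and 10 held-out scenes, the
toy configuration above, and 200 held-out pairs; it accounts for nearly
all of the suite's runtime (a few minutes on one core).

## Known limitations

* The engine is greedy: an accepted wrong hypothesis is never retracted;
  the multipass scheme mitigates misses, not false merges.
* Patch-sized objects only: a cell larger than the patch (plus its mirror
  image for border cells) cannot be explained by one acceptance.
* The contribution-based binarization ties mask identity to acceptance
  order; exporting raw overlapping masks (`mode="patch"`) is the escape
  hatch for downstream tools that resolve overlaps themselves.
* Training at the 500k-step full-scale configuration is supported by the
  code but takes days in pure NumPy on one core; the package's empirical
  claims are made at toy scale only.
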