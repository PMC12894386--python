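# Methods

## Model

LightWaveNet is a compact convolutional classifier for RGB plant-disease
images built around three ideas: frequency-aware feature extraction with a
Haar wavelet convolution, dense feature reuse, and multi-stage supervision.

**Stem.** A 7×7 convolution (stride 2, 64 maps, no bias) → batch
normalization → ReLU → 3×3 max pooling (stride 2), taking a 3×H×W image to
64×H/4×W/4.

**Wavelet convolution (WTConv).** One analysis step of the orthonormal 2D
Haar transform (2×2 filters with coefficients ±0.5) splits a map into four
half-resolution subbands LL/LH/HL/HH; the filters are orthonormal, so the
transform conserves energy and inverts exactly. The subband order and sign
convention are fixed as: for a patch [[a,b],[c,d]], `ll=(a+b+c+d)/2`,
`lh=(a−b+c−d)/2` (vertical-edge response), `hl=(a+b−c−d)/2`
(horizontal-edge response), `hh=(a−b−c+d)/2`. WTConv applies a depthwise
k×k convolution to the input in the spatial domain, plus a recursive
branch: for each of `l` levels the running LL map is decomposed, the four
stacked subbands receive a depthwise k×k convolution *with bias*, the
result is rescaled per channel, and everything is folded back bottom-up
through the inverse transform (the deeper level's reconstruction is added
into the LL band before inversion). A k×k kernel at level `i` therefore
covers a 2^i·k spatial extent at level-0 resolution. Defaults: k=5, l=1.
Odd-sized maps are zero-padded to even before each analysis step and
cropped after synthesis.

**Wavelet pooling module (WPM).** Input → BN → ReLU → 1×1 convolution down
to the growth rate k (compressed feature Z) → channel split into halves.
Branch 1: WTConv(5×5) → BN → GELU (low-frequency context). Branch 2: 3×3
max pooling (stride 1, "same") → 1×1 convolution → BN → GELU
(high-frequency texture). The branches are concatenated, fused by a 1×1
convolution, and Z is added back as a residual; every WPM emits exactly k
maps. The residual target is the compressed feature Z, not the block input
— with stem width 64, stage depths (2,4,6,8), growth 32 and compression
0.5, that choice is what makes the stage widths come out at the documented
128/192/288/400.

**Dense stages and transitions.** Four stages stack 2/4/6/8 WPMs with
dense connectivity (layer i consumes the concatenation of the stage input
and all previous outputs). Between stages a transition applies BN → ReLU →
1×1 convolution keeping θ=0.5 of the channels, then halves resolution with
the element-wise *sum* of a 3×3 max pool and a 3×3 average pool (stride 2,
pad 1, average divisor counts only in-bounds cells). Stage outputs sit at
1/4, 1/8, 1/16, 1/32 of the input resolution.

**Heads.** The stage-4 output passes a final BN → ReLU, global average
pooling (400-dim vector by default) and a linear classifier. During
training only, stages 1–3 additionally feed auxiliary linear classifiers
on their globally averaged outputs (128/192/288-dim). The training
objective is

    L_total = (1 − λ)·L_main + λ·(L_aux1 + L_aux2 + L_aux3),   λ = 0.1,

with all losses cross-entropy. Inference uses the main head alone.

With the default configuration the inference network holds 279,306
learnable scalars (0.28 M); the three auxiliary heads add 6,110 more
during training.

## Numerical engine

No deep-learning framework is used: the package ships a small reverse-mode
autodiff engine over numpy (NCHW layout) with exactly the primitives the
model needs — dense and depthwise convolution (im2col / tap-loop), max and
average pooling, batch normalization, GELU/ReLU, the differentiable Haar
analysis/synthesis pair (the transform is orthogonal, so each op's adjoint
is the other op), channel concatenation/slicing, and a fused
log-softmax/cross-entropy. Every op's backward pass is verified against
float64 central differences in the test suite. Computation is float32 by
default; the engine is dtype-agnostic, which is what the gradient checks
exploit. An op-level multiply-accumulate counter provides the complexity
audit: convolutions count `N·Hout·Wout·Cout·(Cin/groups)·k²`, linear
layers `N·in·out`, and each wavelet analysis/synthesis coefficient counts
4 MACs (a 4-tap dot product); pooling, normalization and activations are
not counted. Serialized model size is reported as 4 bytes per parameter
plus persistent normalization statistic.

## Training procedure

Adam (β=(0.9, 0.999), ε=1e-8), learning rate 1e-3, batch size 32,
cross-entropy, no scheduler, no weight decay, no early stopping. The best
epoch is selected by validation accuracy and its weights restored at the
end. Data enters through a fixed 5:1:4 stratified train/validation/test
split (per-class shuffled, remainders to train); k-fold stratified
cross-validation is available as an explicit alternative mode, never
combined implicitly with the fixed split (inside each fold the non-held
portion is re-split 5:1 so model selection never touches the held-out
fold).

Two implementation details matter for short training runs:

- **Precise BN recalibration.** Momentum-averaged running statistics are a
  poor estimate of activation statistics after few optimizer steps (they
  still remember the initial weights). Before every eval-mode use inside
  the training loop, all batch-norm statistics are recomputed as the plain
  average of batch statistics over one forward sweep of the training set.
  Weights are untouched.
- **Zero-initialized classifier heads.** The main and auxiliary linear
  heads start at zero, so the initial loss is exactly ln C and the first
  gradient steps move each head along class-mean contrasts instead of
  first having to undo a random (and, for the unnormalized auxiliary
  inputs, saturated) initial state. Convolutions use Kaiming fan-out
  normal initialization; batch-norm scales start at one.

**Offline augmentation.** The preprocessing pipeline supports the
augmentation stage as an offline step on the training partition: random
rotation (±30°), horizontal/vertical flips, and brightness/contrast
factors drawn uniformly from [0.8, 1.2], with outputs clipped to [0, 1].
By default minority classes are topped up to the majority count, and small
datasets are expanded so every class reaches at least 200 training images
(`--min-per-class`); epochs then iterate over the augmented set. For
datasets with hundreds of images per class this expansion is a no-op.

## Synthetic data

The generator renders 10 (or 4) classes of 64×64 leaf/panicle scenes so
the full stack is exercisable without any external dataset. Each image
composes (i) a low-frequency silhouette — a tapered elliptical leaf blade,
or a thin curved panicle stem ending in a cluster of tan grains — over a
smoothly varying soil background, (ii) class-specific high-frequency
lesions (dark circular spots with bright chlorotic halos, axis-aligned
yellow streaks, or salt-like speckle), and (iii) i.i.d. Gaussian pixel
noise (σ=0.02 by default). All classes share one green base hue, so hue
alone cannot separate them: the default four classes form a 2×2 grid of
{leaf, panicle} × {clean, lesioned}, forcing any successful classifier to
combine the global-shape and fine-texture cues the two WPM branches are
designed for.

The classes are deliberately compact and well separated — pose, size and
lesion-count jitter are kept small — so that a small model trained for
only a few epochs (a handful of optimizer steps at desk scale) separates
them reliably; the stock 4-class set with 50 images per class reaches ≥90%
test accuracy after 5 epochs of the default recipe across seeds. That is a
pipeline-correctness statement, not a field-performance claim: real
disease imagery has orders of magnitude more appearance variation,
background clutter, and label noise, and the corresponding accuracies
require the real dataset and longer training. The generator likewise does
not emulate specular highlights, occlusion, scale variation, or
camera-level artifacts.

## Evaluation

Per-class precision/recall/F1 are computed one-vs-rest and macro-averaged
(the natural choice for imbalanced multi-class reporting); accuracy is
trace(confusion)/n. Precision or recall with a zero denominator is
reported as 0 and the affected class flagged. McNemar's paired test uses
the exact two-sided binomial on the discordant counts when b+c < 25 and
the continuity-corrected χ² otherwise. The noise-robustness sweep
re-evaluates a model after adding clipped Gaussian noise at levels
0/0.05/0.10/0.15 on the [0,1] intensity scale. Feature export returns
globally averaged stage vectors with an intra-class variance summary (mean
over classes of the mean squared deviation from the class centroid).
Grad-CAM weights the chosen stage's feature maps by the globally averaged
gradient of the target-class logit, rectifies the weighted sum, upsamples
bilinearly and min-max normalizes to [0, 1] per image (constant maps map
to zero).

## Numerical choices and degenerate inputs

- Haar filters are orthonormal (±0.5), so perfect reconstruction holds to
  1e-6 at float32 and energy conservation to 1e-5 relative.
- Max pooling pads with −∞; ties share the gradient equally. Average
  pooling divides by the count of in-bounds cells, so a constant map pools
  to the same constant everywhere (and the transition's max+avg sum maps a
  constant v to exactly 2v).
- Cross-entropy floors probabilities at 1e-12: a zero-probability true
  class yields a large finite loss, never infinity.
- Odd spatial sizes are padded to even per wavelet level and cropped after
  synthesis; maps smaller than 2×2 at any level are rejected with a
  dimension error.
- Batch-norm uses ε=1e-5 and momentum 0.1, with unbiased variance in the
  running estimate; 1-pixel batches fall back to the biased variance.
- FLOPs are reported as MACs under the convention above. Counting
  conventions differ enough across tools that cross-tool comparisons of
  absolute FLOP numbers are unreliable; parameters and serialized size are
  the stable quantities.

## Known limitations

- The engine is CPU/numpy; throughput is adequate for desk-scale
  experiments (a 224×224 forward pass takes ~1.5 s, the stock synthetic
  training run ~1–2 minutes) but not for training on datasets of tens of
  thousands of images.
- `conv2d` implements the two cases the architecture uses (dense and
  depthwise); arbitrary group counts are not supported.
- Learned or non-Haar wavelets, quantization, distillation, and deployment
  exports are out of scope.
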