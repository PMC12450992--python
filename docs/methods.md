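# Methods

This note records the modelling decisions behind `retinagrade`: what the
components compute, which parameters matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Adaptive-window attention

The driving idea is that attention window size should shrink where an image
is locally complex (lesions) and grow where it is smooth (background
retina). A literal reciprocal of local variance does not produce a valid
window geometry — it is a continuous quantity with the wrong units — so the
implementation realises the inverse relationship as a **rank-based quantile
binning**: per feature map, cell variances are compared against the
quantile edges (default terciles) and mapped onto the ordered window set
`S` (default `{3, 8, 15}`, the microaneurysm / hemorrhage / exudate scale
bands; the toy preset uses `{2, 4, 8}` so all sizes tile an 8×8 map).
Properties guaranteed by construction and asserted in tests:

- **Monotonicity** — within one map, a higher-variance cell never receives
  a larger window.
- **Tie-breaking toward the smaller window** — boundary values favour
  detail; comparisons are `>=` against descending-size thresholds.
- **Degenerate maps** — if all cell variances agree to within ε = 1e-8
  (e.g. a constant input), every cell gets `max(S)`; the block is then
  exactly a fixed-window attention block, which the test suite checks
  against an independent straight-line implementation.

The variance grid cell size `g` defaults to `max(S)` so any cell can host
any allowed window; cells assigned a smaller window are subdivided, with
partial windows zero-padded and the padded tokens masked out of the softmax
at −1e9 logits (softmax rows over real tokens still sum to 1). QKV and
output projections are shared across window sizes. The output projection
can be zero-initialised, which makes the residual block an exact identity —
a safe-insertion guarantee used both as a test and as an initialisation
option.

Variance is computed on the backbone feature map, not the raw image: the
branch sits after the feature extractor, and feature variance is the
quantity the window assignment consumes there. A `variance_source` argument
allows callers to rank windows by a different map (e.g. image statistics)
if wanted.

Focus regions at inference cannot come from ground-truth lesion coordinates
(none exist); they are derived from the variance map itself as the
connected bounding rectangles of the top-quantile cells (default top 25 %).
The focus mode restricts attention to those cells and leaves the rest on
the identity path.

## Multi-scale fusion

Three parallel same-padding convolutions (3/5/7) on the shared input,
channel concatenation, and a 1×1 convolution + batch norm + ReLU
compression. Kernels above 7×7 are rejected at configuration time: at
these lesion scales the 3+5+7 set already covers the size range, and larger
kernels buy little accuracy for a steep cost increase. Branch widths are
a free hyperparameter nowhere pinned down by the architecture itself; the
default (`branch_channels = C/2`, `fused_channels = C` with C the backbone
output width) keeps the parameter budget close to the baseline. Zero
padding (not reflective) inside branches is the conventional reading of
same-padding convolution.

## Network assembly

The backbone is a small hierarchical windowed-attention network
(patch-embed conv, per-stage pre-norm attention + MLP blocks, strided-conv
downsampling). Presets: `tiny_vit_toy` (2 stages, 32/64 channels, window 4
— the CPU test scale), `conv_stem_toy` (residual conv blocks, cheapest),
and `swin_tiny_like` (4 stages, 96–768 channels — constructible, not used
in tests). Both branches tap the **final-stage** feature map; their outputs
are channel-concatenated and compressed by a pointwise fusion layer; a
global-average-pool + linear + softmax head yields grade probabilities.
Ablation variants A / B / C_region / C_msfi / D and the kernel ablations
(k3, k5, k7, 3×k3, 3×k5, 3×k7, k357) are all configuration-level rebuilds.
Both C variants exist because "configuration C" can reasonably mean either
lesion-region emphasis or the fusion branch; providing both costs nothing
and removes the ambiguity.

Because no deep-learning framework is part of the package's dependency
surface, the tensor engine (`retinagrade.nn`) is authored here: a
reverse-mode tape over NumPy with exactly the primitives the model needs
(broadcast arithmetic, matmul, im2col convolution, gather/scatter,
padding, softmax). Every primitive is verified against central finite
differences; the Adam optimiser and batch-norm running statistics follow
the standard formulations. Parameters are float32; gradients follow
operand dtype.

Complexity accounting reports the exact trainable-parameter count
(enumeration) and a closed-form multiply–accumulate estimate (conv:
`k²·C_in·C_out·H·W`; linear: `m·n` per token; attention: projections plus
the per-window quadratic term at the nominal uniform window). The MAC
figure is informational: the adaptive assignment changes the quadratic
term at run time.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 1e-4 annealed by a
cosine schedule to `min_lr` (default 1e-6 — the floor is a free choice),
batch size 16, up to 100 epochs with early stopping on validation top-1
(patience 20). Splits are stratified per class by largest-remainder
allocation: 80/20 train-pool/test, then 10 % of the pool held out for
validation (≈72/8/20). An 8:1:1 split is equally expressible through
`TrainConfig.split`. Augmentation: rotation ±15°, Gaussian blur
σ ∈ [0.5, 1.0], ±10 % brightness. Class imbalance is addressed by
inverse-frequency class weights (normalised to mean 1) and by minority
**replication-with-augmentation**: feature-space interpolation is not
well-defined on raw fundus pixels, so minority enrichment replicates real
samples and perturbs them at load time. Early stopping restores the
best-validation checkpoint (including normalisation statistics);
`restore="final"` keeps the last epoch instead, which is the right choice
at toy scale where a handful of validation images makes the argmax epoch
noisy.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structural* features a grader relies on —
circular field, curvilinear vessels, multiplicative sensor noise, lesion
families at separated scales with the clinical ordering MA < HE < EX,
darker red MA/HE photometry versus bright yellowish EX, branching NV, a
monotone grade-from-inventory rule, and the long-tailed class census. It
deliberately does **not** model optic disc or fovea anatomy, camera- or
device-specific artefacts, media opacities, or photometric realism.
Passing tests therefore demonstrate that the architecture and pipeline
behave correctly on images with the right scale and contrast structure;
they say nothing about accuracy on real fundus photographs.

Lesion pixel sizes (MA 1–3 px, HE 4–10 px, EX 11–24 px at 64–224 px image
sizes) keep MA near the resolution limit, as in real fundus photography
where micrometre-scale lesions project onto a few pixels. The grading-rule
thresholds (1–5 MA mild; ≥6 HE severe; NV dominant) are package defaults
chosen to make the rule total and monotone — clinical grading prose is
qualitative, so exact counts are necessarily a design choice. Inventory
sampling is rejection-based with a 1,000-attempt cap before a configuration
error. Per-sample seeds are SHA-256-derived from the root seed, keeping
every sample independent of generation order and every run byte-identical.

## Evaluation and saliency

Top-k accuracy breaks probability ties toward the lower class index
(stable sort). Sensitivity/specificity are one-vs-rest from the confusion
matrix, returning NaN (never a division error) for empty classes. Dice is
`2|A∩B|/(|A|+|B|)` with the both-empty case defined as 1.0. The model is a
classifier, not a segmenter, so lesion localisation is read out as
gradient-weighted class activation over the fused feature stage: channel
weights are spatially averaged logit gradients; the weighted activation sum
is ReLU'd, min–max normalised and bilinearly upsampled. Heatmap Dice
scoring binarises at a threshold (default 0.7, the high-confidence band)
and removes connected components below 2 px.

## Problem sizes

The shipped experiment scale is chosen for single-CPU runs: 64×64 images,
the two-stage toy backbone, 300-image training runs (30 epochs, ~2–3 min),
a 1/100-scale dataset census (349 samples) for manifest checks, and
one-epoch ablation grids. Full-scale generation (35k images) and the
`swin_tiny_like` preset use the same code paths and are exercised only
through their configuration objects.

## Known limitations

- The backbone omits shifted-window cross-window mixing; windows are
  disjoint at every block, so long-range mixing happens only through
  downsampling.
- MAC counts for the adaptive block are nominal (uniform-window regime).
- The toy generalisation gap is large (the generator's backgrounds are
  individually random, so memorisation outpaces generalisation at n=300);
  train-split accuracy and saliency, not held-out accuracy, are the
  desk-scale readouts.
- Grad-CAM saliency at an 8×8 fused stage is coarse; sub-cell lesion
  boundaries are beyond its resolution.
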