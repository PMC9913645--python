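# Methods

This note documents the models, statistics, and design choices behind
`restransnet`, in the order data flows through the package.

## Problem setting

PD-1 (programmed cell death protein 1) expression status in hepatocellular
carcinoma is normally established by immunohistochemistry on resected or
biopsied tissue.  The package implements a non-invasive alternative: a binary
classifier that reads a 128×128 grayscale CT lesion patch (portal-venous
phase, tumour-centred) and predicts PD-1-positive vs PD-1-negative, together
with the clinical evaluation statistics used to judge such a model — ROC/AUC,
decision-curve analysis, and Kaplan–Meier/log-rank survival comparisons
between predicted groups.

## Preprocessing

The region of interest is supplied by the user as a tumour centre and extent
(the package performs no detection or segmentation).  The crop window is
`max(128, extent)` pixels a side, so tumours larger than the patch keep their
full boundary and are bilinearly downscaled (anti-aliased); windows that
overhang the scan are padded by edge replication.  Intensities are min–max
normalised per image to [0, 1]; no Hounsfield windowing is assumed, so the
tool accepts any already-windowed 8/16-bit export.  Augmentation (horizontal
flip, rotation up to ±15°, random crop-and-resize at scale 0.8–1.0, and
brightness/contrast jitter of ±20%) is gated per transform by a probability,
all defaulting to 0.5 and all configurable; with every probability zero the
image passes through bit-identical.

Hold-out splitting is at the **patient** level (no patient's images straddle
train and test) with `n_train = ceil(ratio · n_patients)`, so 93 patients at
an 8:2 ratio give the 75/18 cohort division.

## Architecture

The network is a hybrid of a small residual CNN and a ViT-style transformer:

* **Backbone** — three residual stages with output channels 16 → 32 → 64,
  each stage stride 2 (two 3×3 convolutions with batch normalisation and
  ReLU, plus a 1×1 projected shortcut).  A 128×128 input becomes a 64-channel
  16×16 feature map.
* **Patch embedding** — the feature map is cut into a 4×4 grid of patches
  (n = 16), each flattened and linearly projected to d = 64; a learned class
  token is prepended and learned position embeddings are added.
* **Transformer** — 12 pre-norm blocks: `Z = MSA(LN(X)) + X`,
  `Y = MLP(LN(Z)) + Z`, with 4-head scaled dot-product attention
  (`softmax(QKᵀ/√d_k)V`, d_k = 16) and a GELU MLP of hidden width 4d.
  The pre-norm composition is the standard reading of the published update
  rule, whose literal nesting applies attention twice and does not type-check
  as written; the class/position terms are merged once at embedding time.
  A final layer norm precedes the head, the usual companion of pre-norm
  stacks.
* **Head** — the classifier reads only the final class-token state Y(0)
  through linear → ReLU → linear to two logits; probabilities come from a
  softmax and training minimises the binary cross-entropy
  `−(y log ŷ + (1−y) log(1−ŷ))`, mean-reduced over the batch (a flag switches
  to sum), with predicted probabilities clamped to [1e−7, 1−1e−7].

Initialisation: Kaiming-normal (fan-in) for convolutions, truncated normal
(σ = 0.02) for transformer weights and the class/position tokens, all from a
single seed.  Everything runs on a compact reverse-mode autodiff engine over
NumPy arrays written for this package (channels-last convolution via
im2col + GEMM; gradients verified against central finite differences in the
test suite).

## Class imbalance

The clinical cohort is ~21% PD-1-positive.  Three treatments are provided:

1. **Oversampling** — minority-class images are resampled with replacement
   each epoch until both classes contribute the majority count.
2. **Loss re-weighting** — class-distribution-reverse weights `w_k ∝ 1/n_k`,
   normalised to average 1, multiply the per-sample loss.
3. **Gradient penalty** — oversampling duplicates produce near-identical
   per-sample gradients; for each batch the flattened per-sample gradients
   g_i are compared pairwise by cosine similarity, and every sample involved
   in a pair with cos θ_ij > ε has its gradient shrunk by a factor λ before
   aggregation (aggregate = (1/n) Σ f_i g_i).  The published shrink rule is
   self-referential as printed; it is resolved as `f_i = λ` for penalised
   samples and 1 otherwise, with λ ∈ (0, 1] (default 0.5) and ε default 0.9
   (targeting near-duplicates); a `per_pair` flag compounds λ per
   above-threshold partner instead.  Zero gradients are assigned similarity
   0 and are never penalised.  Per-sample gradients are taken over the last
   transformer block, final norm, and classifier head by default (duplicate
   detection only needs a consistent subspace; a `full` scope exists and the
   two agree on the shared coordinates, which the tests check).  In the
   training loop the factors re-weight the per-sample losses of the batch,
   which by linearity of differentiation equals scaling the per-sample
   gradients.  Re-weighting and the penalty both ride on top of oversampling,
   matching the published strategy comparison.

## Training recipe

SGD with momentum 0.9, weight decay 5e-4, initial learning rate 0.01,
batch 128, and the rate divided by 10 at epochs 50/100/150 with a 1e-5
floor.  The published description also mentions a linear scaling of the rate
between the same endpoints; both schedules are implemented and `step` is the
default.  The default epoch budget is 200 (covering all milestones).  Each
epoch logs training loss/accuracy and test accuracy/AUC; the best-test-AUC
state (parameters and batch-norm statistics) is kept and restored at the
end.  A non-finite loss aborts with a diagnostic.  Fixed seeds give
bit-identical runs.

## Synthetic cohort generator

No imaging data are distributed with the study, so the generator is the
package's test bed.  It emulates: a shared smooth parenchyma-like background;
a per-image smooth intensity field (σ = 16 px Gaussian-filtered noise, sd
0.03) standing in for anatomy variation; a central "tumour" disk whose
radius (uniform 28–44 px) and centre (±3 px jitter) are drawn per patient
and shared by that patient's images; i.i.d. pixel noise (sd 0.08, roughly
the residual noise of a windowed, normalised CT patch); and, for
PD-1-positive patients only, an oriented sinusoidal grating (wavelength 8 px,
30°) confined to the disk with a cosine edge taper, at amplitude
0.1 × `effect_size` in normalised intensity units.  The grating phase is
fixed in image coordinates so that class-mean differencing recovers the
planted template; only the disk mask follows the tumour.  Patient labels are
Bernoulli(prevalence), default 0.213 as in the clinical cohort (a degenerate
single-class draw is repaired by flipping one patient).  Optional survival
times are exponential with a baseline median of 33 months for the negative
class — the clinical overall-survival scale — and hazard ratio
`survival_link` (default 1.4, the ratio of the reported group medians under
an exponential model) for positives, censored administratively at a uniform
6–60 month horizon.

What the generator does *not* emulate: real CT texture statistics, 3-D
anatomy, scanner/protocol variation, segmentation error, or any correlation
between lesion appearance and survival beyond the class label.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that the architecture can learn a planted, learnable signal — not that the
clinical performance figures transfer.

## Evaluation statistics

ACC/SEN/SPEC come from confusion counts with the tie rule *score ≥ threshold
predicts positive* (stated explicitly because the headline metrics depend on
it).  ROC and AUC use the trapezoidal rule, which equals tie-corrected
pairwise concordance; the test suite checks this against an O(n²) oracle at
1e-10.  Decision-curve analysis reports net benefit
`TP/N − FP/N · p_t/(1−p_t)` on a 0.01–0.99 grid of threshold probabilities,
against treat-all and treat-none references.  Group comparisons of
continuous variables use the Mann–Whitney U test (exact enumeration when the
smaller sample has ≤ 8 tie-free observations, tie-corrected normal
approximation otherwise).  Metrics are computed per image by default, with a
mean-score per-patient aggregation available, since prognosis is
patient-level.

Survival analysis wraps lifelines: the Kaplan–Meier product-limit estimator
with deaths preceding censorings at tied times, medians as the first time
S(t) ≤ 0.5 with 95% confidence intervals from the log(−log) transformed
Greenwood variance (the common clinical default; the publication does not
state its CI method), and the standard (O−E)²/V log-rank chi-square with
1 df.  Survival groups use *predicted* PD-1 status by default, with a flag
for true labels.

## Interpretability

Forward hooks capture named activations; convolutional maps are exported as
the first k (default 4) filter grids, transformers as token sequences.  The
class-activation map is the last block's class-token attention row, averaged
over heads, reshaped to the patch grid, bilinearly upsampled to 128×128 and
min–max normalised; attention rollout across all blocks (0.5I + 0.5A,
row-normalised, multiplied front to back) is available behind a flag.  The
"6th/27th layer" aliases follow an undefined flat layer numbering in the
original figures and are mapped to approximate structural equivalents
(`conv_6` → block-2 first conv, `conv_27` → block-3 output).

## Problem sizes and numerical choices

The package trains on CPU in NumPy, so the self-contained experiments are
sized for a desk machine:

* The end-to-end benchmark uses 200 patients at 1–2 images each
  (~300 images), `effect_size` 3, the reduced architecture (2 transformer
  blocks, d = 32, backbone unchanged), 20 epochs, and batch 32 — the smaller
  batch gives ~260 SGD updates on a few hundred images, enough to converge,
  while the clinical recipe's batch 128 remains the `TrainConfig` default.
  Median test AUC over 3 seeds is the reported figure (1.0 in the runs the
  acceptance script reproduces).
* The imbalance-strategy comparison runs at 60 patients / 4 epochs and
  reports mean train-test accuracy gaps per strategy; at this scale the
  ordering is stochastic and is deliberately reported rather than asserted.
* Log-rank calibration uses 1000 replicates of n = 100 under a unit hazard
  ratio and checks the empirical 5%-level rejection rate against its
  binomial band.

Degenerate inputs have fixed conventions: constant images normalise to 0;
all-censored survival data report "median not reached"; single-class label
vectors are an error for oversampling and a warned NaN for sensitivity or
specificity; zero per-sample gradients are never penalised.

## Known limitations

The synthetic texture is far easier than clinical CT texture, so accuracy
figures on generated cohorts say nothing about clinical accuracy.  The
engine is single-threaded NumPy: fine for the reduced model and desk-scale
cohorts, not for the full 12-block model on thousands of images.  The
published cohort's Table of demographics is reconstructed only at the level
of counts actually printed; continuous covariates (age, creatinine, …) are
summarised in the publication by mean/SD only and are not re-simulated.
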