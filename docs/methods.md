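# Methods

This note records the models, algorithmic conventions and design choices
behind `octsaliency`, in the spirit of a package reference manual: what is
computed, under which assumptions, and where the design was genuinely open.

## Preprocessing

B-scans of arbitrary size and bit depth are mapped to a square
unit-interval frame in three steps.

1. **Letterboxing.** Multichannel input is collapsed to grayscale with
   ITU-R BT.601 luma weights; integer images are divided by their dtype
   maximum. The longer side is scaled to the target side (default 256 px)
   with Lanczos resampling; the shorter side scales by the same factor with
   its extent rounded half-up, is centred, and zero-padded. When the padding
   is odd, the extra pixel goes to the bottom/right. These tie rules are
   arbitrary but fixed, so geometry is bit-reproducible. Lanczos ringing is
   clipped back to [0, 1].
2. **Contrast harmonisation.** CLAHE runs on the 8-bit quantisation
   `floor(255·g)` of the full letterboxed frame (pad included), with an 8×8
   tile grid. The clip limit is stated in the OpenCV convention (2.0) and
   converted to scikit-image's normalised fraction as `2.0/256`; the two
   conventions agree in the regime used here (the scikit-image default 0.01
   corresponds to an OpenCV clip of ~2.6). Afterwards the image is clipped
   to its own [P2, P98] range and rescaled so P2 → 0 and P98 → 1. A frame
   whose percentile range collapses (constant image) maps to all zeros with
   a warning rather than failing, keeping batch pipelines total.
3. **Model input.** The grayscale plane is replicated to three channels and
   normalised with the ImageNet statistics (mean 0.485/0.456/0.406, sd
   0.229/0.224/0.225). The transform is affine per channel and exactly
   invertible, which the tests exploit.

Augmentation applies, in a fixed order: horizontal flip (p = 0.5), rotation
up to ±15°, affine translation up to ±3% of the side with isotropic scale in
[0.89, 1.15], multiplicative brightness then mean-anchored contrast jitter
(±0.3), gamma in [0.8, 1.2] (p = 0.7), and a 3-px Gaussian blur (p = 0.05,
sigma ~ U(0.1, 2)). Rotation/affine interpolate bilinearly with zero fill.
The order and interpolation are conventions of this package; each call is a
pure function of the config seed.

## Backbone and capture contract

The classifier is a hierarchical windowed-attention transformer: patch
embedding (4-px patches, layer norm), stages of pre-norm blocks
(window attention then MLP with GELU, residual connections), 2× patch
merging between stages, a final layer norm, global average pooling and a
Linear(·,512)–ReLU–Dropout(0.5)–Linear(512, K) head. Window attention uses
scaled dot-product attention inside non-overlapping windows with a learned
per-head additive position bias; odd-indexed blocks shift the partition by
half a window, with the standard attention mask blocking the cyclic-shift
wrap-around seam.

Because no autodiff framework is a dependency, the package carries a small
reverse-mode autodiff core (`octsaliency.autodiff`) implementing exactly the
operator set the model needs. Every interior node retains its gradient, so
a single backward pass from the target-class pre-softmax logit fills the
gradients of all captured arrays:

- attention probabilities immediately after the softmax (the attn-drop
  input), shaped `(windows, heads, N, N)` with window size and shift
  recorded;
- token descriptors at each block's second normalisation output (norm2
  preferred; norm1 is the fallback and is also capturable);
- the final-norm tokens, optionally transposed to a channel-major
  `C × H × W` activation for the CAM family.

Capture is non-invasive — requesting it does not change the forward
computation — and "first two / last two blocks" address the flattened
global block sequence, not stage-local indices. The target class defaults
to the argmax of the logits so that the explanation refers to the decision
actually made; the gradient target is the pre-softmax logit (the usual CAM
convention).

Gradient correctness is enforced by central finite differences: the forward
pass accepts additive probes at every capture point, and tests require
agreement within 1e-3 relative at randomly chosen coordinates (observed
errors are ~1e-6).

## Training objective and loop

The loss is focal cross-entropy with label smoothing: with
`p = softmax(z)`, `q = (1−ε)·onehot + ε/K`, the per-sample loss is
`(1 − p_t)^γ · (−Σ_k q_k log p_k)`, averaged over the batch; γ = 2.0 and
ε = 0.05 by default. The focal factor modulates the smoothed cross-entropy
as a whole — the simplest composition consistent with "focal with label
smoothing" — and reduces exactly to cross-entropy at γ = 0, ε = 0.

Optimisation is AdamW (decoupled weight decay 1e-4) with two parameter
groups: backbone 3e-5 and head 3e-4 by default, the conservative rates
appropriate for fine-tuning a pretrained backbone. The freezing policy
keeps the head trainable always; under a frozen backbone the deepest
`n` blocks (capped at the total, so large `n` unfreezes everything) and the
final normalisation layer stay trainable. A reduce-on-plateau scheduler
monitors validation accuracy in maximise mode with PyTorch-compatible
semantics (reduction when the bad-epoch count exceeds the patience, i.e. on
a flat curve with patience 3 the rate drops at epoch 5), and early stopping
respects a minimum epoch count. Class-balanced sampling draws indices with
replacement at weight 1/class-frequency.

The tiny fixture (2 stages, depths [2, 2], dims [16, 32], heads [2, 4],
window 4, patch 4, input 32, MLP ratio 4) is randomly initialised, so its
benchmark protocol (`fixture_train_config`) trains from scratch with a
uniform 1.5e-3 learning rate, 40-epoch cap, plateau patience 4 and early-
stop patience 10. On 1000 synthetic scans it reaches >90% accuracy on 200
held-out scans in under two minutes on one CPU; the acceptance script
recomputes this benchmark at every run.

## Heatmap conventions

All methods end in the same contract: per-image min-max normalisation
(constant maps → zeros, tolerance 1e-12) and bilinear upsampling to the
input resolution in the align-corners-off pixel-centre convention (constant
maps stay exactly constant). Specific conventions worth recording:

- **Grad-CAM++** uses the standard closed form with first-derivative powers
  (the exponential-score assumption) and a 0/0 → 0 guard.
- **HiRes-CAM** rectifies after the channel sum, preserving signed
  cancellation between channels.
- **Score-CAM** ranks channels by spatial activation variance, keeps the
  top 64, and weights each by the raw target-class softmax probability of
  the mask-gated input (no baseline subtraction); re-normalising gated
  inputs to ImageNet statistics is available behind a flag, default off.
- **Eigen-CAM**'s SVD sign ambiguity is resolved by requiring a nonnegative
  map sum, then clipping negatives; it is class-agnostic.
- **Attention attribution** multiplies probabilities by their gradients,
  rectifies, column-sums over queries (incoming-attention mass) and averages
  heads arithmetically; per-head column sums and head-averaged column sums
  commute, so the order is immaterial. Each block's grid is min-max
  normalised and upsampled *before* cross-block averaging so blocks of
  different depth and magnitude contribute comparably; early/late fusion
  weights are 0.4/0.6.
- **TRAST** pools the global descriptor as the unweighted token mean and
  inverts cosine similarity as `1 − s` before normalisation (equivalent to
  `−s` under min-max). Cosines involving a vector of norm below 1e-12 are
  defined as 0. vs1 requires the late weight to exceed the early weight;
  vs2 keeps early (base) and late (top) maps separate with the compositing
  rule `max(top, base·(1−top))`.
- **CGFM**'s token branch is the mean of the last two blocks' contrast maps
  (matching TRAST's late map); its CAM branch is Grad-CAM at the resolved
  target layer — on a pure transformer the final-norm token grid, since no
  convolutional map exists. The weighted variant's default α is 0.5.

Panels place the original image beside per-method overlays (jet colormap,
blend alpha 0.4, zero-valued pixels fully transparent) in an order drawn
from a dedicated seed, and emit the slot→method key separately so reviews
stay blinded until unblinding is intended.

## Evaluation statistics

Ratings are 0–4 Likert scores treated as ordinal data. Descriptives report
mean, median, quartiles, % favorable (3–4) and % low (0–1). Method-level
reviewer concordance uses Kendall tau-b (tie-corrected) and Spearman rho;
p-values use exact enumeration where scipy supports it (no ties, small n)
and the asymptotic approximation otherwise. Phase-1 ranking averages the
two reviewer means per method and rounds half-up to two decimals (decimal
arithmetic, so 3.315 → 3.32); ties are reported, never silently broken, and
the top-k selection includes every method tied at the k-th rank.

The Friedman test uses within-row midranks and the tie-corrected statistic
`χ² = (12 ΣR_j² − 3N²k(k+1)²) / (Nk(k+1) − ΣT/(k−1))` with
`T = Σ(t³ − t)` per row; Kendall's W is `χ²/(N(k−1))`, which is 1 exactly
for perfect untied concordance. The implementation is validated against a
loop-based oracle and scipy. Post hoc Wilcoxon signed-rank tests discard
zero differences, use the exact null for n ≤ 25 without ties and the
continuity-corrected normal approximation otherwise, and apply Holm's
step-down adjustment with monotonicity enforcement capped at 1. An
all-zero-difference pair reports p = 1 with a note. Group differences use
the tie-corrected Kruskal–Wallis H on respondent-level mean scores.

The full report pipeline builds, per form, the N×k participant summary
matrix (per-rater mean per method; median available by flag) feeding the
omnibus and post hoc tests, per-image-set Friedman tests on raw scores,
pooled and diagnosis-stratified descriptives, and group-stratified
Kruskal–Wallis tests.

## Synthetic data

The B-scan generator draws a smoothly curved stack of alternating
reflectivity bands (default six) over a dark background with a decaying
choroid, then adds one geometric lesion caricature per class: a bright
subretinal wedge (CNV), a dark subretinal dome (CSR), round intraretinal
cysts (DME), a train of bright bumps undulating the outer band (DRUSEN —
drawn as a contiguous undulation because isolated bumps are unresolvable at
the 32-px fixture scale), a full-thickness central V-shaped gap (MH), or
nothing (NORMAL). Speckle is multiplicative log-normal (sigma 0.15 by
default). Each field draws from its own counter-derived random stream, so
adding a field never shifts another field's draws and every image is a pure
function of its config. Training datasets render at twice the model input
side and letterbox down through the real pipeline, mirroring
native-resolution clinical scans.

These are caricatures: they share with real OCT the layered geometry,
class-localised lesions and multiplicative noise, but not speckle
statistics, vendor artefacts, motion, shadowing or anatomical variability.
Passing tests therefore demonstrate that the algorithms and the pipeline are
correct and that the fixture model can learn class-discriminative structure;
they say nothing about clinical-grade classification or about which heatmap
is clinically preferable on real scans.

The rating simulator is a latent-Gaussian ordinal model:
`latent = method effect + rater offset + image offset + noise`, cut at fixed
thresholds (−1.5, −0.5, 0.5, 1.5) into scores 0–4, over a balanced
21-rater × 10-image-set × 3-method design. Default method effects
(TRAST 0.55, Grad-CAM++ −0.37, CGFM −0.66) were chosen so the expected
score means land near the observed main-form means under the default
variance components (rater and image sd 0.5, noise sd 1.0). Under zero
method effects the Friedman rejection rate at α = 0.05 is nominal (the
acceptance script recomputes it over 1000 replicates), and the injected
ordering is recovered with significance in essentially all replicates.

## Known limitations

- The backbone is a miniature: no pretrained weights, no continuous
  relative-position bias or cosine attention, single-image capture. It is a
  faithful host for the capture contract, not a production classifier.
- Score-CAM runs one forward pass per selected channel; at production
  channel counts this is the dominant cost (hence the variance-based
  restriction to 64).
- The orientation-correction step of the preprocessing chain has no
  published algorithm; it is exposed as an optional metadata-driven vertical
  flip that defaults to a no-op.
- Phase-2 statistics operate on whatever rating table they are given; the
  package ships only a simulator, not clinical responses. DICOM/E2E
  ingestion and 3-D volumes are out of scope.
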