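# octsaliency

Saliency heatmaps and clinician-rating statistics for windowed-attention
OCT classifiers.

Heatmap explanations are the de-facto interface between a retinal-disease
classifier and the ophthalmologist reading its output, but different
attribution algorithms can highlight entirely different regions of the same
B-scan for the same prediction. This package implements a complete,
reproducible stack for generating and comparing such explanations on
hierarchical windowed-attention (Swin-style) transformers classifying OCT
B-scans into six categories (CNV, CSR, DME, DRUSEN, MH, NORMAL), together
with the two-phase expert-evaluation statistics used to decide which
explanation a clinic should actually trust.

It is written for researchers evaluating explainability methods on medical
imaging models: everything runs on synthetic B-scans and a tiny deterministic
backbone, so every algorithm is exercisable and testable without clinical
data or a GPU.

## What is inside

**Twelve heatmap algorithms**, all producing per-image min-max-normalised
maps at input resolution for the model-predicted class:

| Family | Methods |
| --- | --- |
| CAM | Grad-CAM, Grad-CAM++, Score-CAM (top-64 variance channels), Eigen-CAM, HiRes-CAM |
| Attention attribution | final-block self-attention; EL-GWAA (early/late gradient-weighted window attention, fused 0.4/0.6) |
| Token feature similarity | TRAST vs1 (fused) and vs2 (layered) |
| Hybrid | CGFM vs1 (layered), vs2 (elementwise product), weighted (α-interpolation) |

On a windowed-attention backbone the CAM target layer is the final layer-norm
token grid `(H·W tokens → C×H×W)`. Attention attribution rectifies the
gradient-weighted probabilities, `R = ReLU(A ⊙ ∂y_c/∂A)`, reduces them to
per-token incoming-attention mass `I_j = Σ_i R_ij` (head-averaged), and maps
windows back to the spatial grid with the cyclic shift undone. TRAST scores
each token by the inverted cosine similarity to the image's mean token
descriptor, `s_i = 1 − cos(t_i, ḡ)`, min-max normalised and fused across
early/late depths.

**A capture-aware backbone.** A small hierarchical windowed-attention
classifier (patch embedding, shifted-window attention with seam masking,
patch merging, MLP head) built on an in-package reverse-mode autodiff core.
A single forward+backward pass records, at addressable blocks, the
post-softmax attention probabilities, the norm1/norm2 token descriptors and
the final-norm tokens — each with the gradient of the target-class logit
with respect to it. Training uses focal cross-entropy with label smoothing,
`(1 − p_t)^γ · CE_ε` with γ = 2 and ε = 0.05, AdamW with decoupled weight
decay and separate backbone/head learning rates, plateau scheduling on
validation accuracy, early stopping, and optional class-balanced sampling.

**Preprocessing.** Aspect-preserving Lanczos letterboxing to a zero-padded
square, CLAHE (clip 2.0, 8×8 tiles) followed by 2nd/98th-percentile
normalisation, ImageNet-statistics channel replication, and fully seeded
training augmentation.

**Evaluation statistics.** Phase-1 screening: reviewer concordance
(Kendall tau-b, Spearman rho) and combined-mean ranking over the published
12-method screening table. Phase-2 questionnaires: ordinal descriptives,
tie-corrected Friedman tests with Kendall's W = χ²/(N(k−1)), Wilcoxon
signed-rank post hocs with Holm correction, and Kruskal–Wallis tests across
professional groups — plus a latent-Gaussian ordinal rating simulator for
calibration studies.

## Worked example

```python
import octsaliency as oc

# Phase-1 screening: reviewer concordance and ranking on the published table
table = oc.PHASE1_SCREENING()
conc = oc.rank_concordance(table["ophthalmologist"], table["ai_specialist"])
ranked = oc.phase1_rank(table)

# Phase-2 statistics on a simulated 21-rater questionnaire
report = oc.build_report(oc.synth_ratings(oc.RatingSimConfig(seed=0)))

# A TRAST heatmap from the tiny fixture on a synthetic B-scan
model = oc.tiny_backbone(seed=0)
x, _ = oc.make_dataset(1, side=32, seed=7)
hm = oc.compute_heatmap(model, x[0], "trast_vs1")
```

This prints (abridged):

```
tau-b = 0.576 (p = 0.0088), rho = 0.755 (p = 0.0045)
       method  variant  combined_mean  rank
        TRAST      vs1           3.32     1
CGFM-weighted Baseline           3.20     2
   Grad-CAM++ Baseline           3.04     3
         CGFM      vs2           3.04     3
Friedman chi2 = 36.96, p = 9.4e-09, W = 0.88
  CGFM vs Grad-CAM++: Holm-adjusted p = 0.0109
  CGFM vs TRAST: Holm-adjusted p = 0.0002
  Grad-CAM++ vs TRAST: Holm-adjusted p = 0.0002
TRAST vs1 map: shape (32, 32), range [0.0, 1.0]
```

Reading it: the two Phase-1 reviewers ranked the twelve candidate methods
concordantly (tau-b 0.576), with TRAST vs1 top-ranked at a combined mean of
3.32 of 4 and a reported tie at rank 3. The simulated Phase-2 ratings
(injected ordering TRAST > Grad-CAM++ > CGFM) produce a significant omnibus
Friedman test whose Holm-corrected post hocs separate TRAST from both
alternatives. The heatmap itself is a unit-interval map at the model's input
resolution, ready for `oc.overlay` / `oc.build_panel`.

A CLI mirrors the library:

```bash
octsaliency synth oct --class DME --n 10 --out scans/
octsaliency train --out ckpt.npz
octsaliency explain --method trast_vs1 --image scans/DME_7.png --checkpoint ckpt.npz --out maps/
octsaliency panel --image scans/DME_7.png --checkpoint ckpt.npz --out panels/
octsaliency evaluate --ratings ratings.csv --out report/
```

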