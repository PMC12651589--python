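# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions, and known limitations of `busseg`.

## Problem and model

Breast-ultrasound lesion segmentation is hard where lesions are small, low
contrast, and embedded in speckle. The package couples pixel evidence with
clinical context in text form: a *global* prompt (lesion size category and
image-quadrant location) conditions a transformer token pathway that supplies
scene-level semantics, and a *local* prompt (BI-RADS shape, margin, category)
modulates a U-Net-style pathway that preserves boundaries. Conditioning is
channel-wise FiLM: a per-stage two-layer MLP maps the projected prompt
embedding to per-channel scale γ and shift β, broadcast over the spatial
grid. An additive skip (`F_out = γ⊙F + β + F`) is enabled at all sites by
default.

Key structural contracts: patch size 16 (so a 352-pixel side gives a 22×22
token grid, 485 tokens with the class token); global map width C_g = 64;
local map width C_ℓ = 32; fused width 96; two residual blocks and a 1×1
convolution produce logits at the input resolution.

## Frozen components and trainable surface

The vision backbone and the text encoder are frozen; only the token
reducers, conditioning maps, spatial projection, the local encoder–decoder,
SFA MLPs, embedding projectors, and the fusion head train. Tests assert the
frozen parts are bit-identical before and after training (checksums).

The production contracts (`TextEncoder`, `VisionBackbone`) accept pretrained
contrastive encoders. The shipped defaults are deliberately self-contained:

* `HashingTextEncoder` — lowercase tokens hashed (MD5, process-independent)
  into a fixed vocabulary, counts projected by a seeded Gaussian matrix and
  L2-normalized. It is deterministic across processes and gives distinct,
  roughly uncorrelated embeddings for distinct prompts; it carries no
  linguistic structure beyond bag-of-words identity, which is sufficient for
  the fixed-template prompts used here.
* `ToyViT` — a seeded, frozen two-block vision transformer with learned
  positional embeddings per grid size.

The text-embedding width defaults to e = 64 (the stand-in encoder's width; a
CLIP-style adapter would use its native e, e.g. 512), projected to a shared
conditioning width d (64 by default, 16 in the reduced test configuration);
the reduced token width r defaults to 64. These three widths are not fixed
by the design and are configuration-exposed.

## Initialization: every conditioning site starts as the identity

SFA MLP final layers are zero-initialized. Without the additive skip the
γ-bias is 1 and the β-bias 0 (`F̂ = F` exactly); with the skip the γ-bias is
0 so that `F_out = 0·F + 0 + F = F`. The global branch's token conditioning
initializes its multiplicative map to the constant 1 and its additive map to
0, attention blocks zero-initialize their output projections, and the
residual blocks zero-initialize their second convolution. Consequently a
freshly built model is exactly the unconditioned concat → 1×1-conv baseline,
and prompt text has provably zero effect until training moves those weights.
The `use_sfa=False` ablation skips all conditioning paths outright, making
prompt invariance exact by construction rather than by initialization.

## Loss and optimization

The training objective is soft-Dice plus pixel-wise binary cross-entropy
with weights λ1 = λ2 = 1 (configuration-exposed). Optimization is AdamW
(weight decay 0.01) at an initial learning rate of 1e-4 under a cosine
schedule `lr(t) = lr0 (1 + cos(πt/T))/2`, batch size 4, iteration-based
sampling with replacement (the iteration budget exceeds the dataset size).

The fusion head multiplies its 1×1-convolution output by a fixed logit gain
(default 20). Rationale: Adam-style updates move each weight by roughly the
learning rate per step, so a short schedule at lr 1e-4 displaces weights by
only ~1e-2 in total; through unit-scale normalized features that cannot
produce saturated probabilities. The fixed gain rescales the head so that
ordinary weight displacements reach confident logits within short schedules.
It multiplies a zero-initialized layer, so the initial state (logits 0,
probabilities 0.5) is unchanged.

All computation runs on the package's own numpy reverse-mode autodiff core.
Normalization layers are per-sample (group-norm with one group over C×h×w,
token-wise layer norm in attention blocks): no running statistics, so
training and evaluation behaviour are identical and bitwise deterministic
given fixed weights. Transposed convolutions use kernel = stride
(non-overlapping), avoiding checkerboard artefacts.

## Working resolution

By default both branches emit maps at the input resolution (the global
branch upsamples its 22×22 token grid through four stride-2 transposed
convolutions). A half-resolution working grid (`working_stride=2`, three
transposed convolutions, nearest 2× upsampling of the logits) is available
and is what the reduced test configuration uses; it quarters the dominant
full-resolution convolution cost at a small boundary-precision cost.

## Prompt construction conventions

* Coordinates are 0-based, x = column, y = row; centroids are continuous.
* Size terciles (1/3 and 2/3 empirical quantiles, linear interpolation) are
  fitted per fold on the training split only; values at or between the edges
  map to "medium".
* Image halves stand in for anatomical quadrants. Laterality resolves
  inner/outer (right breast: left image half → outer); unknown laterality
  maps the left half to "inner" by fixed convention; exact midlines tie to
  upper/inner.
* Mask-free inference thresholds the first-pass probability map at τ = 0.30
  (inclusive), labels 8-connected components, and keeps the largest (ties:
  smaller top-left flattened index). With no pixel at threshold the quadrant
  clause is simply omitted — no location is invented.
* Missing metadata fields are omitted from the local prompt; with everything
  missing the neutral prompt "breast lesion" is used.

## Metric conventions

ε = 1e-8 stabilizes every denominator. Taken literally this makes the Dice
of an empty prediction against an empty truth ≈ 0 — **not** 1, as several
other toolkits report; comparisons across toolkits must account for this.
FNR with empty ground truth is ε-degenerate and reported as 0. Cross-fold SD
uses the population convention (divide by K). The Wilcoxon signed-rank test
drops zero differences, enumerates all 2^n sign assignments exactly for
n ≤ 12 (midranks, so ties are handled), and otherwise uses the normal
approximation with tie correction. Benjamini–Hochberg adjustment is the
standard step-up with monotonicity enforcement (it is not idempotent — no
adjusted-p procedure of this form is). Bootstrap intervals are seeded
percentile intervals of the resampled mean; percentile bootstrap is known to
undercover slightly for small n (~93% at n ≈ 40), approaching nominal 95%
coverage by n ≈ 100.

## Synthetic phantoms

The generator emulates the features of clinical BUS data that this pipeline
depends on, and only those: a smooth tissue gradient with multiplicative
smoothed log-normal speckle; a single hypoechoic star-convex lesion whose
boundary is an ellipse perturbed by low-order radial harmonics
(`r(θ) = r_ell(θ)(1 + a·Σ_k cos(kθ+φ_k))`, k = 2..5); controllable length,
contrast, irregularity amplitude, and margin blur; and metadata derived
deterministically from the generation parameters (oval vs irregular at
amplitude 0.15; circumscribed vs microlobulated at blur 1.0 px; a BI-RADS
3/4 surrogate from the two). The mask is the exact pre-blur support; images
are quantized to 8-bit so save/load round-trips are exact. The recorded
lesion size is the analytic maximum caliper diameter of the boundary curve.

Default conditions: lengths 40–260 px at side 352 (14–48 px at the test
side 96, preserving the same relative range), contrast drop 0.30–0.60,
irregularity amplitude up to 0.30, margin blur up to 2 px, speckle
log-amplitude 0.25.

What passing tests on phantoms do **not** show: robustness to acoustic
shadowing and posterior enhancement, heterogeneous parenchyma, scanner and
operator variability, multiple or ill-defined lesions, or any correlation
structure between appearance and malignancy beyond the simple surrogate
rules above. Results on phantoms bound correctness of the machinery, not
clinical performance.

## Scaled-down study conditions

CPU tests and the acceptance script run a reduced configuration chosen once:
image side 96, local encoder widths (8, 16, 24, 32, 32), C_g = 16, C_ℓ = 8,
r = d = 16, toy ViT width 32, half-resolution working grid; 200 phantoms,
300 training iterations at batch 4. Under these conditions one fold trains
in about two minutes on a single CPU and reaches held-out Dice ≈ 0.91 with
mask-free two-pass evaluation.

## Known limitations

* The shipped encoders carry no pretrained knowledge; production-grade
  accuracy on real BUS data requires plugging pretrained contrastive
  encoders into the declared contracts and GPU-scale training.
* The cross-validation protocol treats folds as a rotation partition of one
  seeded shuffle (an independent-draws mode is available as an option).
* No boundary-distance metrics (Hausdorff/ASSD) and no test-time
  augmentation.
* Five folds of full-resolution training at side 352 are computationally
  heavy under the numpy engine; the package is designed for correctness and
  protocol fidelity at desk scale.
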