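# Methods

## Model and procedure

The toolkit explains a CNN classifier trained with image-level labels
only. An explanation for image `x` and class `c` at layer `l` is built
in three steps.

**1. Contrastive relevance propagation.** A forward pass records the
stage activations `A^{lk}` (channel `k` of stage `l`) and the logits.
The head-level relevance vector keeps the target logit `L_c` and
replaces each non-target logit by a negative share of it; two
conventions are implemented:

* `clrp_n` (default): non-target entries `−L_c/N`, contrastive score
  `S_c = L_c − (N−1)·L_c/N = L_c/N`;
* `clrp_nminus1`: non-target entries `−L_c/(N−1)`, which makes the
  vector sum exactly zero — for `N = 2` this leaves no conserved score
  to account against, so it is not the default.

The vector is propagated to every stage with per-layer rules:

* ε-rule (assigned to the linear head):
  `R_i = Σ_j a_i w_ij / (ε° + Σ_i a_i w_ij) · R_j`, where `ε°` is
  `ε = 1e−9` carrying the sign of the denominator (avoids catastrophic
  cancellation near zero pre-activations).
* αβ-rule (assigned to convolutions; default `α = 1, β = 0`):
  positive and negative contribution pools are normalized separately
  and combined with weights `α` and `−β`; `α − β = 1` is enforced.

Fixed rules cover the rest of the graph: ReLU and dropout pass
relevance through unchanged; max-pooling routes winner-takes-all;
average/global pooling redistributes through the equivalent linear map;
flatten reshapes; a residual addition `y = x + F(x)` splits incoming
relevance between `x` and `F(x)` in proportion to each addend
(ε-stabilized) and sends the branch share back through the branch;
batch normalization is folded into the preceding convolution
(canonization) so the pair is treated as one affine convolution.

**2. Channel weighting.** The default weighting is
`w^c_{lk} = Σ_ij R^{lk,c}_{ij} / Σ_ij A^{lk}_{ij}`. It is the exact
solution of the conservation-axiom objective — by construction
`Σ_k w_k Σ_ij A^{lk}_{ij} = Σ_k Σ_ij R^{lk,c}_{ij}`, the total
propagated relevance — and approximates the sensitivity axiom with the
intractable relevance-redistribution factor set to 1. Any common scale
factor on the weights cancels in the final normalization (tested), so
the remaining scale term in the derivation is fixed to 1. Baselines:
per-channel relevance means, per-channel mean gradients, and
activation-normalized gradient sums.

**3. Map assembly.** The raw map `Σ_k w_k A^{lk}` is rectified
(negative values clipped; a flag disables this), bilinearly upsampled
to input resolution, and min-max normalized to [0, 1]; a constant raw
map normalizes to all zeros. Aggregation over stages averages the
*normalized* per-stage maps and renormalizes once — each stage
contributes on equal footing, and each per-stage map remains
individually inspectable. (Averaging raw maps first is the other
defensible reading; normalized-first was chosen so a stage with large
raw amplitude cannot dominate.)

## Classifier

A compact 4-stage residual CNN written directly in numpy (explicit
forward/backward): per stage one 3×3 convolution + batch normalization
+ ReLU, a residual block in stages 3–4, and 2×2 max-pool downsampling;
widths 8/16/32/64; global average pooling and a **bias-free** linear
head (the classic CAM head: with no head bias, relevance leaving the
head equals the contrastive score exactly, so stage-level conservation
is limited only by ε-leakage). Convolutions keep biases; their
relevance share is absorbed, the standard LRP choice. Training:
cross-entropy, AdaMax with learning rate 0.001, batch size 16, early
stopping after 10 epochs without validation-accuracy improvement
(max 30 epochs), augmentations vflip/hflip/90°-rotations/contrast
jitter, everything seeded. The explanation machinery is
model-agnostic; this network exists so every propagation case
(convolution, pooling, normalization, residual addition, dropout) is
exercised at a size that trains in under a minute on one CPU.

Optional dropout layers (rate 0.1) sit after each stage output; they
are active during training and, for the Monte-Carlo protocol, during
evaluation. Where exactly dropout should sit relative to the residual
blocks is an open layout choice; after each stage's pooled output was
chosen and is not claimed to be canonical.

## Synthetic benchmark

The generator emulates a monochrome endomicroscopy setting with two
tissue classes at 64×64, 60 images per class, split 80/10/10 per class:

* class 0 ("meningioma-like"): 2–5 dark ellipses (radii 4–9 px,
  rejection-sampled non-overlapping, 100 extra tries before accepting
  overlap) subtracted at full contrast 0.5 from a speckled background
  (Gaussian-smoothed uniform noise around brightness 0.65, sd 0.08);
  the rendered ellipse pixels are the ground-truth mask;
* class 1 ("GBM-like"): same background plus 2–4 bright elongated
  ridges; no maskable structure, mask empty.

The discriminative cue is therefore a localized structure, not global
brightness — a method must localize to score. The defaults make the
task cleanly separable (held-out accuracy 1.0 at seed 0); sizes and
counts are free parameters, not morphometric claims. What the
generator does **not** emulate: video structure, probe vignetting,
annotation noise, patient-level heterogeneity (every image is
independent), or class-imbalanced clinics. Results on this benchmark
show the machinery is correct and internally consistent; they do not
certify localisation quality on real tissue.

## Evaluation protocols

* **Weakly supervised segmentation**: on annotated-class test images
  the model classifies correctly, threshold each map at 0.2 of its
  maximum (configurable; reported in every run) and score mean IoU
  against the masks, per stage and per stage-aggregation. An empty
  union counts as IoU 1 (never reached on annotated images).
* **Axiom metrics** (lower is better): the conservation metric is the
  mean relative gap `|S_c − Σ_k w_k Σ_ij X^{lk}_{ij}| / |S_c|` with
  `X = A` by default (the axiom's accounting; under it the default
  weighting is algebraically exact) and `X = R` behind a flag; the
  sensitivity metric compares each channel's weight mass against the
  logit drop when that channel is zeroed at the stage and the forward
  pass resumed, normalized by the total absolute drop. `S_c` is the
  contrastive score for relevance methods and the raw logit otherwise.
  Images with zero score (or zero total drop) are skipped.
* **Cascading randomization**: re-initialize the head, then
  progressively stages 4→1; after each step recompute the map at a
  viewing stage and report Spearman rank correlation of absolute map
  values against the trained-model map (rank correlation is robust to
  the scale/sign indeterminacy of saliency values; a constant map
  scores 0). A sound method's similarity must decay to below 0.5 at
  full randomization.
* **Monte-Carlo dropout**: average the raw CAM over 10 stochastic
  passes with dropout active, then normalize once (averaging
  normalized maps is the alternative reading; raw-then-normalize keeps
  the 0-pass/1-pass equivalence exact when dropout is off).

## Numerical notes and limitations

* ε = 1e−9 everywhere a denominator is stabilized, always signed like
  the denominator.
* αβ-rule conservation presumes every output unit has a non-empty
  positive pool (and non-empty negative pool when β > 0); an output
  whose contributions are all of one sign loses the other pool's share.
  Conservation tests condition on this support assumption.
* Dead-channel guard: channels with `|Σ A| < 1e−8` get weight 0 in the
  activation-normalized weightings.
* Scale invariance of the final map under uniform weight rescaling is
  exact in exact arithmetic; in floating point it holds bit-exactly for
  power-of-two factors and to ~1 ulp otherwise.
* Relevance is propagated one image at a time; no batching semantics.
* The toy network trains on 96 images; mIoU values on 6 annotated test
  images are high-variance and meaningful as orderings and consistency
  checks, not as absolute quality claims. On this benchmark the
  shallow stages localize the small blobs *better* than layer 4 (whose
  4×4 grid cannot resolve them) — the aggregate-over-stages map
  improving on the deepest stage is the expected and observed trend.
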