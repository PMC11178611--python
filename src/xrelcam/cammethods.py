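"""Class-activation maps from pluggable channel-weighting strategies.

Every method shares the same pipeline: capture stage activations
A^{lk}, obtain a backpropagated quantity (CLRP relevance or the target
logit's gradient), reduce it to one weight per channel, and assemble
the saliency map Σ_k w_k·A^{lk} (rectified, upsampled, min-max
normalized).

Weightings:

* ``xrelevancecam`` — w_k = Σ_ij R_ij / Σ_ij A_ij: relevance totals
  normalized by activation mass. This is the axiom-motivated weighting:
  it is the exact minimizer of the conservation-axiom objective
  (Σ_k w_k Σ A^{lk} then equals the total propagated relevance), and
  approximates the sensitivity axiom with the hard-to-evaluate
  redistribution factor set to 1. A uniform rescaling of all weights
  cancels in the min-max normalization, which is why the remaining
  scale factor in the derivation can be fixed to 1.
* ``relevancecam`` — w_k = mean_ij R_ij (simple relevance averaging).
* ``gradcam`` — w_k = mean_ij ∂L_c/∂A_ij.
* ``xgradcam`` — w_k = Σ_ij (∂L_c/∂A_ij · A_ij) / Σ_ij A_ij.

Channels whose activation mass |ΣA| falls below a small guard get
weight 0 in the ΣA-normalized methods (a dead channel carries no
signal; dividing by its near-zero mass would only amplify noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .netkit import ActivationStack, forward_capture
from .lrpcore import RelevanceStack, RuleConfig, clrp_init, propagate
from .nn import ModelGraph

__all__ = ["ChannelWeights", "SaliencyMap", "xrelevance_weights",
           "relevance_weights", "gradient_weights", "assemble_cam",
           "aggregate_layers", "explain", "CAMExplainer", "METHODS"]

METHODS = ("xrelevancecam", "relevancecam", "gradcam", "xgradcam")
RELEVANCE_METHODS = ("xrelevancecam", "relevancecam")
DEAD_CHANNEL_GUARD = 1e-8
ALL_STAGES = ("layer1", "layer2", "layer3", "layer4")


@dataclass
class ChannelWeights:
    stage: str
    target_class: int
    weights: np.ndarray   # (C,)
    guarded: np.ndarray   # (C,) bool — channels zeroed by the dead guard

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite channel weights")


@dataclass
class SaliencyMap:
    """Min-max normalized map at input resolution (all-zero if constant)."""

    values: np.ndarray                 # (H, W) in [0, 1]
    stage_provenance: frozenset[str]
    target_class: int


def _guard(sums: np.ndarray):
    return np.abs(sums) < DEAD_CHANNEL_GUARD


def xrelevance_weights(acts: np.ndarray, rels: np.ndarray, stage: str = "",
                       target_class: int = 0) -> ChannelWeights:
    """Per-channel relevance total over activation total (dead guard → 0)."""
    if acts.shape != rels.shape:
        raise ValueError("activation/relevance shape mismatch")
    a_sum = acts.reshape(acts.shape[0], -1).sum(axis=1)
    r_sum = rels.reshape(rels.shape[0], -1).sum(axis=1)
    guarded = _guard(a_sum)
    w = np.where(guarded, 0.0, r_sum / np.where(guarded, 1.0, a_sum))
    return ChannelWeights(stage, target_class, w, guarded)


def relevance_weights(rels: np.ndarray, stage: str = "",
                      target_class: int = 0) -> ChannelWeights:
    """Per-channel mean relevance (the plain relevance-averaging baseline)."""
    w = rels.reshape(rels.shape[0], -1).mean(axis=1)
    return ChannelWeights(stage, target_class, w,
                          np.zeros(rels.shape[0], dtype=bool))


def gradient_weights(acts: np.ndarray, grads: np.ndarray,
                     variant: str = "gradcam", stage: str = "",
                     target_class: int = 0) -> ChannelWeights:
    """Gradient-based weightings: mean gradient, or activation-normalized."""
    if acts.shape != grads.shape:
        raise ValueError("activation/gradient shape mismatch")
    if variant == "gradcam":
        w = grads.reshape(grads.shape[0], -1).mean(axis=1)
        return ChannelWeights(stage, target_class, w,
                              np.zeros(acts.shape[0], dtype=bool))
    if variant == "xgradcam":
        a_sum = acts.reshape(acts.shape[0], -1).sum(axis=1)
        ga_sum = (grads * acts).reshape(acts.shape[0], -1).sum(axis=1)
        guarded = _guard(a_sum)
        w = np.where(guarded, 0.0, ga_sum / np.where(guarded, 1.0, a_sum))
        return ChannelWeights(stage, target_class, w, guarded)
    raise ValueError(f"unknown gradient variant {variant!r}")


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def assemble_cam(acts: np.ndarray, weights: ChannelWeights, input_shape,
                 clip_negative: bool = True, return_raw: bool = False):
    """Weighted channel sum → rectify → upsample → min-max normalize."""
    if weights.weights.shape[0] != acts.shape[0]:
        raise ValueError("weights do not match stage channel count")
    raw = np.tensordot(weights.weights, acts, axes=(0, 0))
    if clip_negative:
        raw = np.maximum(raw, 0.0)
    up = resize(raw, input_shape, order=1, mode="edge", anti_aliasing=False,
                preserve_range=True)
    sm = SaliencyMap(_normalize(up), frozenset({weights.stage}),
                     weights.target_class)
    return (sm, up) if return_raw else sm


def aggregate_layers(maps: dict[str, SaliencyMap],
                     stages=ALL_STAGES) -> SaliencyMap:
    """Pixel-wise mean of normalized per-stage maps, renormalized.

    Each stage contributes on an equal [0, 1] footing before averaging.
    """
    stages = tuple(stages)
    if not stages:
        raise ValueError("empty stage selection")
    arrs = [maps[s].values for s in stages]
    target = maps[stages[0]].target_class
    mean = np.mean(arrs, axis=0)
    return SaliencyMap(_normalize(mean), frozenset(stages), target)


def compute_weights(method: str, acts: ActivationStack, stage: str,
                    rels: RelevanceStack | None = None,
                    grads: dict[str, np.ndarray] | None = None,
                    target_class: int = 0) -> ChannelWeights:
    """Dispatch one stage's channel weights for a named method."""
    a = acts.activations[stage]
    if method == "xrelevancecam":
        return xrelevance_weights(a, rels.relevances[stage], stage,
                                  target_class)
    if method == "relevancecam":
        return relevance_weights(rels.relevances[stage], stage, target_class)
    if method in ("gradcam", "xgradcam"):
        return gradient_weights(a, grads[stage], method, stage, target_class)
    raise ValueError(f"unknown method {method!r}")


def _gradients_for(model: ModelGraph, acts: ActivationStack, target_class):
    """Gradient of the raw target logit w.r.t. every stage activation."""
    glogits = np.zeros((1, model.n_classes))
    glogits[0, target_class] = 1.0
    model.zero_grads()
    _, grads = model.backward(glogits, capture=True)
    return {k: v[0] for k, v in grads.items()}


def explain(model: ModelGraph, image: np.ndarray, target_class: int,
            method: str = "xrelevancecam", stages=ALL_STAGES,
            rules: RuleConfig | None = None, aggregate: bool = True,
            convention: str = "clrp_n", clip_negative: bool = True,
            dropout_on: bool = False, rng: np.random.Generator | None = None,
            return_raw: bool = False):
    """Produce per-stage saliency maps (and optionally their aggregate).

    Relevance methods run one CLRP propagation; gradient methods run one
    backward pass from the target logit. Deterministic with dropout off.

    Returns a dict ``{stage: SaliencyMap, ...}`` plus key ``"aggregate"``
    when requested; with ``return_raw=True`` also returns the raw
    (pre-normalization, post-upsampling) per-stage maps.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    stages = tuple(stages)
    acts = forward_capture(model, image, dropout_on=dropout_on, rng=rng)
    rels = grads = None
    if method in RELEVANCE_METHODS:
        init = clrp_init(acts.logits, target_class, convention)
        rels = propagate(model, acts, init, rules)
    else:
        grads = _gradients_for(model, acts, target_class)
    input_shape = image.shape[-2:]
    maps, raws = {}, {}
    for stage in stages:
        w = compute_weights(method, acts, stage, rels, grads, target_class)
        maps[stage], raws[stage] = assemble_cam(
            acts.activations[stage], w, input_shape,
            clip_negative=clip_negative, return_raw=True)
    if aggregate:
        maps["aggregate"] = aggregate_layers(maps, stages)
    return (maps, raws) if return_raw else maps


class CAMExplainer(BaseEstimator, TransformerMixin):
    """Scikit-learn style saliency transformer over a fitted classifier.

    ``transform(X)`` maps images ``(n, H, W)`` or ``(n, C, H, W)`` to
    aggregated saliency maps ``(n, H, W)`` in [0, 1] for each image's
    predicted class (or a fixed ``target_class``).

    Parameters
    ----------
    estimator : fitted CNNClassifier or ModelGraph
    method : one of METHODS
    stages : stage names to use (and aggregate over)
    """

    def __init__(self, estimator=None, method="xrelevancecam",
                 stages=ALL_STAGES, target_class=None, epsilon=1e-9,
                 alpha=1.0, beta=0.0, convention="clrp_n",
                 clip_negative=True):
        self.estimator = estimator
        self.method = method
        self.stages = stages
        self.target_class = target_class
        self.epsilon = epsilon
        self.alpha = alpha
        self.beta = beta
        self.convention = convention
        self.clip_negative = clip_negative

    def _model(self) -> ModelGraph:
        est = self.estimator
        if isinstance(est, ModelGraph):
            return est
        model = getattr(est, "model_", None)
        if model is None:
            raise ValueError("estimator must be fitted (or a ModelGraph)")
        return model

    def _rules(self):
        return RuleConfig(epsilon=self.epsilon, alpha=self.alpha,
                          beta=self.beta)

    def fit(self, X=None, y=None):
        self._model()  # validates
        self.model_ = self._model()
        return self

    def explain(self, image, target_class=None, **kw):
        """Full per-stage output for one image; see :func:`explain`."""
        model = self._model()
        if image.ndim == 3 and image.shape[0] == model.input_shape[0]:
            img = image
        else:
            img = np.asarray(image)
        if target_class is None:
            target_class = self.target_class
        if target_class is None:
            target_class = forward_capture(model, img).predicted_class
        return explain(model, img, target_class, method=self.method,
                       stages=tuple(self.stages), rules=self._rules(),
                       convention=self.convention,
                       clip_negative=self.clip_negative, **kw)

    def transform(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None]
        out = []
        for img in X:
            maps = self.explain(img)
            out.append(maps["aggregate"].values)
        return np.stack(out)
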