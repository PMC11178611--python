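"""Contrastive layer-wise relevance propagation over the model graph.

Relevance starts at the head from a contrastively modified logit vector
(the target logit kept, non-target logits negated and rescaled) and is
redistributed layer by layer down to each named stage with the LRP-ε
and LRP-αβ rules:

    ε-rule:   R_i = Σ_j  a_i w_ij / (ε° + Σ_i a_i w_ij) · R_j
    αβ-rule:  R_i = Σ_j [ α · (a_i w_ij)⁺ / (ε + Σ_i (a_i w_ij)⁺)
                        − β · (a_i w_ij)⁻ / (−ε + Σ_i (a_i w_ij)⁻) ] · R_j

with ε° added with the sign of the denominator (avoids cancellation)
and α − β = 1 so the αβ-rule conserves. Bias contributions are absorbed
(not redistributed), the standard choice; the αβ pools exclude biases
entirely, so bias-free layers conserve exactly.

Non-parametric layers have fixed built-in rules: ReLU and dropout pass
relevance through, max-pooling routes winner-takes-all, average pools
redistribute via the equivalent linear map, flatten reshapes, residual
additions split relevance between skip and branch in proportion to each
addend, and batch normalization is folded into the preceding
convolution (canonization) before the rule is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (AvgPool2d, BatchNorm2d, Conv2d, Dropout, Flatten,
                 GlobalAvgPool, Linear, MaxPool2d, ModelGraph, ReLU,
                 ResidualBlock)
from .netkit import ActivationStack

__all__ = ["ContrastiveInit", "RelevanceStack", "RuleConfig", "clrp_init",
           "lrp_epsilon", "lrp_alphabeta", "propagate"]

CONVENTIONS = ("clrp_nminus1", "clrp_n")


@dataclass
class ContrastiveInit:
    """Head-level relevance vector for a target class.

    ``convention`` picks how non-target logits are rescaled:
    ``clrp_nminus1`` sets them to −L_t/(N−1) (so the vector sums to zero
    — degenerate as a conserved score for N=2), ``clrp_n`` (default
    elsewhere) sets them to −L_t/N, giving contrastive score
    S_c = L_t − (N−1)·L_t/N = L_t/N.
    """

    target_class: int
    initial_relevance: np.ndarray
    convention: str
    contrastive_score: float = field(init=False)

    def __post_init__(self):
        self.contrastive_score = float(self.initial_relevance.sum())


@dataclass
class RelevanceStack:
    """Per-stage relevance grids, shape-matched to an ActivationStack."""

    relevances: dict[str, np.ndarray]   # stage -> (C, H, W)
    target_class: int
    contrastive_score: float


@dataclass
class RuleConfig:
    """Propagation-rule settings.

    Default assignment: ε-rule for the linear head, αβ-rule with
    α=1, β=0 (positive contributions only) for convolutions — the usual
    relevance-CAM configuration.
    """

    epsilon: float = 1e-9
    alpha: float = 1.0
    beta: float = 0.0
    rule_assignment: dict[str, str] = field(
        default_factory=lambda: {"linear": "epsilon", "conv": "alphabeta"})

    def validate(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if abs(self.alpha - self.beta - 1.0) > 1e-12:
            raise ValueError("alpha - beta must equal 1 (conservation)")
        bad = set(self.rule_assignment.values()) - {"epsilon", "alphabeta"}
        if bad:
            raise ValueError(f"unknown rules: {sorted(bad)}")


def clrp_init(logits: np.ndarray, target_class: int,
              convention: str = "clrp_n") -> ContrastiveInit:
    """Build the contrastive initial relevance vector at the head."""
    logits = np.asarray(logits, dtype=float)
    n = logits.shape[0]
    if n < 2:
        raise ValueError("contrastive initialization needs >= 2 classes")
    if not 0 <= target_class < n:
        raise ValueError("target_class out of range")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    lt = logits[target_class]
    denom = (n - 1) if convention == "clrp_nminus1" else n
    init = np.full(n, -lt / denom)
    init[target_class] = lt
    return ContrastiveInit(target_class=int(target_class),
                           initial_relevance=init, convention=convention)


def _stab(z, eps):
    """Add ε with the sign of z (zero treated as positive)."""
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def lrp_epsilon(a, w, r_out, eps=1e-9, bias=None):
    """ε-rule on a dense layer; ``w`` is (in, out), relevance flows out→in.

    Bias (if given) enters the denominator but receives no relevance —
    its share is absorbed, so relevance shrinks by the bias fraction.
    """
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    r_out = np.asarray(r_out, dtype=float)
    z = a @ w
    if bias is not None:
        z = z + bias
    s = r_out / _stab(z, eps) if eps > 0 else r_out / z
    return a * (w @ s)


def lrp_alphabeta(a, w, r_out, alpha=1.0, beta=0.0, eps=1e-9):
    """αβ-rule on a dense layer; positive/negative pools split separately."""
    if abs(alpha - beta - 1.0) > 1e-12:
        raise ValueError("alpha - beta must equal 1")
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    r_out = np.asarray(r_out, dtype=float)
    contrib = a[:, None] * w          # (in, out) signed contributions
    pos = np.maximum(contrib, 0.0)
    neg = np.minimum(contrib, 0.0)
    zp = pos.sum(axis=0)
    zn = neg.sum(axis=0)
    rp = pos @ (alpha * r_out / (zp + eps))
    rn = neg @ (beta * r_out / (zn - eps))
    return rp - rn


# -- graph propagation ---------------------------------------------------

def _conv_rule(layer: Conv2d, r_out, rules: RuleConfig, w_eff, b_eff):
    """Apply the assigned rule to a convolution with (possibly folded) weights."""
    a = layer.x
    rule = rules.rule_assignment.get("conv", "alphabeta")
    eps = rules.epsilon
    if rule == "epsilon":
        z = layer.apply(a, w_eff, b_eff)
        s = r_out / _stab(z, eps)
        return a * layer.input_grad(s, w_eff)
    ap, an = np.maximum(a, 0.0), np.minimum(a, 0.0)
    wp, wn = np.maximum(w_eff, 0.0), np.minimum(w_eff, 0.0)
    zp = layer.apply(ap, wp, None) + layer.apply(an, wn, None)
    zn = layer.apply(ap, wn, None) + layer.apply(an, wp, None)
    sp = rules.alpha * r_out / (zp + eps)
    sn = rules.beta * r_out / (zn - eps)
    r_pos = ap * layer.input_grad(sp, wp) + an * layer.input_grad(sp, wn)
    r_neg = ap * layer.input_grad(sn, wn) + an * layer.input_grad(sn, wp)
    return r_pos - r_neg


def _linear_rule(layer: Linear, r_out, rules: RuleConfig):
    a = layer.x[0]
    rule = rules.rule_assignment.get("linear", "epsilon")
    if rule == "epsilon":
        return lrp_epsilon(a, layer.W.T, r_out[0], rules.epsilon,
                           bias=layer.b if layer.has_bias else None)[None]
    return lrp_alphabeta(a, layer.W.T, r_out[0], rules.alpha, rules.beta,
                         rules.epsilon)[None]


def _prop_layers(layers, r, rules: RuleConfig, record=None, boundary_of=None):
    """Walk ``layers`` in reverse, mapping output relevance to input relevance.

    ``record``/``boundary_of`` capture relevance at stage outputs on the
    top-level walk; recursion into residual branches passes neither.
    """
    pending_bn: BatchNorm2d | None = None
    for i in range(len(layers) - 1, -1, -1):
        lyr = layers[i]
        if boundary_of and i in boundary_of:
            record[boundary_of[i]] = r.copy()
        if isinstance(lyr, Linear):
            r = _linear_rule(lyr, r, rules)
        elif isinstance(lyr, BatchNorm2d):
            if pending_bn is not None:
                raise ValueError("batchnorm must directly follow a conv")
            pending_bn = lyr
        elif isinstance(lyr, Conv2d):
            w_eff, b_eff = lyr.W, lyr.b
            if pending_bn is not None:
                scale, shift = pending_bn.effective_scale_shift()
                w_eff = lyr.W * scale[:, None, None, None]
                b0 = lyr.b if lyr.has_bias else 0.0
                b_eff = scale * b0 + shift
                pending_bn = None
            r = _conv_rule(lyr, r, rules, w_eff, b_eff)
        elif isinstance(lyr, (ReLU, Dropout)):
            pass  # identity for relevance
        elif isinstance(lyr, MaxPool2d):
            r = lyr.route(r)
        elif isinstance(lyr, AvgPool2d):
            # equivalent linear map: redistribute proportionally to inputs
            a = lyr.x
            n, c, h, w = a.shape
            k = lyr.ksize
            z = a.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
            s = r / _stab(z, rules.epsilon) / (k * k)
            r = a * np.repeat(np.repeat(s, k, axis=2), k, axis=3)
        elif isinstance(lyr, GlobalAvgPool):
            a = lyr.x
            hw = a.shape[2] * a.shape[3]
            z = a.mean(axis=(2, 3), keepdims=True)
            r = a * (r / _stab(z, rules.epsilon)) / hw
        elif isinstance(lyr, Flatten):
            r = r.reshape(lyr.x.shape)
        elif isinstance(lyr, ResidualBlock):
            x, f = lyr.x, lyr.branch_out
            z = _stab(x + f, rules.epsilon)
            r_skip = r * x / z
            r_branch = _prop_layers(lyr.branch, r * f / z, rules)
            r = r_skip + r_branch
        else:
            raise ValueError(f"no relevance rule for layer kind {lyr.kind!r}")
    if pending_bn is not None:
        raise ValueError("dangling batchnorm with no preceding conv")
    return r


def propagate(model: ModelGraph, acts: ActivationStack, init: ContrastiveInit,
              rules: RuleConfig | None = None) -> RelevanceStack:
    """Backpropagate contrastive relevance from head to every stage output.

    ``acts`` must come from the most recent ``forward_capture`` on this
    model — the rules read the per-layer input caches of that pass.
    Activations are only read, never modified.
    """
    rules = rules or RuleConfig()
    rules.validate()
    r = init.initial_relevance[None, :].astype(float)
    boundary_of = {v: k for k, v in model.stage_boundaries.items()}
    record: dict[str, np.ndarray] = {}
    _prop_layers(model.layers, r, rules, record=record,
                 boundary_of=boundary_of)
    return RelevanceStack(
        relevances={k: v[0] for k, v in record.items()},
        target_class=init.target_class,
        contrastive_score=init.contrastive_score,
    )
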