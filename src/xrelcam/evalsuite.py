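"""Evaluation protocols for saliency methods.

Four protocols, each weakly supervised in the strict sense — ground
truth masks are read for scoring only and never shown to the model:

* weakly supervised segmentation (WSS): threshold the saliency map at a
  fraction of its maximum, score mean IoU against ground-truth masks on
  correctly classified annotated images;
* axiom metrics: per-stage conservation and sensitivity gaps of a
  weighting strategy, both normalized and averaged over images
  (lower is better);
* cascading randomization sanity check: progressively re-initialize the
  network top-down and track the rank correlation of the saliency map
  with the trained-model map — a sound method's maps must degrade;
* Monte-Carlo-dropout sensitivity: average the CAM over repeated
  stochastic forward passes with dropout active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from . import cammethods
from .cammethods import (ALL_STAGES, RELEVANCE_METHODS, SaliencyMap,
                         aggregate_layers, compute_weights, explain,
                         _normalize)
from .lrpcore import RuleConfig, clrp_init, propagate
from .netkit import forward_capture
from .nn import ModelGraph
from .netkit import randomize_stages

__all__ = ["WSSReport", "AxiomReport", "extract_mask", "miou", "run_wss",
           "conservation_metric", "sensitivity_metric",
           "cascading_randomization", "mc_dropout_cam"]

DEFAULT_THRESHOLD = 0.2
DEFAULT_AGGREGATIONS = (
    ("layer4",),
    ("layer4", "layer3"),
    ("layer4", "layer3", "layer2"),
    ("layer4", "layer3", "layer2", "layer1"),
)


@dataclass
class WSSReport:
    method: str
    threshold: float
    n_images: int
    per_stage_miou: dict[str, float]          # stage -> mIoU in percent
    per_aggregation_miou: dict[str, float]    # "layer4+3" style -> percent
    excluded_ids: list[str] = field(default_factory=list)


@dataclass
class AxiomReport:
    method: str
    conservation: dict[str, float]   # stage -> score
    sensitivity: dict[str, float]
    conservation_avg: float = 0.0
    sensitivity_avg: float = 0.0

    def __post_init__(self):
        if self.conservation:
            self.conservation_avg = float(np.mean(list(self.conservation.values())))
        if self.sensitivity:
            self.sensitivity_avg = float(np.mean(list(self.sensitivity.values())))


def extract_mask(saliency, threshold_fraction: float = DEFAULT_THRESHOLD):
    """Pixels at or above ``threshold_fraction`` of the map maximum."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    values = saliency.values if isinstance(saliency, SaliencyMap) else saliency
    peak = values.max()
    if peak <= 0:
        return np.zeros(values.shape, dtype=bool)
    return values >= threshold_fraction * peak


def miou(pred_masks, gt_masks) -> float:
    """Mean IoU over aligned mask pairs; an empty union scores IoU 1."""
    if len(pred_masks) != len(gt_masks):
        raise ValueError("mask lists must be aligned")
    ious = []
    for p, g in zip(pred_masks, gt_masks):
        if p.shape != g.shape:
            raise ValueError("mask shapes differ")
        union = np.logical_or(p, g).sum()
        if union == 0:
            ious.append(1.0)
        else:
            ious.append(np.logical_and(p, g).sum() / union)
    return float(np.mean(ious))


def _correct_annotated(model, samples, annotated_class=0):
    """Annotated-class samples the model classifies correctly (+ excluded ids)."""
    keep, excluded = [], []
    for s in samples:
        if s.label != annotated_class:
            continue
        acts = forward_capture(model, s.image)
        if acts.predicted_class == s.label:
            keep.append(s)
        else:
            excluded.append(s.sample_id)
    return keep, excluded


def run_wss(model: ModelGraph, test_samples, method: str = "xrelevancecam",
            stages=ALL_STAGES, aggregations=DEFAULT_AGGREGATIONS,
            threshold: float = DEFAULT_THRESHOLD,
            rules: RuleConfig | None = None,
            annotated_class: int = 0) -> WSSReport:
    """Weakly supervised segmentation benchmark on the annotated class."""
    keep, excluded = _correct_annotated(model, test_samples, annotated_class)
    stage_preds = {s: [] for s in stages}
    agg_preds = {"+".join(a): [] for a in aggregations}
    gts = []
    for s in keep:
        maps = explain(model, s.image, annotated_class, method=method,
                       stages=stages, rules=rules, aggregate=False)
        gts.append(s.mask)
        for st in stages:
            stage_preds[st].append(extract_mask(maps[st], threshold))
        for agg in aggregations:
            m = aggregate_layers(maps, agg)
            agg_preds["+".join(agg)].append(extract_mask(m, threshold))
    per_stage = {st: 100.0 * miou(stage_preds[st], gts) if keep else float("nan")
                 for st in stages}
    per_agg = {name: 100.0 * miou(preds, gts) if keep else float("nan")
               for name, preds in agg_preds.items()}
    return WSSReport(method=method, threshold=threshold, n_images=len(keep),
                     per_stage_miou=per_stage, per_aggregation_miou=per_agg,
                     excluded_ids=excluded)


def _score_and_weights(model, image, method, stage, rules, convention):
    """Return (S_c, weights, relevance or None, acts) for one image.

    S_c is the contrastive score for relevance-propagation methods and
    the raw target logit for gradient methods; the target is the
    predicted class.
    """
    acts = forward_capture(model, image)
    c = acts.predicted_class
    rels = grads = None
    if method in RELEVANCE_METHODS:
        init = clrp_init(acts.logits, c, convention)
        rels = propagate(model, acts, init, rules)
        s_c = init.contrastive_score
    else:
        grads = cammethods._gradients_for(model, acts, c)
        s_c = float(acts.logits[c])
    w = compute_weights(method, acts, stage, rels, grads, c)
    return s_c, w, rels, acts, c


def conservation_metric(model: ModelGraph, images, method: str, stage: str,
                        rules: RuleConfig | None = None,
                        convention: str = "clrp_n",
                        accounting: str = "activation") -> float:
    """Mean relative conservation gap  |S_c − Σ_k w_k Σ_ij X| / |S_c|.

    ``accounting="activation"`` uses X = A^{lk} (the axiom's weighted
    activation sum); ``accounting="relevance"`` uses X = R^{lk} instead.
    Images with S_c = 0 are skipped (and counted in the denominator n
    reported by callers if needed).
    """
    rules = rules or RuleConfig()
    gaps = []
    for image in images:
        s_c, w, rels, acts, c = _score_and_weights(
            model, image, method, stage, rules, convention)
        if abs(s_c) < 1e-12:
            continue
        if accounting == "activation":
            per_ch = acts.activations[stage].reshape(len(w.weights), -1).sum(axis=1)
        elif accounting == "relevance":
            if rels is None:
                raise ValueError("relevance accounting needs a relevance method")
            per_ch = rels.relevances[stage].reshape(len(w.weights), -1).sum(axis=1)
        else:
            raise ValueError(f"unknown accounting {accounting!r}")
        total = float((w.weights * per_ch).sum())
        gaps.append(abs(s_c - total) / abs(s_c))
    if not gaps:
        raise ValueError("no images with nonzero score")
    return float(np.mean(gaps))


def _score_from_logits(logits, c, method, convention):
    if method in RELEVANCE_METHODS:
        return clrp_init(logits, c, convention).contrastive_score
    return float(logits[c])


def sensitivity_metric(model: ModelGraph, images, method: str, stage: str,
                       rules: RuleConfig | None = None,
                       convention: str = "clrp_n",
                       accounting: str = "relevance") -> float:
    """Mean normalized sensitivity gap of the channel weights.

    For each channel k, the score drop S_c(A) − S_c(A with channel k
    zeroed) is computed by resuming the forward pass from the stage; the
    metric compares it with the weight's attributed mass
    Σ_ij w_k R_ij (``accounting="relevance"``, the printed form) or
    Σ_ij w_k A_ij (``accounting="activation"``, the axiom's form),
    normalized by the total absolute score drop. Images with zero
    denominator are skipped.
    """
    rules = rules or RuleConfig()
    vals = []
    for image in images:
        s_c, w, rels, acts, c = _score_and_weights(
            model, image, method, stage, rules, convention)
        a = acts.activations[stage]
        n_ch = a.shape[0]
        num = den = 0.0
        for k in range(n_ch):
            ablated = a.copy()
            ablated[k] = 0.0
            logits_k = model.forward_from(stage, ablated[None])[0]
            drop = s_c - _score_from_logits(logits_k, c, method, convention)
            if accounting == "relevance":
                mass = float(w.weights[k] * rels.relevances[stage][k].sum()) \
                    if rels is not None else \
                    float(w.weights[k] * a[k].sum())
            elif accounting == "activation":
                mass = float(w.weights[k] * a[k].sum())
            else:
                raise ValueError(f"unknown accounting {accounting!r}")
            num += abs(drop - mass)
            den += abs(drop)
        if den < 1e-12:
            continue
        vals.append(num / den)
    if not vals:
        raise ValueError("no images with nonzero score drops")
    return float(np.mean(vals))


def cascading_randomization(model: ModelGraph, image, method: str = "xrelevancecam",
                            stage_to_view: str = "layer3", seed: int = 0,
                            rules: RuleConfig | None = None,
                            target_class: int | None = None):
    """Randomize head + stages top-down; track map similarity to t=0.

    Returns ``(maps, similarities)`` — six saliency maps (t = 0..5
    randomized units) and their Spearman rank correlations (on absolute
    map values) against the trained-model map. A valid explanation
    method's similarity must decay.
    """
    if target_class is None:
        target_class = forward_capture(model, image).predicted_class
    maps, sims = [], []
    ref = None
    for t in range(6):
        m_t = randomize_stages(model, t, seed=seed)
        cam = explain(m_t, image, target_class, method=method,
                      stages=(stage_to_view,), rules=rules,
                      aggregate=False)[stage_to_view]
        maps.append(cam)
        flat = np.abs(cam.values).ravel()
        if t == 0:
            ref = flat
            sims.append(1.0)
        else:
            if np.ptp(flat) < 1e-12 or np.ptp(ref) < 1e-12:
                sims.append(0.0)
            else:
                sims.append(float(spearmanr(ref, flat).statistic))
    return maps, sims


def mc_dropout_cam(model: ModelGraph, image, method: str = "xrelevancecam",
                   stage: str = "layer4", n_passes: int = 10, seed: int = 0,
                   rules: RuleConfig | None = None,
                   target_class: int | None = None) -> SaliencyMap:
    """Average the CAM over stochastic dropout passes, then normalize.

    ``stage`` may be a stage name or ``"aggregate"``. With no dropout
    layers (rate 0) every pass is identical and the result equals a
    single deterministic pass. Fully reproducible given ``seed``.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    rng = np.random.default_rng(seed)
    if target_class is None:
        target_class = forward_capture(model, image).predicted_class
    acc = None
    for _ in range(n_passes):
        maps, raws = explain(model, image, target_class, method=method,
                             stages=ALL_STAGES, rules=rules, aggregate=False,
                             dropout_on=True, rng=rng, return_raw=True)
        if stage == "aggregate":
            contrib = np.mean([maps[s].values for s in ALL_STAGES], axis=0)
        else:
            contrib = raws[stage]
        acc = contrib if acc is None else acc + contrib
    provenance = frozenset(ALL_STAGES) if stage == "aggregate" \
        else frozenset({stage})
    return SaliencyMap(_normalize(acc / n_passes), provenance, target_class)
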