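"""Image-specific fine-tuning: alternating label and classifier updates.

Given a pre-trained network and one cropped test region, segmentation and
model are refined jointly by coordinate descent on the CRF energy:

1. *label update* — with the network fixed, the globally optimal binary
   labeling under the current probability map is found by graph cuts,
   honoring any scribble constraints;
2. *network update* — with the labeling fixed, the classifier block is
   refitted to it by gradient descent on a weighted cross-entropy (summed
   over pixels), where scribbles weigh ``omega``, uncertain pixels weigh 0
   and the rest weigh 1.  Only classifier parameters move; the backbone
   features were cached once, which is what makes the update cheap.

With no scribbles this is unsupervised refinement: the scribble set and
scribble-based uncertainty are empty and no pixel carries weight omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crf as _crf
from .crf import CRFParams, ScribbleSet, energy, solve_labels
from .errors import InputError
from .instance_prep import (BoundingBox, ImageRegion, crop_region,
                            map_indices_to_resized, normalize_region,
                            resize_for_network, restore_to_source)
from .networks import (FeatureCache, Network, ProbabilityMap,
                       softmax_cross_entropy)
from .uncertainty import (GEODESIC_GAMMA, UncertaintyParams, build_weight_map,
                          network_uncertainty, scribble_uncertainty)


@dataclass(frozen=True)
class FineTuneConfig:
    """Alternation schedule and per-step optimizer settings."""

    rounds: int = 4
    lr: float = 1e-2
    steps: int = 20
    momentum: float = 0.0
    crf: CRFParams = field(default_factory=CRFParams)
    unc: UncertaintyParams = field(default_factory=UncertaintyParams)
    gamma: float = GEODESIC_GAMMA
    recompute_network_uncertainty: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 0:
            raise InputError("rounds must be >= 0")
        if self.lr <= 0 or self.steps < 1:
            raise InputError("lr must be positive and steps >= 1")


@dataclass
class RoundRecord:
    """Energies around one label update, plus optional Dice-vs-reference."""

    energy_before: float
    energy_after: float
    loss_before: float
    loss_after: float
    dice: float | None = None


@dataclass
class SegmentationState:
    labeling: np.ndarray
    prob: ProbabilityMap
    cache: FeatureCache
    history: list[RoundRecord]


def weighted_loss(prob, labeling, weights) -> float:
    """Weighted negative log-likelihood, summed (not averaged) over pixels."""
    p = np.asarray(prob.p if hasattr(prob, "p") else prob, dtype=np.float64)
    y = np.asarray(labeling, dtype=np.float64)
    w = np.asarray(weights.w if hasattr(weights, "w") else weights, dtype=np.float64)
    if not (p.shape == y.shape == w.shape):
        raise InputError("probability, labeling and weight shapes differ")
    pc = np.clip(p, _crf.PROB_EPS, 1.0 - _crf.PROB_EPS)
    return float(-np.sum(w * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))))


def network_update(net: Network, cache: FeatureCache, labeling, weights,
                   lr: float, steps: int, momentum: float = 0.0,
                   seed: int = 0) -> dict[str, np.ndarray]:
    """Refit the classifier block to ``labeling`` on the cached features.

    Plain (optionally momentum) gradient descent on the summed weighted
    cross-entropy; every non-classifier parameter is untouched.  The run is
    deterministic; ``seed`` is accepted for interface symmetry but no
    randomness is drawn.  Raises if the cache no longer matches the
    backbone.  Returns the updated classifier parameter dict.
    """
    net.check_cache(cache)
    y = np.asarray(labeling, dtype=np.float64)
    w = np.asarray(weights.w if hasattr(weights, "w") else weights, dtype=np.float64)
    if y.shape != cache.spatial_shape or w.shape != cache.spatial_shape:
        raise InputError("labeling/weights shape does not match the cached region")
    c = net.classifier
    velocity = {k: 0.0 for k in ("W", "b")}
    for _ in range(steps):
        logits = net.classifier_logits_from_cache(cache)
        # objective is the summed weighted NLL; the descent direction is the
        # per-pixel mean gradient so the step size is region-size invariant
        _, dlogits = softmax_cross_entropy(logits, y, w, reduction="mean")
        out_ch = dlogits.shape[0]
        dflat = dlogits.reshape(out_ch, -1)
        cols = cache.concat_features.reshape(cache.concat_features.shape[0], -1)
        dw = (dflat @ cols.T).reshape(c.weight.shape)
        db = dflat.sum(axis=1)
        if momentum > 0.0:
            velocity["W"] = momentum * velocity["W"] + dw
            velocity["b"] = momentum * velocity["b"] + db
            dw, db = velocity["W"], velocity["b"]
        c.weight = (c.weight - lr * dw).astype(c.weight.dtype)
        c.bias = (c.bias - lr * db).astype(c.bias.dtype)
    return {k: v for k, v in net.parameters().items()
            if k in net.classifier_parameter_names()}


def refine(net: Network, region: ImageRegion, scribbles: ScribbleSet | None,
           cfg: FineTuneConfig, reference: np.ndarray | None = None) -> SegmentationState:
    """Run the alternating refinement on one prepared (normalized, resized)
    region and return the final state.

    Each round: (a) graph-cut label update, (b) uncertainty sets and weight
    map, (c) classifier update on the cached features, (d) probability
    refresh from the cache.  ``rounds == 0`` degenerates to the initial
    forward pass plus a single CRF solve (network + CRF baseline).
    """
    x = region.intensities if hasattr(region, "intensities") else np.asarray(region)
    if scribbles is None:
        scribbles = ScribbleSet.empty(x.shape)
    if scribbles.fg.shape != x.shape:
        raise InputError("scribbles must be given in region coordinates")
    # stateless per image: the classifier is adapted to this region only and
    # restored afterwards, so successive test images start from the same
    # trained checkpoint
    snapshot = {k: v.copy() for k, v in net.parameters().items()
                if k in net.classifier_parameter_names()}
    try:
        cache = net.cache_features(x)
        prob = net.probability_from_cache(cache)
        labeling = (prob.p > 0.5).astype(np.uint8)
        history: list[RoundRecord] = []
        if cfg.rounds == 0:
            labeling = solve_labels(prob, x, scribbles, cfg.crf)
            return SegmentationState(labeling, prob, cache, history)
        frozen_u_p = None
        if not cfg.recompute_network_uncertainty:
            frozen_u_p = network_uncertainty(prob, cfg.unc.t0, cfg.unc.t1)
        for _ in range(cfg.rounds):
            e_before = energy(labeling, prob.p, x, scribbles, cfg.crf)
            labeling = solve_labels(prob, x, scribbles, cfg.crf)
            e_after = energy(labeling, prob.p, x, scribbles, cfg.crf)
            u_p = (network_uncertainty(prob, cfg.unc.t0, cfg.unc.t1)
                   if frozen_u_p is None else frozen_u_p)
            u_s = scribble_uncertainty(x, scribbles, labeling, cfg.unc.epsilon, cfg.gamma)
            wmap = build_weight_map(scribbles, u_p, u_s, cfg.unc.omega)
            loss_before = weighted_loss(prob, labeling, wmap)
            network_update(net, cache, labeling, wmap, cfg.lr, cfg.steps,
                           cfg.momentum, cfg.seed)
            prob = net.probability_from_cache(cache)
            loss_after = weighted_loss(prob, labeling, wmap)
            rec = RoundRecord(e_before, e_after, loss_before, loss_after)
            if reference is not None:
                rec.dice = _dice(labeling, reference)
            history.append(rec)
        return SegmentationState(labeling, prob, cache, history)
    finally:
        params = net.parameters()
        params.update(snapshot)
        net.set_parameters(params)


def segment(net: Network, image: np.ndarray, box: BoundingBox,
            scribbles: ScribbleSet | None, cfg: FineTuneConfig,
            resize_mode: str | None = None, resize_target: int | None = None) -> np.ndarray:
    """End-to-end entry point: crop, normalize, resize, refine, restore.

    ``scribbles`` are masks in source-image coordinates and must lie inside
    the box.  Returns a binary labeling on the full image canvas.
    """
    image = np.asarray(image)
    region = crop_region(image, box)
    region = normalize_region(region)
    if resize_mode is None:
        resize_mode = "2d_min_side" if image.ndim == 2 else "3d_max_side"
    if resize_target is None:
        resize_target = 96 if image.ndim == 2 else 80
    region = resize_for_network(region, resize_mode, resize_target)
    region_scribbles = _scribbles_to_region(scribbles, box, region) \
        if scribbles is not None else None
    state = refine(net, region, region_scribbles, cfg)
    return restore_to_source(state.labeling, region, image.shape, kind="mask")


def _scribbles_to_region(scribbles: ScribbleSet, box: BoundingBox,
                         region: ImageRegion) -> ScribbleSet:
    crop_shape = region.original_crop_shape
    out_shape = region.shape
    masks = []
    for mask in (scribbles.fg, scribbles.bg):
        idx = np.argwhere(mask)
        if idx.size and not all(
                np.all(idx[:, ax] >= box.lo[ax]) and np.all(idx[:, ax] < box.hi[ax])
                for ax in range(box.ndim)):
            raise InputError("scribbles must lie inside the bounding box")
        local = idx - np.array(box.lo)
        mapped = map_indices_to_resized(local, crop_shape, out_shape) if idx.size \
            else local.reshape(0, box.ndim)
        m = np.zeros(out_shape, dtype=bool)
        if mapped.size:
            m[tuple(mapped.T)] = True
        masks.append(m)
    fg, bg = masks
    bg &= ~fg  # resolve rare collisions after downscaling in favor of foreground
    return ScribbleSet(fg, bg)


def _dice(a, b) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
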