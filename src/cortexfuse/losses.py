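"""Training objectives.

Segmentation terms (DSC+BCE), shape-consistency terms built on concave hulls
and contours, the excess penalty discouraging vessel predictions outside the
refined cortex annotation, the supervised-contrastive objective for encoder
pre-training, masked BCE terms for HSI fine-tuning on inner/outer/unknown
ground truth, and an equivariance regularizer.

Hull regions and contour maps are geometric quantities of the *binarized*
prediction; they are computed on detached masks and treated as constant
targets within a step. Gradients flow through the soft comparisons of the
predicted probabilities against those constant targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny

from .hull import hull_region
from .nn import Tensor

_ELLIPSE_3x3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_EPS = 1e-6


@dataclass
class LossConfig:
    alpha: float = 10.0               # Eq. 1 factor
    tau: float = 0.1                  # SupCon temperature
    binarize_threshold: float = 0.5   # hull/contour geometry

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.binarize_threshold < 1:
            raise ValueError("binarize_threshold must lie in (0, 1)")


@dataclass
class LossBreakdown:
    l_ctx: float
    l_self_hull: float
    l_cont: float
    l_vsl: float
    l_cross_hull: float
    l_excess: float
    total: float
    total_tensor: Tensor = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("l_ctx", "l_self_hull", "l_cont", "l_vsl",
                 "l_cross_hull", "l_excess", "total")}


# ---------------------------------------------------------------- primitives
def _lift(pred) -> Tensor:
    t = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    return t


def _batched(pred: Tensor) -> Tensor:
    """Normalise to (N, H, W)."""
    if pred.ndim == 2:
        return pred.reshape(1, *pred.shape)
    if pred.ndim == 4:          # (N, 1, H, W)
        n, c, h, w = pred.shape
        if c != 1:
            raise ValueError("expected single-channel probability maps")
        return pred.reshape(n, h, w)
    if pred.ndim == 3:
        return pred
    raise ValueError(f"unsupported prediction rank {pred.ndim}")


def _target_like(target, pred: Tensor) -> np.ndarray:
    t = np.asarray(target, dtype=float)
    if t.ndim == 2:
        t = np.broadcast_to(t, pred.shape)
    if t.shape != tuple(pred.shape):
        raise ValueError(f"target shape {t.shape} does not match prediction "
                         f"{tuple(pred.shape)}")
    return t


def _soft_dice(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    inter = (pred * target).sum()
    return (2.0 * inter + smooth) / (pred.sum() + target.sum() + smooth)


def _bce_mean(pred: Tensor, target: np.ndarray) -> Tensor:
    p = pred.clip(_EPS, 1.0 - _EPS)
    ll = p.log() * target + (1.0 - p).log() * (1.0 - target)
    return -ll.mean()


def _binarize(pred: Tensor, threshold: float) -> np.ndarray:
    return pred.data >= threshold


# ------------------------------------------------------------- segmentation
def dsc_bce_loss(pred, target) -> Tensor:
    """(1 - soft-Dice) + mean binary cross-entropy."""
    p = _batched(_lift(pred))
    t = _target_like(target, p)
    return (1.0 - _soft_dice(p, t)) + _bce_mean(p, t)


def contour_loss(pred_cortex, contour_pseudo,
                 config: LossConfig | None = None) -> Tensor:
    """BCE between the predicted mask's contour and the contour pseudo-labels.

    The predicted contour is the Canny edge map of the binarized prediction
    dilated with a 3x3 elliptical kernel (constant geometry). The loss value
    is the BCE of that hard edge indicator against target 1 on the pixels
    where ``contour_pseudo`` is positive; the gradient is routed through the
    soft edge-likelihood 4*p*(1-p) at those pixels (straight-through).
    """
    cfg = config or LossConfig()
    p = _batched(_lift(pred_cortex))
    pseudo = np.asarray(contour_pseudo, bool)
    if pseudo.ndim == 2:
        pseudo = np.broadcast_to(pseudo, p.shape)
    if not pseudo.any():
        return Tensor(np.float64(0.0))
    hard = np.zeros(p.shape, float)
    for i in range(p.shape[0]):
        mask = _binarize(p, cfg.binarize_threshold)[i]
        edges = canny(mask.astype(float), sigma=1.0)
        hard[i] = ndi.binary_dilation(edges, structure=_ELLIPSE_3x3)
    sel = p[pseudo]
    soft = 4.0 * sel * (1.0 - sel)                       # edge likelihood
    soft_bce = -(soft.clip(_EPS, 1.0 - _EPS)).log()
    hard_bce = -np.log(np.clip(hard[pseudo], _EPS, 1.0 - _EPS))
    # straight-through: value from the hard edge map, gradient from soft
    return (soft_bce + (hard_bce - soft_bce.data)).mean()


def self_hull_loss(pred_cortex, config: LossConfig | None = None) -> Tensor:
    """1 - soft-Dice between the prediction and its own concave-hull fill."""
    cfg = config or LossConfig()
    p = _batched(_lift(pred_cortex))
    terms = []
    for i in range(p.shape[0]):
        mask = _binarize(p, cfg.binarize_threshold)[i]
        if not mask.any():
            terms.append(Tensor(np.float64(1.0)))
            continue
        hull = hull_region(mask).astype(float)
        terms.append(1.0 - _soft_dice(p[i], hull))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


def cross_hull_loss(pred_cortex, pred_vessel,
                    config: LossConfig | None = None) -> Tensor:
    """1 - Dice between the cortex-hull and vessel-hull filled regions.

    Vessels spread over the cortical surface, so the concave hull of the
    vessel mask should coincide with the cortex hull. The value is the hard
    Dice complement of the two hull fills (either hull empty -> 1); the
    gradient is routed through the symmetric soft-Dice of each probability
    map against the *other* mask's hull (straight-through).
    """
    cfg = config or LossConfig()
    pc = _batched(_lift(pred_cortex))
    pv = _batched(_lift(pred_vessel))
    if tuple(pc.shape) != tuple(pv.shape):
        raise ValueError("cortex and vessel predictions must share a shape")
    terms = []
    for i in range(pc.shape[0]):
        mc = _binarize(pc, cfg.binarize_threshold)[i]
        mv = _binarize(pv, cfg.binarize_threshold)[i]
        if not mc.any() or not mv.any():
            terms.append(Tensor(np.float64(1.0)))
            continue
        hc = hull_region(mc)
        hv = hull_region(mv)
        hard = 1.0 - 2.0 * (hc & hv).sum() / (hc.sum() + hv.sum())
        soft = 1.0 - 0.5 * (_soft_dice(pc[i], hv.astype(float))
                            + _soft_dice(pv[i], hc.astype(float)))
        terms.append(soft + (hard - soft.data))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


def excess_loss(pred_vessel_batch, refined_annotation_batch,
                alpha: float = 10.0) -> Tensor:
    """Eq. 1: mean over the batch of ln(alpha * DSC(1 - Y, Yhat) + 1).

    The Dice term is unsmoothed (0/0 -> 0) so a prediction fully inside the
    refined annotation scores exactly 0.
    """
    p = _batched(_lift(pred_vessel_batch))
    y = _target_like(refined_annotation_batch, p)
    comp = 1.0 - y
    terms = []
    for i in range(p.shape[0]):
        denom_const = float(p.data[i].sum() + comp[i].sum())
        if denom_const == 0.0:
            terms.append(Tensor(np.float64(0.0)))
            continue
        dice = 2.0 * (p[i] * comp[i]).sum() / (p[i].sum() + comp[i].sum())
        terms.append((alpha * dice + 1.0).log())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


def total_rgb_loss(outputs, pseudolabels, config: LossConfig | None = None
                   ) -> LossBreakdown:
    """Unweighted Eq. 2 sum over all six RGB-training terms."""
    cfg = config or LossConfig()
    if isinstance(pseudolabels, dict):
        labels = pseudolabels
    else:
        labels = {"cortex_mask": getattr(pseudolabels, "cortex_mask", None),
                  "contour_map": getattr(pseudolabels, "contour_map", None),
                  "vessel_mask": getattr(pseudolabels, "vessel_mask", None)}
    for key in ("cortex_mask", "contour_map", "vessel_mask"):
        if labels.get(key) is None:
            raise ValueError(f"missing pseudo-label: {key}")
    pc, pv = outputs.cortex_prob, outputs.vessel_prob
    l_ctx = dsc_bce_loss(pc, labels["cortex_mask"])
    l_self = self_hull_loss(pc, cfg)
    l_cont = contour_loss(pc, labels["contour_map"], cfg)
    l_vsl = dsc_bce_loss(pv, labels["vessel_mask"])
    l_cross = cross_hull_loss(pc, pv, cfg)
    l_exc = excess_loss(pv, labels["cortex_mask"], cfg.alpha)
    total = l_ctx + l_self + l_cont + l_vsl + l_cross + l_exc
    return LossBreakdown(
        l_ctx=float(l_ctx.data), l_self_hull=float(l_self.data),
        l_cont=float(l_cont.data), l_vsl=float(l_vsl.data),
        l_cross_hull=float(l_cross.data), l_excess=float(l_exc.data),
        total=float(total.data), total_tensor=total)


# --------------------------------------------------------------- contrastive
def supcon_loss(embeddings, labels, tau: float = 0.1) -> Tensor:
    """Supervised contrastive loss (L_out formulation) over unit embeddings."""
    z = _lift(embeddings)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need a batch of at least two embedding vectors")
    labels = np.asarray(labels).reshape(-1)
    if len(labels) != z.shape[0]:
        raise ValueError("labels must match the batch size")
    n = z.shape[0]
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)
    pos = same & off_diag
    anchors = np.nonzero(pos.any(axis=1))[0]
    if len(anchors) == 0:
        raise ValueError("no anchor has a positive partner")
    sim = (z @ z.transpose(1, 0)) / tau
    # stabilized log-sum-exp over non-self candidates
    shift = sim.data.max()
    exps = (sim - shift).exp() * off_diag
    log_denom = exps.sum(axis=1, keepdims=True).log() + shift
    log_prob = sim - log_denom
    terms = []
    for i in anchors:
        idx = np.nonzero(pos[i])[0]
        acc = log_prob[i, idx[0]]
        for j in idx[1:]:
            acc = acc + log_prob[i, j]
        terms.append(-acc / len(idx))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)


# ---------------------------------------------------------------- fine-tuning
def masked_cortex_bce(pred_cortex, adjusted) -> Tensor:
    """BCE with target 1 on inner and 0 on outer pixels; unknown excluded."""
    p = _batched(_lift(pred_cortex))
    lab = np.asarray(getattr(adjusted, "labels", adjusted))
    if lab.ndim == 2:
        lab = np.broadcast_to(lab, p.shape)
    known = lab > 0
    if not known.any():
        warnings.warn("adjusted ground truth is all-unknown; loss is 0")
        return Tensor(np.float64(0.0))
    target = (lab[known] == 1).astype(float)
    sel = p[known].clip(_EPS, 1.0 - _EPS)
    ll = sel.log() * target + (1.0 - sel).log() * (1.0 - target)
    return -ll.mean()


def masked_vessel_bce(pred_vessel, vessel_pseudo, adjusted) -> Tensor:
    """BCE with target = vessel pseudo-labels on inner pixels, 0 on outer."""
    p = _batched(_lift(pred_vessel))
    lab = np.asarray(getattr(adjusted, "labels", adjusted))
    pseudo = np.asarray(vessel_pseudo, bool)
    if lab.ndim == 2:
        lab = np.broadcast_to(lab, p.shape)
    if pseudo.ndim == 2:
        pseudo = np.broadcast_to(pseudo, p.shape)
    known = lab > 0
    if not known.any():
        warnings.warn("adjusted ground truth is all-unknown; loss is 0")
        return Tensor(np.float64(0.0))
    target = np.where(lab == 1, pseudo.astype(float), 0.0)[known]
    sel = p[known].clip(_EPS, 1.0 - _EPS)
    ll = sel.log() * target + (1.0 - sel).log() * (1.0 - target)
    return -ll.mean()


# --------------------------------------------------------------- equivariance
_TRANSFORMS = {
    "identity": (lambda a: a, lambda t: t),
    "hflip": (lambda a: a[..., :, ::-1].copy(),
              lambda t: t[..., :, ::-1]),
    "vflip": (lambda a: a[..., ::-1, :].copy(),
              lambda t: t[..., ::-1, :]),
    "rot180": (lambda a: a[..., ::-1, ::-1].copy(),
               lambda t: t[..., ::-1, ::-1]),
}


def equivariance_loss(model, image, modality: str = "rgb",
                      transform_set=("hflip", "vflip", "rot180"),
                      seed: int = 0, n_samples: int = 2) -> Tensor:
    """MSE between predictions of transformed inputs and transformed
    predictions, averaged over randomly sampled grid-invertible transforms."""
    unknown = set(transform_set) - set(_TRANSFORMS)
    if unknown:
        raise ValueError(f"unknown transforms: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    x = np.asarray(image, dtype=np.float32)
    base = model.forward(x, modality)
    picks = rng.choice(list(transform_set),
                       size=min(n_samples, len(transform_set)), replace=False)
    terms = []
    for name in picks:
        f_arr, f_tensor = _TRANSFORMS[name]
        out_t = model.forward(f_arr(x), modality)
        for branch, ref in ((out_t.cortex_prob, base.cortex_prob),
                            (out_t.vessel_prob, base.vessel_prob)):
            diff = branch - f_tensor(ref)
            terms.append((diff * diff).mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms)
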