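"""Probability-map fusion (Eqs. 3-4) and a minimal reference tissue classifier.

Any 4-class tissue probability map (healthy, tumor, vessel, dura) is first
reduced to a healthy-vs-non-healthy pair with

    Qclf = softmax([Ph, max(Pt, Pv, Pd)])                               (Eq. 3)

and then combined with the cortex probability Pctx and vessel probability
Pvsl from the surface-segmentation network:

    Pout = [Qh*(1-Pvsl)*Pctx, Qnh*(1-Pvsl)*Pctx, Pvsl*Pctx, 1-Pctx]    (Eq. 4)

The four output channels are healthy, tumor, vessel, background; dura is
folded into "non-healthy" by Eq. 3 and never reappears. The vessel channel
is exactly Pvsl*Pctx, so the surface network's vessel evidence always
survives fusion. Note Eq. 3 applies a softmax to probabilities rather than
logits, which compresses the pair toward (0.5, 0.5); it is implemented as
printed, so downstream consumers should not treat Qclf as calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import AdamW, LeakyReLU, Linear, Sequential, Tensor, cosine_lr, \
    manual_seed


# ------------------------------------------------------------------- types
@dataclass
class TissueProbMap:
    """Per-pixel 4-vector (Ph, Pt, Pv, Pd): healthy, tumor, vessel, dura."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[-1] != 4:
            raise ValueError("probs must have shape (H, W, 4)")
        if np.isnan(p).any():
            raise ValueError("probability map contains NaN")
        if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")
        self.probs = p


@dataclass
class FusedMap:
    """Fused output: (healthy, tumor, vessel, background) probabilities."""

    probs: np.ndarray
    class_map: np.ndarray

    #: class indices of the fused map
    HEALTHY, TUMOR, VESSEL, BACKGROUND = 0, 1, 2, 3


#: render_map palette (RGB, uint8): healthy green, tumor red, vessel blue,
#: background gray
PALETTE = np.array([[0, 153, 51],
                    [204, 0, 0],
                    [0, 51, 204],
                    [128, 128, 128]], dtype=np.uint8)


# --------------------------------------------------------------------- Eq. 3
def transform_probs(pclf) -> np.ndarray:
    """Reduce a 4-class tissue map to Qclf = softmax([Ph, max(Pt, Pv, Pd)])."""
    if not isinstance(pclf, TissueProbMap):
        pclf = TissueProbMap(np.asarray(pclf))
    p = pclf.probs
    ph = p[..., 0]
    pnh = p[..., 1:].max(axis=-1)
    # pairwise softmax in a numerically stable closed form
    q_h = 1.0 / (1.0 + np.exp(pnh - ph))
    return np.stack([q_h, 1.0 - q_h], axis=-1)


# --------------------------------------------------------------------- Eq. 4
def _force_exact_sum(probs: np.ndarray) -> np.ndarray:
    """Push any rounding residual (a few ulp) onto the largest channel among
    healthy/tumor/background so each pixel's four probabilities sum to 1.0
    exactly; the vessel channel is never touched, preserving Pvsl*Pctx."""
    adjustable = probs[..., [0, 1, 3]]
    target = np.array([0, 1, 3])[adjustable.argmax(axis=-1)]
    idx = np.indices(probs.shape[:-1])
    for _ in range(4):
        residual = probs.sum(axis=-1) - 1.0
        if not residual.any():
            break
        probs[(*idx, target)] -= residual
    return probs


def fuse(qclf: np.ndarray, pctx: np.ndarray, pvsl: np.ndarray) -> FusedMap:
    """Combine Qclf with the cortex/vessel probability masks via Eq. 4."""
    qclf = np.asarray(qclf, dtype=float)
    pctx = np.asarray(pctx, dtype=float)
    pvsl = np.asarray(pvsl, dtype=float)
    if qclf.ndim != 3 or qclf.shape[-1] != 2:
        raise ValueError("qclf must have shape (H, W, 2)")
    if pctx.shape != qclf.shape[:2] or pvsl.shape != qclf.shape[:2]:
        raise ValueError("pctx/pvsl shapes must match qclf's spatial shape")
    inside = (1.0 - pvsl) * pctx
    probs = np.stack([qclf[..., 0] * inside,
                      qclf[..., 1] * inside,
                      pvsl * pctx,
                      1.0 - pctx], axis=-1)
    probs = _force_exact_sum(probs)
    # np.argmax already breaks ties toward the lowest class index
    return FusedMap(probs=probs, class_map=probs.argmax(axis=-1))


def fuse_tissue_map(pclf, pctx, pvsl) -> FusedMap:
    """Convenience: Eq. 3 followed by Eq. 4."""
    return fuse(transform_probs(pclf), pctx, pvsl)


# ----------------------------------------------------------------- rendering
def render_map(fused: FusedMap) -> np.ndarray:
    """Color the class map: green/red/blue/gray for h/t/v/background."""
    return PALETTE[np.asarray(fused.class_map, dtype=int)]


# ------------------------------------------------- reference tissue classifier
@dataclass
class ClassifierConfig:
    hidden: tuple = (28, 40)
    epochs: int = 100
    batch: int = 512
    val_every: int = 10
    val_fraction: float = 0.15
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if len(self.hidden) != 2:
            raise ValueError("the reference classifier has two hidden layers")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")


class TissueClassifier:
    """Per-pixel MLP 25 -> 28 -> 40 -> 4 with softmax output."""

    N_FEATURES, N_CLASSES = 25, 4

    def __init__(self, config: ClassifierConfig | None = None):
        cfg = config or ClassifierConfig()
        self.config = cfg
        h1, h2 = cfg.hidden
        self.net = Sequential(
            Linear(self.N_FEATURES, h1), LeakyReLU(0.01),
            Linear(h1, h2), LeakyReLU(0.01),
            Linear(h2, self.N_CLASSES),
        )

    def logits(self, pixels) -> Tensor:
        x = np.asarray(pixels, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.N_FEATURES:
            raise ValueError(f"pixels must have shape (N, {self.N_FEATURES})")
        return self.net(Tensor(x))

    def predict_probs(self, pixels) -> np.ndarray:
        z = self.logits(pixels).data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_cube(self, cube) -> TissueProbMap:
        """Classify every pixel of a (25, H, W) reflectance cube."""
        cube = np.asarray(cube, dtype=np.float32)
        if cube.ndim != 3 or cube.shape[0] != self.N_FEATURES:
            raise ValueError("cube must have shape (25, H, W)")
        h, w = cube.shape[1:]
        probs = self.predict_probs(cube.reshape(25, -1).T)
        return TissueProbMap(probs.reshape(h, w, 4))

    def accuracy(self, pixels, labels) -> float:
        pred = self.predict_probs(pixels).argmax(axis=1)
        return float((pred == np.asarray(labels)).mean())


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    shift = logits.data.max()
    exps = (logits - shift).exp()
    log_probs = (logits - shift) - exps.sum(axis=1, keepdims=True).log()
    picked = log_probs[np.arange(len(labels)), labels]
    return -picked.mean()


def train_reference_classifier(hsi_pixels, labels,
                               config: ClassifierConfig | None = None
                               ) -> dict:
    """Train the reference tissue classifier on labeled HSI pixels.

    ``labels`` use 0..3 for healthy, tumor, vessel, dura; all four classes
    must be present. Selection keeps the weights with the best validation
    accuracy, checked every ``val_every`` epochs. Returns
    {"classifier": TissueClassifier, "history": [...], "best_accuracy": float}.
    """
    cfg = config or ClassifierConfig()
    x = np.asarray(hsi_pixels, dtype=np.float32)
    y = np.asarray(labels, dtype=int).reshape(-1)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("pixels and labels must align")
    missing = sorted(set(range(4)) - set(np.unique(y)))
    if missing:
        raise ValueError(f"training labels missing classes: {missing}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(cfg.val_fraction * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    manual_seed(cfg.seed)
    clf = TissueClassifier(cfg)
    opt = AdamW(list(clf.net.parameters()), lr=cfg.lr_start,
                weight_decay=cfg.weight_decay)
    best = {"acc": -1.0, "state": None, "epoch": None}
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg.epochs, cfg.lr_start, cfg.lr_end)
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), cfg.batch):
            batch = perm[start:start + cfg.batch]
            loss = _cross_entropy(clf.logits(x[batch]), y[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "loss": float(np.mean(losses)),
                  "lr": opt.lr}
        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            acc = clf.accuracy(x[val_idx], y[val_idx])
            record["val_accuracy"] = acc
            if acc > best["acc"]:
                best = {"acc": acc, "epoch": epoch,
                        "state": clf.net.state_dict()}
        history.append(record)
    if best["state"] is not None:
        clf.net.load_state_dict(best["state"])
    return {"classifier": clf, "history": history,
            "best_accuracy": best["acc"], "best_epoch": best["epoch"]}
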