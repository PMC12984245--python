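"""Three-step training pipeline.

Step 1 pre-trains the encoder with supervised-contrastive learning on
positive (cortex) and negative (non-cortex) patches. Step 2 trains the full
network on RGB images against the pseudo-labels with the six-term objective.
Step 3 fine-tunes on hyperspectral cubes: the HSI stem trains at the full
learning rate while the shared trunk's rate is divided by exactly 1e3, with
masked BCE losses on the inner/outer/unknown adjusted ground truth.

All randomness is driven by explicit seeds; runs are deterministic on a
single CPU thread.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from . import losses as lss
from .evaluation import dsc
from .network import CortexNet, NetworkConfig, TRUNK_GROUPS, save_checkpoint
from .nn import AdamW, cosine_lr, manual_seed


# ------------------------------------------------------------------- configs
@dataclass
class Step1Config:
    epochs: int = 400
    batch: int = 128
    pos_fraction: float = 1.0 / 3.0
    tau: float = 0.1

    def __post_init__(self):
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch < 2:
            raise ValueError("epochs and batch must be positive")


@dataclass
class Step2Config:
    epochs: int = 1000
    batch: int = 8
    val_every: int = 10
    crop_area: tuple = (0.2, 1.0)
    crop_aspect: tuple = (0.55, 1.3)

    def __post_init__(self):
        if min(self.epochs, self.batch, self.val_every) < 1:
            raise ValueError("epochs, batch and val_every must be positive")


@dataclass
class Step3Config:
    epochs: int = 700
    batch: int = 8
    val_every: int = 10
    trunk_lr_divisor: float = 1e3

    def __post_init__(self):
        if min(self.epochs, self.batch, self.val_every) < 1:
            raise ValueError("epochs, batch and val_every must be positive")
        if self.trunk_lr_divisor <= 0:
            raise ValueError("trunk_lr_divisor must be positive")


@dataclass
class TrainConfig:
    step1: Step1Config = field(default_factory=Step1Config)
    step2: Step2Config = field(default_factory=Step2Config)
    step3: Step3Config = field(default_factory=Step3Config)
    lr_start: float = 1e-4
    lr_end: float = 1e-5
    weight_decay: float = 1e-4
    seed: int = 0

    def as_dict(self):
        return asdict(self)


def desk_scale_config(seed: int = 0) -> TrainConfig:
    """Default desk-scale profile: paper epoch counts divided by 20."""
    return TrainConfig(step1=Step1Config(epochs=20, batch=12),
                       step2=Step2Config(epochs=50, batch=2, val_every=10),
                       step3=Step3Config(epochs=35, batch=2, val_every=10),
                       seed=seed)


#: ablation experiment matrix: which steps/regularizers are active
ABLATIONS = {
    "solo": {"pretrain": False, "rgb": True, "finetune": False,
             "equivariance": False},
    "pretrain+finetune": {"pretrain": True, "rgb": False, "finetune": True,
                          "equivariance": False},
    "rgb+finetune": {"pretrain": False, "rgb": True, "finetune": True,
                     "equivariance": False},
    "pretrain+rgb": {"pretrain": True, "rgb": True, "finetune": False,
                     "equivariance": False},
    "full": {"pretrain": True, "rgb": True, "finetune": True,
             "equivariance": False},
    "full+EV": {"pretrain": True, "rgb": True, "finetune": True,
                "equivariance": True},
}


# -------------------------------------------------------------------- splits
@dataclass
class SplitSpec:
    n_total: int
    n_train: int
    n_val: int
    n_test: int
    train_ids: list
    val_ids: list
    test_ids: list
    fold: int
    seed: int

    def __post_init__(self):
        if self.n_train + self.n_val + self.n_test != self.n_total:
            raise ValueError("split sizes must sum to the cohort size")


def make_splits(patient_ids, fractions=(0.70, 0.10, 0.20), n_folds: int = 5,
                seed: int = 0) -> list:
    """Fixed test split (round-down 20%), train/val re-split per fold."""
    ids = list(patient_ids)
    n = len(ids)
    if n < n_folds or n < 3:
        raise ValueError("too few patients for the requested folds")
    f_train, f_val, f_test = fractions
    n_test = int(np.floor(f_test * n))
    n_train = int(round(f_train * n))
    n_val = n - n_test - n_train
    if min(n_test, n_train, n_val) < 1:
        raise ValueError("each split needs at least one patient")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_ids = [ids[i] for i in order[:n_test]]
    rest = [ids[i] for i in order[n_test:]]
    specs = []
    for fold in range(n_folds):
        fold_rng = np.random.default_rng(seed * 1000 + fold + 1)
        fold_order = fold_rng.permutation(len(rest))
        val_ids = [rest[i] for i in fold_order[:n_val]]
        train_ids = [rest[i] for i in fold_order[n_val:]]
        specs.append(SplitSpec(n_total=n, n_train=n_train, n_val=n_val,
                               n_test=n_test, train_ids=train_ids,
                               val_ids=val_ids, test_ids=list(test_ids),
                               fold=fold, seed=seed))
    return specs


# ------------------------------------------------------------- augmentations
def _color_jitter(img, rng, strength=0.2):
    out = img.copy()
    for c in range(out.shape[0]):
        out[c] = out[c] * (1 + rng.uniform(-strength, strength)) \
            + rng.uniform(-strength / 2, strength / 2)
    return np.clip(out, 0.0, 1.0)


def augment_patch(img, rng, flips=True, jitter=True, blur=True):
    """Flips, color jitter and Gaussian blur, each with probability 0.5."""
    out = np.asarray(img, dtype=np.float32)
    if flips and rng.random() < 0.5:
        out = out[..., :, ::-1]
    if flips and rng.random() < 0.5:
        out = out[..., ::-1, :]
    if jitter and rng.random() < 0.5:
        out = _color_jitter(out, rng)
    if blur and rng.random() < 0.5:
        sigma = rng.uniform(0.3, 1.2)
        out = ndi.gaussian_filter(out, sigma=(0, sigma, sigma))
    return np.ascontiguousarray(out, dtype=np.float32)


def random_resized_crop(img, masks, rng, area_range=(0.2, 1.0),
                        aspect_range=(0.55, 1.3), target=None):
    """Torchvision-style random resized crop of an image and aligned masks."""
    h, w = img.shape[-2:]
    target = target or (h, w)
    for _ in range(10):
        area = rng.uniform(*area_range) * h * w
        aspect = rng.uniform(*aspect_range)
        ch = int(round(np.sqrt(area / aspect)))
        cw = int(round(np.sqrt(area * aspect)))
        if 0 < ch <= h and 0 < cw <= w:
            break
    else:
        ch, cw = h, w
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))

    def crop_resize(a, order):
        cropped = a[..., top:top + ch, left:left + cw]
        moved = np.moveaxis(cropped, 0, -1) if cropped.ndim == 3 else cropped
        out = resize(moved.astype(float), target, order=order,
                     preserve_range=True, anti_aliasing=order > 0)
        return np.moveaxis(out, -1, 0) if cropped.ndim == 3 else out

    img_out = crop_resize(img, 1).astype(np.float32)
    masks_out = {k: crop_resize(np.asarray(m, float), 0).astype(bool)
                 for k, m in masks.items()}
    return img_out, masks_out


def flips_only(img, masks, rng):
    out, mout = np.asarray(img), {k: np.asarray(m) for k, m in masks.items()}
    for axis in (-1, -2):
        if rng.random() < 0.5:
            out = np.flip(out, axis=axis)
            mout = {k: np.flip(m, axis=axis) for k, m in mout.items()}
    return (np.ascontiguousarray(out),
            {k: np.ascontiguousarray(m) for k, m in mout.items()})


# ------------------------------------------------------------- training steps
def _log(history, path=None, **record):
    history.append(record)
    if path is not None:
        with open(path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(record) + "\n")


def pretrain_encoder(model: CortexNet, patch_dataset: dict,
                     config: TrainConfig, log_path=None) -> dict:
    """Step 1: supervised-contrastive pre-training on cortex patches.

    ``patch_dataset`` maps ``positives``/``negatives`` to lists of (3, h, w)
    arrays. Returns {"history": [...], "state": trained state dict}.
    """
    cfg = config.step1
    pos = patch_dataset.get("positives") or []
    neg = patch_dataset.get("negatives") or []
    if not pos or not neg:
        raise ValueError("need both positive and negative patches")
    n_pos = int(round(cfg.batch * cfg.pos_fraction))
    n_neg = cfg.batch - n_pos
    rng = np.random.default_rng(config.seed)
    opt = AdamW(list(model.parameters()), lr=config.lr_start,
                weight_decay=config.weight_decay)
    model.train()
    history = []
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg.epochs, config.lr_start, config.lr_end)
        pick_p = rng.choice(len(pos), n_pos, replace=len(pos) < n_pos)
        pick_n = rng.choice(len(neg), n_neg, replace=len(neg) < n_neg)
        batch = [augment_patch(pos[i], rng) for i in pick_p] \
            + [augment_patch(neg[i], rng) for i in pick_n]
        labels = np.array([1] * n_pos + [0] * n_neg)
        emb = model.project_embedding(np.stack(batch), "rgb")
        loss = lss.supcon_loss(emb, labels, tau=cfg.tau)
        opt.zero_grad()
        loss.backward()
        opt.step()
        _log(history, log_path, step="pretrain", epoch=epoch,
             supcon=float(loss.data), lr=opt.lr,
             n_pos=int(n_pos), n_neg=int(n_neg))
    return {"history": history, "state": model.state_dict(),
            "batch_composition": (n_pos, n_neg)}


def _val_rgb_score(model, val_items):
    model.eval()
    scores = []
    for item in val_items:
        out = model.forward(item["image"], "rgb")
        pc = out.cortex_prob.data[0, 0] >= 0.5
        pv = out.vessel_prob.data[0, 0] >= 0.5
        scores.append(0.5 * (dsc(pc, item["labels"]["cortex_mask"])
                             + dsc(pv, item["labels"]["vessel_mask"])))
    model.train()
    return float(np.mean(scores))


def train_rgb(model: CortexNet, train_items, val_items, config: TrainConfig,
              loss_config=None, augment=True, log_path=None) -> dict:
    """Step 2: full-network RGB training on pseudo-labels (Eq. 2 objective).

    Items are dicts with ``image`` (3, H, W) and ``labels`` holding
    ``cortex_mask``, ``contour_map`` and ``vessel_mask``. Model selection:
    best validation mean of cortex and vessel DSC, checked every
    ``val_every`` epochs.
    """
    cfg = config.step2
    lcfg = loss_config or lss.LossConfig()
    if not train_items:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    opt = AdamW(list(model.parameters()), lr=config.lr_start,
                weight_decay=config.weight_decay)
    model.train()
    history = []
    best = {"score": -np.inf, "epoch": None, "state": None}
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg.epochs, config.lr_start, config.lr_end)
        order = rng.permutation(len(train_items))
        epoch_total = 0.0
        for idx in order:
            item = train_items[idx]
            img, labels = item["image"], item["labels"]
            if augment:
                img, labels = random_resized_crop(
                    img, labels, rng, cfg.crop_area, cfg.crop_aspect)
                img = augment_patch(img, rng)
            out = model.forward(img, "rgb")
            breakdown = lss.total_rgb_loss(out, labels, lcfg)
            opt.zero_grad()
            breakdown.total_tensor.backward()
            opt.step()
            epoch_total += breakdown.total
        record = {"step": "rgb", "epoch": epoch, "lr": opt.lr,
                  "train_loss": epoch_total / len(train_items)}
        if val_items and (epoch + 1) % cfg.val_every == 0:
            score = _val_rgb_score(model, val_items)
            record["val_dsc_mean"] = score
            if score > best["score"]:
                best = {"score": score, "epoch": epoch,
                        "state": copy.deepcopy(model.state_dict())}
        _log(history, log_path, **record)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return {"history": history, "state": model.state_dict(),
            "best_epoch": best["epoch"], "best_score": best["score"]}


def _val_hsi_score(model, val_items):
    model.eval()
    scores = []
    for item in val_items:
        out = model.forward(item["cube"], "hsi")
        lab = np.asarray(getattr(item["adjusted"], "labels",
                                 item["adjusted"]))
        known = lab > 0
        pc = out.cortex_prob.data[0, 0] >= 0.5
        acc = float((pc[known] == (lab[known] == 1)).mean()) if known.any() \
            else 0.0
        inner = lab == 1
        pv = (out.vessel_prob.data[0, 0] >= 0.5) & inner
        vdsc = dsc(pv, np.asarray(item["vessel_pseudo"], bool) & inner) / 100.0
        scores.append(0.5 * (acc + vdsc))
    model.train()
    return float(np.mean(scores))


def finetune_hsi(model: CortexNet, train_items, val_items,
                 config: TrainConfig, trunk_loaded: bool = True,
                 equivariance: bool = False, log_path=None) -> dict:
    """Step 3: HSI fine-tuning with masked BCE losses.

    Items are dicts with ``cube`` (25, H, W), ``adjusted`` (AdjustedGT) and
    ``vessel_pseudo``. The HSI stem trains at the full learning rate; every
    other weight group uses lr / ``trunk_lr_divisor`` (exactly 1e3 by
    default).
    """
    cfg = config.step3
    if not trunk_loaded:
        raise ValueError("finetune_hsi requires an RGB-trained trunk")
    if not train_items:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 2)
    stem_params, trunk_params = [], []
    for name, p in model.named_parameters():
        (stem_params if name.startswith("hsi_stem") else trunk_params).append(p)
    opt = AdamW([{"params": stem_params, "lr_scale": 1.0},
                 {"params": trunk_params,
                  "lr_scale": 1.0 / cfg.trunk_lr_divisor}],
                lr=config.lr_start, weight_decay=config.weight_decay)
    model.train()
    history = []
    epoch0 = _val_hsi_score(model, val_items) if val_items else None
    best = {"score": -np.inf, "epoch": None, "state": None}
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg.epochs, config.lr_start, config.lr_end)
        order = rng.permutation(len(train_items))
        epoch_loss = 0.0
        for idx in order:
            item = train_items[idx]
            masks = {"adj": np.asarray(getattr(item["adjusted"], "labels",
                                               item["adjusted"])),
                     "pseudo": np.asarray(item["vessel_pseudo"], bool)}
            cube, masks = flips_only(item["cube"], masks, rng)
            out = model.forward(cube, "hsi")
            loss = lss.masked_cortex_bce(out.cortex_prob, masks["adj"]) \
                + lss.masked_vessel_bce(out.vessel_prob, masks["pseudo"],
                                        masks["adj"])
            record_ev = None
            if equivariance:
                ev = lss.equivariance_loss(model, cube, "hsi",
                                           seed=int(rng.integers(2 ** 31)))
                loss = loss + ev
                record_ev = float(ev.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            if record_ev is not None:
                _log(history, log_path, step="hsi", epoch=epoch,
                     equivariance=record_ev)
        record = {"step": "hsi", "epoch": epoch, "lr": opt.lr,
                  "train_loss": epoch_loss / len(train_items)}
        if val_items and (epoch + 1) % cfg.val_every == 0:
            score = _val_hsi_score(model, val_items)
            record["val_score"] = score
            if score > best["score"]:
                best = {"score": score, "epoch": epoch,
                        "state": copy.deepcopy(model.state_dict())}
        _log(history, log_path, **record)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return {"history": history, "state": model.state_dict(),
            "best_epoch": best["epoch"], "best_score": best["score"],
            "epoch0_score": epoch0}
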