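"""End-to-end demo pipeline: synth -> preproc -> pseudolabel -> train ->
fuse -> eval, at desk scale, with a JSON manifest of every artifact."""

from __future__ import annotations

import json
import platform
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from types import SimpleNamespace

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

from . import evaluation as ev
from . import fusion as fu
from . import pseudolabel as pl
from . import synthetic as sy
from .config import config_hash, load_config, validate_config
from .io import save_label_png, save_prob_png, save_rgb_png
from .network import CortexNet, NetworkConfig, save_checkpoint
from .nn import manual_seed
from .preproc import (calibrate_reflectance, demosaic, reconstruct_prgb,
                      select_rgb_bands_by_harmonic)
from .training import (Step1Config, Step2Config, Step3Config, TrainConfig,
                       finetune_hsi, pretrain_encoder, train_rgb)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    versions: dict
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _versions() -> dict:
    import skimage
    import sklearn

    return {"python": platform.python_version(),
            "numpy": np.__version__, "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__}


class _Logger:
    def __init__(self, path=None):
        self.path = Path(path) if path else None

    def log(self, **record):
        line = json.dumps(record, default=float)
        print(line, file=sys.stderr)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")


def _resize_mask(mask, target):
    return resize(np.asarray(mask, float), target, order=0,
                  preserve_range=True, anti_aliasing=False).astype(mask.dtype)


def _resize_img(img, target):
    chan_last = np.moveaxis(img, 0, -1) if img.ndim == 3 and \
        img.shape[0] in (3, 25) else img
    out = resize(chan_last.astype(float), target, order=1,
                 preserve_range=True, anti_aliasing=True)
    if chan_last is not img:
        out = np.moveaxis(out, -1, 0)
    return out.astype(np.float32)


def make_contrastive_patches(rgb_images, cortex_masks, patch: int = 32,
                             per_image: int = 8, seed: int = 0) -> dict:
    """Positive (cortex-centered) and negative (off-cortex) square crops."""
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for img, mask in zip(rgb_images, cortex_masks):
        h, w = mask.shape
        half = patch // 2
        inside = np.argwhere(mask)
        outside = np.argwhere(~mask)
        for bucket, coords in ((pos, inside), (neg, outside)):
            picks = coords[rng.choice(len(coords),
                                      min(per_image, len(coords)),
                                      replace=False)]
            for r, c in picks:
                r = int(np.clip(r, half, h - half))
                c = int(np.clip(c, half, w - half))
                bucket.append(img[:, r - half:r + half, c - half:c + half])
    return {"positives": pos, "negatives": neg}


def _train_config_from(cfg: dict) -> TrainConfig:
    t = cfg["training"]
    return TrainConfig(
        step1=Step1Config(epochs=int(t["step1"]["epochs"]),
                          batch=int(t["step1"]["batch"])),
        step2=Step2Config(epochs=int(t["step2"]["epochs"]),
                          batch=int(t["step2"]["batch"]),
                          val_every=int(t["step2"]["val_every"])),
        step3=Step3Config(epochs=int(t["step3"]["epochs"]),
                          batch=int(t["step3"]["batch"]),
                          val_every=int(t["step3"]["val_every"]),
                          trunk_lr_divisor=float(
                              t["step3"]["trunk_lr_divisor"])),
        lr_start=float(t["lr_start"]), lr_end=float(t["lr_end"]),
        weight_decay=float(t["weight_decay"]), seed=int(cfg["seed"]))


def run_demo(config, out_dir) -> RunManifest:
    """Run every stage on synthetic data; returns the manifest.

    ``config`` is a YAML path, a plain dict, or None for full defaults.
    """
    if config is None or isinstance(config, dict):
        cfg = validate_config(config)
    else:
        cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "data").mkdir(exist_ok=True)
    logger = _Logger(out / "log.jsonl")
    manifest = RunManifest(config_hash=config_hash(cfg),
                           seeds={"root": int(cfg["seed"])},
                           versions=_versions())
    state = {}
    stages = [("synth", _stage_synth), ("preproc", _stage_preproc),
              ("pseudolabel", _stage_pseudolabel), ("train", _stage_train),
              ("fuse", _stage_fuse), ("eval", _stage_eval)]
    for name, fn in stages:
        t0 = time.perf_counter()
        logger.log(stage=name, status="start")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fn(cfg, state, out, manifest)
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest.stage_seconds[name] = round(dt, 3)
        logger.log(stage=name, status="done", seconds=round(dt, 3))
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=float)
    manifest.outputs["config"] = str(out / "config.json")
    manifest.save(out / "manifest.json")
    return manifest


# -------------------------------------------------------------------- stages
def _stage_synth(cfg, state, out, manifest):
    seed = int(cfg["seed"])
    syn = cfg["synthetic"]
    packs = [sy.generate_scene(sy.SceneConfig(
        seed=seed + i, rgb_size=tuple(syn["rgb_size"]),
        n_vessels=int(syn["n_vessels"]), noise_sd=float(syn["noise_sd"]),
        sparse_fraction=float(syn["sparse_fraction"])))
        for i in range(int(syn["n_scenes"]))]
    state["packs"] = packs
    manifest.seeds["scenes"] = [seed + i for i in range(len(packs))]
    save_rgb_png(out / "scene0_rgb.png", packs[0].rgb)
    manifest.outputs["scene0_rgb"] = str(out / "scene0_rgb.png")


def _stage_preproc(cfg, state, out, manifest):
    cubes, prgbs = [], []
    for pack in state["packs"]:
        cube = calibrate_reflectance(demosaic(pack.raw), pack.refs)
        bands = select_rgb_bands_by_harmonic(cube.wavelengths_nm)
        cubes.append(cube)
        prgbs.append(reconstruct_prgb(cube, bands))
    state["cubes"], state["prgbs"] = cubes, prgbs
    save_rgb_png(out / "scene0_prgb.png", prgbs[0])
    manifest.outputs["scene0_prgb"] = str(out / "scene0_prgb.png")


def _stage_pseudolabel(cfg, state, out, manifest):
    seed = int(cfg["seed"])
    pcfg = cfg["pseudolabel"]
    target = tuple(int(v) for v in cfg["training"]["train_size"])
    rgb_items, hsi_items = [], []
    for i, pack in enumerate(state["packs"]):
        rgb = np.asarray(pack.rgb)
        rgb_cortex = _resize_mask(pack.cortex_gold, rgb.shape[:2])
        ann = pl.simulate_patch_annotations(rgb_cortex,
                                            coverage=float(pcfg["coverage"]),
                                            seed=seed + i)
        labels = pl.generate_rgb_pseudolabels(
            rgb, ann, k_clusters=int(pcfg["n_clusters"]), seed=seed + i,
            threshold_quantile=float(pcfg["quantile"]),
            min_area=int(pcfg["min_vessel_area"]))
        adapted_img, adapted_masks = pl.adapt_rgb_dataset(
            rgb, labels.cortex_mask,
            masks={"contour_map": labels.contour_map,
                   "vessel_mask": labels.vessel_mask,
                   "cortex_gold": _resize_mask(pack.cortex_gold,
                                               rgb.shape[:2]),
                   "vessel_truth": _resize_mask(pack.vessel_truth,
                                                rgb.shape[:2])},
            target=target)
        img = np.moveaxis(adapted_img, -1, 0).astype(np.float32)
        rgb_items.append({"image": img,
                          "labels": {
                              "cortex_mask": adapted_masks["refined"],
                              "contour_map": adapted_masks["contour_map"],
                              "vessel_mask": adapted_masks["vessel_mask"]},
                          "gold": {"cortex": adapted_masks["cortex_gold"],
                                   "vessel": adapted_masks["vessel_truth"]}})

        densified = pl.densify_gt(pack.gt_sparse)
        background = pl.complement_background(state["prgbs"][i], densified,
                                              seed=seed + i)
        adjusted = pl.build_adjusted_gt(densified, background)
        gray = rgb2gray(state["prgbs"][i])
        bank = pl.make_operator_bank(5, 11)
        vessels = pl.detect_vessels(gray, bank,
                                    threshold_quantile=float(
                                        pcfg["quantile"]),
                                    min_area=int(pcfg["min_vessel_area"]))
        cube_small = _resize_img(state["cubes"][i].data, target)
        hsi_items.append({"cube": cube_small,
                          "adjusted": _resize_mask(adjusted.labels, target),
                          "vessel_pseudo": _resize_mask(vessels & (
                              adjusted.labels == pl.AdjustedGT.INNER),
                              target)})
    state["rgb_items"], state["hsi_items"] = rgb_items, hsi_items
    save_label_png(out / "data" / "scene0_pseudolabels.png",
                   rgb_items[0]["labels"]["cortex_mask"].astype(np.uint8)
                   + 2 * rgb_items[0]["labels"]["vessel_mask"])
    manifest.outputs["scene0_pseudolabels"] = \
        str(out / "data" / "scene0_pseudolabels.png")


def _stage_train(cfg, state, out, manifest):
    tc = _train_config_from(cfg)
    ncfg = NetworkConfig(base_channels=int(cfg["network"]["base_channels"]),
                         stage_blocks=tuple(cfg["network"]["stage_blocks"]),
                         embedding_dim=int(cfg["network"]["embedding_dim"]))
    manual_seed(tc.seed)
    model = CortexNet(ncfg)
    n = len(state["rgb_items"])
    n_test = max(1, n // 5)
    n_val = max(1, (n - n_test) // 5)
    state["test_slice"] = slice(n - n_test, n)
    train_rgb_items = state["rgb_items"][:n - n_test - n_val]
    val_rgb_items = [
        {"image": it["image"], "labels": {
            "cortex_mask": it["gold"]["cortex"],
            "vessel_mask": it["gold"]["vessel"]}}
        for it in state["rgb_items"][n - n_test - n_val:n - n_test]]

    patches = make_contrastive_patches(
        [it["image"] for it in train_rgb_items],
        [it["labels"]["cortex_mask"] for it in train_rgb_items],
        seed=tc.seed)
    pre = pretrain_encoder(model, patches, tc,
                           log_path=out / "train_step1.jsonl")
    rgb_out = train_rgb(model, train_rgb_items, val_rgb_items, tc,
                        augment=bool(cfg["training"]["step2"]["augment"]),
                        log_path=out / "train_step2.jsonl")
    hsi_train = state["hsi_items"][:n - n_test - n_val]
    hsi_val = state["hsi_items"][n - n_test - n_val:n - n_test]
    hsi_out = finetune_hsi(model, hsi_train, hsi_val, tc,
                           log_path=out / "train_step3.jsonl")
    save_checkpoint(model, out / "checkpoint.npz")
    manifest.outputs["checkpoint"] = str(out / "checkpoint.npz")
    manifest.outputs["train_logs"] = [str(out / f"train_step{i}.jsonl")
                                      for i in (1, 2, 3)]
    state["model"] = model
    state["train_summary"] = {
        "step1_final_supcon": pre["history"][-1]["supcon"],
        "step2_best_val_dsc": rgb_out["best_score"],
        "step3_epoch0_score": hsi_out["epoch0_score"],
        "step3_best_score": hsi_out["best_score"]}


def _stage_fuse(cfg, state, out, manifest):
    model = state["model"]
    conf_p = float(cfg["fusion"]["vessel_tumor_confusion"])
    confusion = np.eye(4)
    confusion[2] = (0.0, conf_p, 1.0 - conf_p, 0.0)
    target = tuple(int(v) for v in cfg["training"]["train_size"])
    fused_records = []
    for i in range(*state["test_slice"].indices(len(state["packs"]))):
        pack = state["packs"][i]
        truth_small = _resize_mask(pack.truth, target)
        raw_probs = sy.generate_flawed_probs(
            SimpleNamespace(truth=truth_small), confusion,
            seed=int(cfg["seed"]) + 100 + i)
        net_out = model.forward(state["hsi_items"][i]["cube"], "hsi")
        pctx = net_out.cortex_prob.data[0, 0]
        pvsl = net_out.vessel_prob.data[0, 0]
        fused = fu.fuse_tissue_map(fu.TissueProbMap(raw_probs), pctx, pvsl)
        # oracle-mask fusion isolates the fusion algebra from the quality
        # of the desk-scale surface network
        fused_oracle = fu.fuse_tissue_map(
            fu.TissueProbMap(raw_probs),
            _resize_mask(pack.cortex_gold, target).astype(float),
            _resize_mask(pack.vessel_truth, target).astype(float))
        fused_records.append({"truth": truth_small, "raw": raw_probs,
                              "fused": fused, "fused_oracle": fused_oracle,
                              "scene": i})
    state["fused_records"] = fused_records
    first = fused_records[0]
    save_rgb_png(out / "fused0.png", fu.render_map(first["fused"]) / 255.0)
    save_prob_png(out / "fused0_pctx.png",
                  first["fused"].probs[..., :3].sum(axis=-1))
    manifest.outputs["fused_render"] = str(out / "fused0.png")


def _stage_eval(cfg, state, out, manifest):
    per_scene = []
    for rec in state["fused_records"]:
        truth = rec["truth"]
        raw_map = rec["raw"].argmax(axis=-1) + 1
        fused_map = rec["fused"].class_map + 1
        f_raw = ev.f1_per_class(raw_map, truth)
        f_fused = ev.f1_per_class(fused_map, truth)
        f_oracle = ev.f1_per_class(rec["fused_oracle"].class_map + 1, truth)
        i = rec["scene"]
        pack = state["packs"][i]
        target = truth.shape
        gold = _resize_mask(pack.cortex_gold, target)
        net_out = state["model"].forward(state["hsi_items"][i]["cube"], "hsi")
        pred_ctx = net_out.cortex_prob.data[0, 0] >= 0.5
        per_scene.append({
            "scene": i,
            "raw_f1": {str(k): v for k, v in f_raw.f1.items()},
            "fused_f1": {str(k): v for k, v in f_fused.f1.items()},
            "oracle_fused_f1": {str(k): v for k, v in f_oracle.f1.items()},
            "cortex_dsc": ev.dsc(pred_ctx, gold)})
        save_label_png(out / f"pred_class_{i}.png",
                       fused_map.astype(np.uint8))
    def _mean(key, cls):
        return float(np.mean([s[key][cls] for s in per_scene
                              if cls in s[key]]))
    metrics = {
        "per_scene": per_scene,
        "raw_tumor_f1": _mean("raw_f1", "2"),
        "fused_tumor_f1": _mean("fused_f1", "2"),
        "oracle_fused_tumor_f1": _mean("oracle_fused_f1", "2"),
        "raw_vessel_f1": _mean("raw_f1", "3"),
        "fused_vessel_f1": _mean("fused_f1", "3"),
        "oracle_fused_vessel_f1": _mean("oracle_fused_f1", "3"),
        "cortex_dsc_mean": float(np.mean([s["cortex_dsc"]
                                          for s in per_scene])),
        "train_summary": state["train_summary"],
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    manifest.outputs["metrics"] = str(out / "metrics.json")
    state["metrics"] = metrics
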