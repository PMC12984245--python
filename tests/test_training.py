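"""Split arithmetic, augmentations and small end-to-end training runs."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

from cortexfuse import training as tr
from cortexfuse.network import CortexNet, NetworkConfig
from cortexfuse.nn import manual_seed


TINY = NetworkConfig(base_channels=4, stage_blocks=(1, 1, 1))


def _tiny_model(seed=0):
    manual_seed(seed)
    return CortexNet(TINY)


# -------------------------------------------------------------------- splits
def test_split_sizes_for_67_patients():
    specs = tr.make_splits(range(67), n_folds=5, seed=0)
    assert len(specs) == 5
    for s in specs:
        assert (s.n_test, s.n_train, s.n_val) == (13, 47, 7)


def test_split_sizes_for_70_patients():
    s = tr.make_splits(range(70), n_folds=5, seed=1)[0]
    assert (s.n_test, s.n_train, s.n_val) == (14, 49, 7)


def test_test_split_fixed_across_folds_and_partitions_cohort():
    specs = tr.make_splits(range(30), n_folds=4, seed=7)
    test_sets = {frozenset(s.test_ids) for s in specs}
    assert len(test_sets) == 1
    for s in specs:
        groups = [set(s.train_ids), set(s.val_ids), set(s.test_ids)]
        assert set().union(*groups) == set(range(30))
        assert sum(len(g) for g in groups) == 30  # pairwise disjoint
    # validation sets differ between folds
    assert len({frozenset(s.val_ids) for s in specs}) > 1


def test_splits_deterministic_under_seed():
    a = tr.make_splits(range(25), n_folds=3, seed=5)
    b = tr.make_splits(range(25), n_folds=3, seed=5)
    for sa, sb in zip(a, b):
        assert sa.train_ids == sb.train_ids
        assert sa.val_ids == sb.val_ids
        assert sa.test_ids == sb.test_ids


def test_splits_reject_tiny_cohorts():
    with pytest.raises(ValueError):
        tr.make_splits(range(3), n_folds=5)
    with pytest.raises(ValueError):
        tr.make_splits(range(2), n_folds=1)


# ------------------------------------------------------------------- configs
def test_step1_batch_composition_is_43_of_128():
    cfg = tr.Step1Config()
    assert cfg.batch == 128
    assert int(round(cfg.batch * cfg.pos_fraction)) == 43


def test_step3_trunk_divisor_is_exactly_1000():
    assert tr.Step3Config().trunk_lr_divisor == 1e3


def test_full_scale_epoch_defaults():
    cfg = tr.TrainConfig()
    assert (cfg.step1.epochs, cfg.step2.epochs, cfg.step3.epochs) \
        == (400, 1000, 700)
    assert (cfg.lr_start, cfg.lr_end) == (1e-4, 1e-5)


def test_desk_profile_divides_epochs_by_20():
    cfg = tr.desk_scale_config()
    assert (cfg.step1.epochs, cfg.step2.epochs, cfg.step3.epochs) \
        == (400 // 20, 1000 // 20, 700 // 20)


def test_ablation_matrix_names_and_flags():
    assert set(tr.ABLATIONS) == {"solo", "pretrain+finetune", "rgb+finetune",
                                 "pretrain+rgb", "full", "full+EV"}
    assert tr.ABLATIONS["full+EV"]["equivariance"]
    assert not tr.ABLATIONS["full"]["equivariance"]
    assert not tr.ABLATIONS["solo"]["pretrain"]
    assert all(set(v) == {"pretrain", "rgb", "finetune", "equivariance"}
               for v in tr.ABLATIONS.values())


def test_config_validation_errors():
    with pytest.raises(ValueError):
        tr.Step1Config(pos_fraction=1.5)
    with pytest.raises(ValueError):
        tr.Step2Config(val_every=0)
    with pytest.raises(ValueError):
        tr.Step3Config(trunk_lr_divisor=0.0)


# ------------------------------------------------------------- augmentations
def test_augment_patch_shape_range_and_determinism():
    img = np.random.default_rng(0).random((3, 20, 24)).astype(np.float32)
    a = tr.augment_patch(img, np.random.default_rng(42))
    b = tr.augment_patch(img, np.random.default_rng(42))
    assert a.shape == img.shape and a.dtype == np.float32
    assert a.min() >= 0.0 and a.max() <= 1.0
    np.testing.assert_array_equal(a, b)


def test_random_resized_crop_keeps_image_and_masks_aligned():
    img = np.zeros((3, 40, 60), np.float32)
    mask = np.zeros((40, 60), bool)
    rr, cc = disk((20, 30), 12)
    mask[rr, cc] = True
    img[:, mask] = 1.0
    out_img, out_masks = tr.random_resized_crop(img, {"m": mask},
                                                np.random.default_rng(3))
    assert out_img.shape == (3, 40, 60)
    assert out_masks["m"].shape == (40, 60)
    assert out_masks["m"].dtype == bool
    # nearest-neighbour mask stays aligned with the bright image region
    agree = (out_img[0] > 0.5) == out_masks["m"]
    assert agree.mean() > 0.95


def test_flips_only_keeps_alignment_and_is_seeded():
    img = np.arange(2 * 6 * 8, dtype=np.float32).reshape(2, 6, 8)
    mask = img[0] > img[0].mean()
    out, masks = tr.flips_only(img, {"m": mask}, np.random.default_rng(1))
    np.testing.assert_array_equal(out[0] > img[0].mean(), masks["m"])
    out2, _ = tr.flips_only(img, {"m": mask}, np.random.default_rng(1))
    np.testing.assert_array_equal(out, out2)


# ----------------------------------------------------- synthetic tiny dataset
def _rgb_item(seed, h=24, w=32):
    rng = np.random.default_rng(seed)
    cortex = np.zeros((h, w), bool)
    rr, cc = disk((h // 2, w // 2), min(h, w) // 3)
    cortex[rr, cc] = True
    vessel = np.zeros_like(cortex)
    vessel[h // 2, w // 2 - 4:w // 2 + 4] = True
    img = np.where(cortex, 0.75, 0.25)[None].repeat(3, 0).astype(np.float32)
    img[1][vessel] = 0.2
    img += rng.normal(0, 0.02, img.shape).astype(np.float32)
    contour = cortex ^ ndi.binary_erosion(cortex)
    return {"image": np.clip(img, 0, 1),
            "labels": {"cortex_mask": cortex, "contour_map": contour,
                       "vessel_mask": vessel}}


def _hsi_item(seed, h=24, w=32):
    rng = np.random.default_rng(seed)
    adj = np.zeros((h, w), np.uint8)
    rr, cc = disk((h // 2, w // 2), min(h, w) // 3)
    inner = np.zeros((h, w), bool)
    inner[rr, cc] = True
    adj[inner] = 1
    adj[~inner] = 2
    adj[0:2] = 0                       # a band of unknown pixels
    vessel = np.zeros((h, w), bool)
    vessel[h // 2, w // 2 - 4:w // 2 + 4] = True
    cube = np.where(inner, 0.7, 0.3)[None].repeat(25, 0).astype(np.float32)
    cube[:, vessel] = 0.15
    cube += rng.normal(0, 0.02, cube.shape).astype(np.float32)
    return {"cube": np.clip(cube, 0, 1), "adjusted": adj,
            "vessel_pseudo": vessel}


# ------------------------------------------------------------------ step 1
def test_pretrain_runs_and_reports_batch_composition():
    model = _tiny_model()
    rng = np.random.default_rng(0)
    patches = {"positives": [rng.random((3, 16, 16)).astype(np.float32) * 0.3
                             for _ in range(4)],
               "negatives": [0.7 + 0.3 * rng.random((3, 16, 16))
                             .astype(np.float32) for _ in range(4)]}
    cfg = tr.TrainConfig(step1=tr.Step1Config(epochs=3, batch=6), seed=0)
    out = tr.pretrain_encoder(model, patches, cfg)
    assert out["batch_composition"] == (2, 4)
    assert len(out["history"]) == 3
    assert all(np.isfinite(rec["supcon"]) for rec in out["history"])


def test_pretrain_requires_both_classes():
    model = _tiny_model()
    with pytest.raises(ValueError):
        tr.pretrain_encoder(model, {"positives": [np.zeros((3, 8, 8))],
                                    "negatives": []}, tr.TrainConfig())


# ------------------------------------------------------------------ step 2
def test_train_rgb_selects_best_validation_state():
    model = _tiny_model(1)
    items = [_rgb_item(s) for s in range(3)]
    cfg = tr.TrainConfig(step2=tr.Step2Config(epochs=6, batch=2, val_every=2),
                         seed=0)
    out = tr.train_rgb(model, items[:2], items[2:], cfg, augment=False)
    assert out["best_epoch"] is not None
    assert np.isfinite(out["best_score"])
    vals = [r["val_dsc_mean"] for r in out["history"] if "val_dsc_mean" in r]
    assert len(vals) == 3
    # the restored weights reproduce the best validation score
    assert tr._val_rgb_score(model, items[2:]) == pytest.approx(
        out["best_score"])


def test_train_rgb_deterministic_under_seed():
    items = [_rgb_item(s) for s in range(2)]
    cfg = tr.TrainConfig(step2=tr.Step2Config(epochs=2, batch=2, val_every=2),
                         seed=9)
    losses = []
    for _ in range(2):
        model = _tiny_model(4)
        out = tr.train_rgb(model, items, [], cfg, augment=False)
        losses.append([r["train_loss"] for r in out["history"]])
    assert losses[0] == losses[1]


def test_train_rgb_augmented_pass_runs():
    model = _tiny_model(2)
    items = [_rgb_item(5)]
    cfg = tr.TrainConfig(step2=tr.Step2Config(epochs=2, batch=1, val_every=5),
                         seed=3)
    out = tr.train_rgb(model, items, [], cfg, augment=True)
    assert all(np.isfinite(r["train_loss"]) for r in out["history"])


def test_train_rgb_rejects_empty_training_set():
    with pytest.raises(ValueError):
        tr.train_rgb(_tiny_model(), [], [], tr.TrainConfig())


# ------------------------------------------------------------------ step 3
def test_finetune_updates_stem_much_faster_than_trunk():
    model = _tiny_model(3)
    before = {n: p.data.copy() for n, p in model.named_parameters()}
    items = [_hsi_item(s) for s in range(2)]
    cfg = tr.TrainConfig(step3=tr.Step3Config(epochs=2, batch=2, val_every=2),
                         seed=0)
    out = tr.finetune_hsi(model, items, items, cfg)
    deltas = {n: np.abs(p.data - before[n]).max()
              for n, p in model.named_parameters()}
    stem = max(v for n, v in deltas.items() if n.startswith("hsi_stem"))
    trunk = max(v for n, v in deltas.items()
                if not n.startswith(("hsi_stem", "projection")))
    assert stem > 0 and trunk > 0
    assert stem / trunk > 50          # lr ratio is 1000; allow Adam dynamics
    assert np.isfinite(out["epoch0_score"])


def test_finetune_requires_trunk_and_data():
    model = _tiny_model()
    with pytest.raises(ValueError):
        tr.finetune_hsi(model, [_hsi_item(0)], [], tr.TrainConfig(),
                        trunk_loaded=False)
    with pytest.raises(ValueError):
        tr.finetune_hsi(model, [], [], tr.TrainConfig())


def test_finetune_with_equivariance_term_runs():
    model = _tiny_model(6)
    items = [_hsi_item(7)]
    cfg = tr.TrainConfig(step3=tr.Step3Config(epochs=1, batch=1, val_every=1),
                         seed=1)
    out = tr.finetune_hsi(model, items, items, cfg, equivariance=True)
    evs = [r["equivariance"] for r in out["history"] if "equivariance" in r]
    assert evs and all(np.isfinite(v) and v >= 0 for v in evs)


def test_finetune_restores_best_validation_state():
    model = _tiny_model(8)
    items = [_hsi_item(s) for s in range(2)]
    cfg = tr.TrainConfig(step3=tr.Step3Config(epochs=4, batch=2, val_every=2),
                         seed=2)
    out = tr.finetune_hsi(model, items[:1], items[1:], cfg)
    assert out["best_epoch"] is not None
    assert tr._val_hsi_score(model, items[1:]) == pytest.approx(
        out["best_score"])


# ----------------------------------------------------------------- schedules
def test_cosine_schedule_endpoints_in_history():
    model = _tiny_model(10)
    items = [_rgb_item(0)]
    cfg = tr.TrainConfig(step2=tr.Step2Config(epochs=3, batch=1, val_every=9),
                         seed=0)
    out = tr.train_rgb(model, items, [], cfg, augment=False)
    lrs = [r["lr"] for r in out["history"]]
    assert lrs[0] == pytest.approx(cfg.lr_start)
    assert lrs[-1] == pytest.approx(cfg.lr_end)
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))
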