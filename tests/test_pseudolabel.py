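"""Pseudo-label generation: patch masks, refinement, contours, vessels."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.transform import resize

from cortexfuse import pseudolabel as pl
from cortexfuse.evaluation import dsc


def _upscale_mask(mask, shape):
    return resize(mask.astype(float), shape, order=0,
                  preserve_range=True) > 0.5


@pytest.fixture(scope="module")
def rgb_truth(scene_small_rgb):
    """Scene truth masks resampled to the RGB grid."""
    shape = scene_small_rgb.rgb.shape[:2]
    return {
        "cortex": _upscale_mask(scene_small_rgb.cortex_gold, shape),
        "vessels": _upscale_mask(scene_small_rgb.vessel_truth, shape),
    }


# ------------------------------------------------------------- patch masks
def test_build_patch_mask_union_and_bounds():
    ann = pl.PatchAnnotationSet([(0, 0, 4), (2, 2, 4)], (10, 10))
    mask = pl.build_patch_mask(ann)
    assert mask.sum() == 16 + 16 - 4
    with pytest.raises(ValueError):
        pl.PatchAnnotationSet([(8, 8, 4)], (10, 10))
    with pytest.raises(ValueError):
        pl.build_patch_mask(pl.PatchAnnotationSet([], (10, 10)))


def test_simulated_annotations_lie_inside_cortex(scene_small_rgb, rgb_truth):
    cortex = rgb_truth["cortex"]
    ann = pl.simulate_patch_annotations(cortex, coverage=0.4, seed=2)
    mask = pl.build_patch_mask(ann)
    assert mask[~cortex].sum() == 0          # every patch fully inside
    assert mask.sum() >= 0.3 * cortex.sum()  # reached useful coverage
    # determinism
    ann2 = pl.simulate_patch_annotations(cortex, coverage=0.4, seed=2)
    assert ann.positive_patches == ann2.positive_patches


def test_negative_patches_respect_margin_and_do_not_overlap():
    mask = np.zeros((500, 900), bool)
    mask[0:40, 0:40] = True
    patches = pl.sample_negative_patches(mask, seed=1)
    assert patches
    cheb = ndi.distance_transform_cdt(~mask, metric="chessboard")
    occupied = np.zeros_like(mask)
    for (t, l, s) in patches:
        assert s == 217
        window = cheb[t:t + s, l:l + s]
        assert window.min() >= 108
        assert not occupied[t:t + s, l:l + s].any()
        occupied[t:t + s, l:l + s] = True
    with pytest.raises(ValueError):
        pl.sample_negative_patches(np.zeros((100, 100), bool))


# -------------------------------------------------------- cortex refinement
def test_refinement_recovers_cortex_from_patches(scene_small_rgb, rgb_truth):
    cortex = rgb_truth["cortex"]
    ann = pl.simulate_patch_annotations(cortex, coverage=0.4, seed=0)
    patch_mask = pl.build_patch_mask(ann)
    refined = pl.refine_cortex_annotation(scene_small_rgb.rgb, patch_mask,
                                          seed=0)
    assert dsc(refined, cortex) > dsc(patch_mask, cortex)
    assert dsc(refined, cortex) > 80.0
    # monotone: contains the closing of the input annotation
    closed = ndi.binary_closing(patch_mask, structure=np.ones((3, 3)))
    assert refined[closed].all()


def test_refinement_on_uniform_image_returns_closed_patch_mask():
    rgb = np.full((120, 160, 3), 0.5)
    patch_mask = pl.build_patch_mask(
        pl.PatchAnnotationSet([(30, 40, 25), (50, 60, 25)], (120, 160)))
    refined = pl.refine_cortex_annotation(rgb, patch_mask, seed=0)
    from skimage.morphology import disk
    expect = ndi.binary_fill_holes(
        ndi.binary_closing(patch_mask, structure=disk(5)) | patch_mask)
    assert np.array_equal(refined, expect)


def test_refinement_rejects_degenerate_inputs():
    rgb = np.zeros((50, 50, 3))
    with pytest.raises(ValueError):
        pl.refine_cortex_annotation(rgb, np.zeros((50, 50), bool))
    with pytest.raises(ValueError):
        pl.refine_cortex_annotation(rgb, np.ones((50, 50), bool), k_clusters=1)


# ------------------------------------------------------------------ contours
def test_perimeter_contours_hug_the_true_boundary(scene_small_rgb, rgb_truth):
    cortex = rgb_truth["cortex"]
    contour = pl.approximate_perimeter(scene_small_rgb.rgb, cortex)
    assert contour.any()
    # contour pixels stay close to the true cortex boundary
    boundary = cortex & ~ndi.binary_erosion(cortex)
    dist = ndi.distance_transform_edt(~boundary)
    assert np.median(dist[contour]) < 8.0


def test_perimeter_on_edge_free_image_is_empty():
    rgb = np.full((100, 140, 3), 0.4)
    mask = np.zeros((100, 140), bool)
    mask[30:70, 40:100] = True
    contour = pl.approximate_perimeter(rgb, mask)
    assert not contour.any()
    with pytest.raises(ValueError):
        pl.approximate_perimeter(rgb, np.zeros((100, 140), bool))


# ------------------------------------------------------------------ vessels
def test_operator_bank_kernels_are_zero_mean_and_oriented():
    bank = pl.make_operator_bank(7, 15)
    assert bank.kernels["thin"].shape == (12, 7, 7)
    assert bank.kernels["thick"].shape == (12, 15, 15)
    np.testing.assert_allclose(bank.kernels["thin"].sum(axis=(1, 2)), 0.0,
                               atol=1e-12)
    np.testing.assert_allclose(bank.kernels["thick"].sum(axis=(1, 2)), 0.0,
                               atol=1e-12)
    with pytest.raises(ValueError):
        pl.make_operator_bank(6, 15)
    with pytest.raises(ValueError):
        pl.make_operator_bank(7, 1)


def test_line_response_is_rotation_consistent():
    rng = np.random.default_rng(4)
    img = ndi.gaussian_filter(rng.random((64, 64)), 2)
    bank = pl.make_operator_bank(7, 15)
    r = pl.line_response(img, bank)
    r_rot = pl.line_response(np.rot90(img), bank)
    np.testing.assert_allclose(np.rot90(r), r_rot, atol=1e-8)


def test_detect_vessels_finds_dark_lines():
    img = np.full((80, 120), 0.8)
    img[40, 10:110] = 0.2                     # horizontal dark line
    img[10:70, 60] += 0                      # keep a single line scenario
    bank = pl.make_operator_bank(7, 15)
    mask = pl.detect_vessels(img, bank, min_area=10)
    line = np.zeros_like(mask)
    line[40, 10:110] = True
    assert mask[line].mean() > 0.9            # line recovered
    assert mask[~ndi.binary_dilation(line, iterations=8)].mean() < 0.12


def test_detect_vessels_degenerate_and_min_area():
    bank = pl.make_operator_bank(5, 11)
    assert not pl.detect_vessels(np.full((40, 40), 0.5), bank).any()
    # a huge min_area removes every component
    img = np.full((60, 60), 0.8)
    img[30, 10:50] = 0.2
    assert pl.detect_vessels(img, bank, min_area=10).any()
    assert not pl.detect_vessels(img, bank, min_area=10**6).any()


def test_vessel_pseudolabels_on_scene(scene_small_rgb, rgb_truth):
    gray = rgb2gray(scene_small_rgb.rgb)
    bank = pl.make_operator_bank(7, 15)
    mask = pl.detect_vessels(gray, bank, min_area=40)
    mask &= rgb_truth["cortex"]
    vessels = rgb_truth["vessels"]
    hit = mask[vessels].mean()
    false = mask[rgb_truth["cortex"] & ~vessels].mean()
    assert hit > 2 * false                    # concentrates on true vessels


# ---------------------------------------------------------- densification
def test_densify_fills_gaps_keeps_labels_resolves_conflicts():
    from skimage.morphology import disk
    gt = np.zeros((40, 40), np.uint8)
    rr, cc = np.mgrid[0:40, 0:40]
    in_rows = (rr >= 5) & (rr <= 15)
    # sparse 3-spaced sampling grids of two overlapping regions
    grid_a = (rr % 3 == 0) & (cc % 3 == 0)
    grid_b = (rr % 3 == 1) & (cc % 3 == 1)
    gt[in_rows & (cc >= 5) & (cc <= 20) & grid_a] = pl.HEALTHY
    gt[in_rows & (cc >= 15) & (cc <= 30) & grid_b] = pl.TUMOR
    dense = pl.densify_gt(gt)
    assert dense[10, 8] == pl.HEALTHY          # interior hole filled
    # original labels never removed
    assert np.all(dense[gt > 0] == gt[gt > 0])
    # where both class closings claim a previously-unlabeled pixel -> unlabeled
    fp = disk(5)
    ca = ndi.binary_closing(gt == pl.HEALTHY, structure=fp) | (gt == pl.HEALTHY)
    cb = ndi.binary_closing(gt == pl.TUMOR, structure=fp) | (gt == pl.TUMOR)
    conflict = ca & cb & (gt == 0)
    assert conflict.any()
    assert not dense[conflict].any()
    # empty input stays empty
    assert not pl.densify_gt(np.zeros((10, 10), np.uint8)).any()


def test_densified_gt_consistent_with_truth(scene_small_rgb):
    dense = pl.densify_gt(scene_small_rgb.gt_sparse)
    truth = scene_small_rgb.truth
    both = (dense > 0) & (truth > 0)
    agree = (dense[both] == truth[both]).mean()
    assert agree > 0.95
    assert (dense > 0).sum() >= (scene_small_rgb.gt_sparse > 0).sum()


# ------------------------------------------------- background and adjusted GT
@pytest.fixture(scope="module")
def densified(scene_small_rgb):
    return pl.densify_gt(scene_small_rgb.gt_sparse)


def test_background_complement_avoids_cortex(scene_small_rgb, densified):
    feats = np.moveaxis(scene_small_rgb.cube.data, 0, -1)
    bg = pl.complement_background(feats, densified, seed=0)
    cortex = scene_small_rgb.cortex_gold
    assert not bg[np.isin(densified, pl.CORTICAL)].any()
    # mostly lands outside the true cortex
    assert bg[~cortex].sum() > 4 * bg[cortex].sum()
    with pytest.raises(ValueError):
        pl.complement_background(feats, densified, k_clusters=8, n_background=8)
    with pytest.raises(ValueError):
        pl.complement_background(feats, np.zeros_like(densified))


def test_adjusted_gt_inner_outer_disjoint(scene_small_rgb, densified):
    feats = np.moveaxis(scene_small_rgb.cube.data, 0, -1)
    bg = pl.complement_background(feats, densified, seed=0)
    adj = pl.build_adjusted_gt(densified, bg)
    inner = adj.labels == pl.AdjustedGT.INNER
    outer = adj.labels == pl.AdjustedGT.OUTER
    assert not (inner & outer).any()
    assert set(np.unique(adj.labels)) <= {0, 1, 2}
    assert inner[np.isin(densified, pl.CORTICAL)].all()
    # the hull interior stays almost entirely inside the true cortex
    cortex = ndi.binary_dilation(scene_small_rgb.cortex_gold, iterations=2)
    assert (inner & cortex).sum() / inner.sum() > 0.9
    with pytest.raises(ValueError):
        pl.build_adjusted_gt(np.zeros((10, 10), np.uint8), bg[:10, :10])


# ---------------------------------------------------------- dataset adaptation
def test_adapt_rgb_dataset_hits_target_fraction(scene_small_rgb, rgb_truth):
    cortex = rgb_truth["cortex"]
    img, masks = pl.adapt_rgb_dataset(scene_small_rgb.rgb, cortex,
                                      masks={"vessels": rgb_truth["vessels"]})
    assert img.shape == (217, 409, 3)
    assert img.min() >= 0.0 and img.max() <= 1.0
    frac = masks["refined"].mean()
    assert 0.12 < frac < 0.30
    assert masks["vessels"].shape == (217, 409)
    with pytest.raises(ValueError):
        pl.adapt_rgb_dataset(scene_small_rgb.rgb,
                             np.zeros_like(cortex))


def test_adapt_rgb_dataset_warns_when_mask_dominates():
    rgb = np.random.default_rng(0).random((100, 200, 3))
    mask = np.zeros((100, 200), bool)
    mask[5:95, 5:195] = True
    with pytest.warns(UserWarning):
        img, masks = pl.adapt_rgb_dataset(rgb, mask)
    assert img.shape == (217, 409, 3)


# ------------------------------------------------------------- orchestration
def test_generate_rgb_pseudolabels_end_to_end(scene_small_rgb, rgb_truth):
    ann = pl.simulate_patch_annotations(rgb_truth["cortex"], seed=1)
    labels = pl.generate_rgb_pseudolabels(scene_small_rgb.rgb, ann, seed=1)
    assert labels.provenance == "rgb"
    assert labels.vessel_mask[~labels.cortex_mask].sum() == 0
    assert dsc(labels.cortex_mask, rgb_truth["cortex"]) > 80.0
    assert labels.vessel_mask.any()
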