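"""Loss values against hand computations and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest

from cortexfuse import losses as L
from cortexfuse.nn import Tensor
from cortexfuse.network import NetOutput


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _softish(mask, eps=1e-4):
    return np.where(mask, 1.0 - eps, eps)


# ------------------------------------------------------------------ DSC+BCE
def test_dsc_bce_hand_computed_2x2_toy():
    pred = np.array([[0.9, 0.1], [0.8, 0.2]])
    target = np.array([[1.0, 0.0], [1.0, 0.0]])
    dice = (2 * (0.9 + 0.8) + 1) / (2.0 + 2.0 + 1)
    bce = -(2 * math.log(0.9) + 2 * math.log(0.8)) / 4
    expect = (1 - dice) + bce
    assert float(L.dsc_bce_loss(pred, target).data) == pytest.approx(expect,
                                                                     abs=1e-9)


def test_dsc_bce_extremes():
    target = _disk((30, 30), (15, 15), 8).astype(float)
    near_perfect = L.dsc_bce_loss(_softish(target > 0), target)
    assert float(near_perfect.data) == pytest.approx(0.0, abs=1e-2)
    inverted = L.dsc_bce_loss(_softish(target == 0), target)
    assert float(inverted.data) > 1.0


def test_dsc_bce_gradient_is_finite():
    pred = Tensor(np.full((5, 5), 0.6), requires_grad=True)
    L.dsc_bce_loss(pred, np.eye(5)).backward()
    assert np.isfinite(pred.grad).all() and np.any(pred.grad != 0)


# ------------------------------------------------------------------ contour
def test_contour_aligned_boundary_is_cheaper_than_offset():
    shape = (60, 60)
    disc = _disk(shape, (30, 30), 15)
    from scipy import ndimage as ndi
    from skimage.feature import canny
    # contour pseudo-labels lying exactly on the predicted boundary
    pseudo = ndi.binary_dilation(canny(disc.astype(float), sigma=1.0),
                                 structure=L._ELLIPSE_3x3)
    aligned = L.contour_loss(_softish(disc), pseudo)
    shifted = L.contour_loss(_softish(_disk(shape, (30, 40), 15)), pseudo)
    assert float(aligned.data) < float(shifted.data)
    assert float(aligned.data) == pytest.approx(0.0, abs=0.5)


def test_contour_empty_pseudo_is_zero():
    out = L.contour_loss(_softish(_disk((20, 20), (10, 10), 5)),
                         np.zeros((20, 20), bool))
    assert float(out.data) == 0.0


# ---------------------------------------------------------------- self hull
def test_self_hull_convex_solid_near_zero_split_blobs_higher():
    shape = (60, 80)
    solid = _softish(_disk(shape, (30, 30), 14))
    blobs = _disk(shape, (30, 15), 10) | _disk(shape, (30, 65), 10)
    solid_loss = float(L.self_hull_loss(solid).data)
    blob_loss = float(L.self_hull_loss(_softish(blobs)).data)
    assert solid_loss == pytest.approx(0.0, abs=0.05)
    assert blob_loss > solid_loss + 0.05


def test_self_hull_empty_prediction_is_one():
    assert float(L.self_hull_loss(np.full((20, 20), 1e-4)).data) == 1.0


# --------------------------------------------------------------- cross hull
def test_cross_hull_identical_and_concentric_and_empty():
    shape = (80, 80)
    disc = _disk(shape, (40, 40), 24)
    same = L.cross_hull_loss(_softish(disc), _softish(disc))
    assert float(same.data) == pytest.approx(0.0, abs=0.02)
    # vessel hull = cortex hull shrunk 50% linearly -> Dice 0.4, loss 0.6
    half = _disk(shape, (40, 40), 12)
    conc = L.cross_hull_loss(_softish(disc), _softish(half))
    assert float(conc.data) == pytest.approx(0.6, abs=0.03)
    empty = L.cross_hull_loss(_softish(disc), np.full(shape, 1e-4))
    assert float(empty.data) == 1.0


# ------------------------------------------------------------------- excess
def test_excess_nested_zero_and_complement_ln11():
    y = _disk((40, 40), (20, 20), 12).astype(float)
    inside = _disk((40, 40), (20, 20), 6).astype(float)
    assert float(L.excess_loss(inside, y).data) == pytest.approx(0.0,
                                                                 abs=1e-12)
    comp = 1.0 - y
    assert float(L.excess_loss(comp, y).data) == pytest.approx(math.log(11),
                                                               abs=1e-9)
    batch_pred = np.stack([inside, comp])
    batch_y = np.stack([y, y])
    assert float(L.excess_loss(batch_pred, batch_y).data) == pytest.approx(
        math.log(11) / 2, abs=1e-9)


def test_excess_monotone_in_outside_overlap():
    y = np.zeros((30, 30))
    y[5:25, 5:15] = 1.0
    vals = []
    for extent in (15, 18, 21, 24, 27):
        pred = np.zeros((30, 30))
        pred[5:25, 5:extent] = 1.0     # grows further outside y
        vals.append(float(L.excess_loss(pred, y).data))
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] > vals[0]


def test_excess_shape_mismatch_errors():
    with pytest.raises(ValueError):
        L.excess_loss(np.zeros((4, 4)), np.zeros((5, 5)))


# -------------------------------------------------------------------- total
def test_total_is_exact_sum_of_components():
    rng = np.random.default_rng(0)
    shape = (48, 48)
    cortex = _disk(shape, (24, 24), 15)
    vessel = _disk(shape, (24, 24), 15) & (rng.random(shape) < 0.3)
    from scipy import ndimage as ndi
    boundary = cortex & ~ndi.binary_erosion(cortex)
    out = NetOutput(cortex_prob=Tensor(_softish(cortex)),
                    vessel_prob=Tensor(np.clip(
                        _softish(vessel) + 0.05 * rng.random(shape),
                        1e-4, 1 - 1e-4)))
    bd = L.total_rgb_loss(out, {"cortex_mask": cortex.astype(float),
                                "contour_map": boundary,
                                "vessel_mask": vessel.astype(float)})
    parts = (bd.l_ctx + bd.l_self_hull + bd.l_cont + bd.l_vsl
             + bd.l_cross_hull + bd.l_excess)
    assert bd.total == pytest.approx(parts, rel=1e-6)
    assert bd.total_tensor is not None


def test_total_missing_pseudolabel_is_named():
    out = NetOutput(cortex_prob=Tensor(np.full((8, 8), 0.5)),
                    vessel_prob=Tensor(np.full((8, 8), 0.5)))
    with pytest.raises(ValueError, match="vessel_mask"):
        L.total_rgb_loss(out, {"cortex_mask": np.ones((8, 8)),
                               "contour_map": np.ones((8, 8), bool)})


# ------------------------------------------------------------------- SupCon
def _supcon_bruteforce(z, labels, tau):
    n = len(z)
    anchor_losses = []
    for i in range(n):
        pos = [p for p in range(n) if p != i and labels[p] == labels[i]]
        if not pos:
            continue
        denom = sum(math.exp(z[i] @ z[a] / tau) for a in range(n) if a != i)
        anchor_losses.append(-np.mean(
            [math.log(math.exp(z[i] @ z[p] / tau) / denom) for p in pos]))
    return float(np.mean(anchor_losses))


def test_supcon_matches_bruteforce_pair_sum():
    z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    labels = np.array([0, 0, 1, 1])
    ours = float(L.supcon_loss(z, labels, tau=0.1).data)
    assert ours == pytest.approx(_supcon_bruteforce(z, labels, 0.1), rel=1e-6)
    rng = np.random.default_rng(3)
    z = rng.normal(size=(6, 4))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    labels = np.array([0, 1, 0, 1, 2, 2])
    ours = float(L.supcon_loss(z, labels, tau=0.1).data)
    assert ours == pytest.approx(_supcon_bruteforce(z, labels, 0.1), rel=1e-6)


def test_supcon_prefers_true_labels_over_shuffled():
    z = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [-0.1, 0.9]])
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    good = float(L.supcon_loss(z, [0, 0, 1, 1]).data)
    bad = float(L.supcon_loss(z, [0, 1, 0, 1]).data)
    assert good < bad


def test_supcon_tau_monotone_and_no_partner_error():
    z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    vals = [float(L.supcon_loss(z, [0, 0, 1, 1], tau=t).data)
            for t in (0.05, 0.1, 0.2, 0.5)]
    diffs = np.diff(vals)
    assert np.all(diffs > 0) or np.all(diffs < 0)
    with pytest.raises(ValueError):
        L.supcon_loss(np.eye(3), [0, 1, 2])


# --------------------------------------------------------------- masked BCE
def test_masked_cortex_bce_hand_toy():
    pred = np.array([[0.8, 0.8, 0.8, 0.3, 0.3, 0.123]])
    lab = np.array([[1, 1, 1, 2, 2, 0]])
    expect = -(3 * math.log(0.8) + 2 * math.log(0.7)) / 5
    assert float(L.masked_cortex_bce(pred, lab).data) == pytest.approx(
        expect, rel=1e-6)
    # unknown-pixel change leaves the loss untouched
    pred2 = pred.copy()
    pred2[0, 5] = 0.999
    assert float(L.masked_cortex_bce(pred2, lab).data) == pytest.approx(
        float(L.masked_cortex_bce(pred, lab).data), rel=1e-12)


def test_masked_cortex_bce_all_unknown_warns():
    with pytest.warns(UserWarning):
        out = L.masked_cortex_bce(np.full((4, 4), 0.5), np.zeros((4, 4), int))
    assert float(out.data) == 0.0


def test_masked_vessel_bce_outer_activation_and_ignored_pseudo():
    pred = np.array([[0.9, 0.9]])
    lab = np.array([[2, 0]])                     # one outer, one unknown
    pseudo = np.array([[1, 1]], bool)            # pseudo-label outside inner
    out = float(L.masked_vessel_bce(pred, pseudo, lab).data)
    assert out == pytest.approx(-math.log(1 - 0.9), rel=1e-6)
    # perfect: match pseudo on inner, silence on outer
    pred = np.array([[0.999, 0.001, 0.001]])
    lab = np.array([[1, 1, 2]])
    pseudo = np.array([[1, 0, 0]], bool)
    assert float(L.masked_vessel_bce(pred, pseudo, lab).data) < 0.01


# ------------------------------------------------------------- equivariance
class _PixelwiseModel:
    """Perfectly equivariant toy model: probabilities are pixelwise maps."""

    def forward(self, x, modality):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        p = 1.0 / (1.0 + np.exp(-x[:, :1]))
        return NetOutput(cortex_prob=Tensor(p), vessel_prob=Tensor(1.0 - p))


class _ConstantModel:
    def forward(self, x, modality):
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        shape = (x.shape[0], 1, *x.shape[-2:])
        return NetOutput(cortex_prob=Tensor(np.full(shape, 0.7)),
                         vessel_prob=Tensor(np.full(shape, 0.2)))


def test_equivariance_identity_and_pixelwise_and_constant_are_zero():
    x = np.random.default_rng(0).random((3, 12, 16))
    ident = L.equivariance_loss(_PixelwiseModel(), x,
                                transform_set=("identity",))
    assert float(ident.data) == pytest.approx(0.0, abs=1e-12)
    pix = L.equivariance_loss(_PixelwiseModel(), x, n_samples=3)
    assert float(pix.data) == pytest.approx(0.0, abs=1e-12)
    const = L.equivariance_loss(_ConstantModel(), x,
                                transform_set=("hflip", "vflip"))
    assert float(const.data) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        L.equivariance_loss(_ConstantModel(), x, transform_set=("shear",))


# --------------------------------------------------------------- invariants
def test_all_losses_nonnegative_and_finite_on_random_inputs():
    rng = np.random.default_rng(42)
    p1 = np.clip(rng.random((24, 24)), 1e-6, 1 - 1e-6)
    p2 = np.clip(rng.random((24, 24)), 1e-6, 1 - 1e-6)
    mask = rng.random((24, 24)) < 0.4
    lab = rng.integers(0, 3, (24, 24))
    vals = [
        L.dsc_bce_loss(p1, mask.astype(float)),
        L.contour_loss(p1, mask),
        L.self_hull_loss(p1),
        L.cross_hull_loss(p1, p2),
        L.excess_loss(p2, mask.astype(float)),
        L.masked_cortex_bce(p1, lab),
        L.masked_vessel_bce(p2, mask, lab),
    ]
    for v in vals:
        fv = float(v.data)
        assert np.isfinite(fv) and fv >= 0.0


def test_loss_config_validation():
    with pytest.raises(ValueError):
        L.LossConfig(alpha=0)
    with pytest.raises(ValueError):
        L.LossConfig(tau=-1)
    with pytest.raises(ValueError):
        L.LossConfig(binarize_threshold=1.5)
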