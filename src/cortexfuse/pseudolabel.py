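"""Pseudo-label generation from weak annotations.

Turns coarse square-patch annotations of the exposed cortex and sparse
spectral ground truth into the dense supervision used for training:

* ``refine_cortex_annotation`` grows the patch mask toward the true cortex
  boundary through K-means color clusters (vessel-like clusters propagate the
  region, chromatically similar clusters are absorbed);
* ``approximate_perimeter`` extracts the strongest Canny contours near the
  refined mask with a SLIC superpixel search band;
* oriented line-operator banks score dark elongated structures on the
  inverted grayscale image to produce vessel pseudo-labels;
* sparse 4-class ground truth is densified by per-class morphological closing
  and complemented with background clusters most dissimilar to cortical
  tissue, then reduced to the inner/outer/unknown adjusted ground truth used
  for HSI fine-tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans
from skimage.color import rgb2gray, rgb2lab
from skimage.feature import canny
from skimage.filters import sobel
from skimage.morphology import disk, remove_small_objects
from skimage.segmentation import slic
from skimage.transform import resize

from .hull import hull_region_of_points

UNLABELED, HEALTHY, TUMOR, VESSEL, DURA = 0, 1, 2, 3, 4
CORTICAL = (HEALTHY, TUMOR, VESSEL)

NEG_PATCH_SIZE = 217              # height of the HSI frame
NEG_MARGIN = 217 // 2             # floor(217/2) = 108 px safety margin

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class PatchAnnotationSet:
    """Axis-aligned square patches (top, left, size) marking cortex."""

    positive_patches: list
    image_size: tuple

    def __post_init__(self):
        h, w = self.image_size
        for (t, l, s) in self.positive_patches:
            if t < 0 or l < 0 or t + s > h or l + s > w:
                raise ValueError(f"patch {(t, l, s)} outside image {h}x{w}")


@dataclass
class PseudoLabelSet:
    cortex_mask: np.ndarray
    contour_map: np.ndarray
    vessel_mask: np.ndarray
    provenance: str = "rgb"


@dataclass
class LinearOperatorBank:
    n_orientations: int
    kernel_sizes: dict          # {"thin": k, "thick": k}
    line_width: int
    kernels: dict               # size name -> (N, k, k) float array


@dataclass
class AdjustedGT:
    """Three-way ground truth for HSI fine-tuning: 0 unknown, 1 inner, 2 outer."""

    labels: np.ndarray

    INNER = 1
    OUTER = 2


# -------------------------------------------------------------- patch masks
def build_patch_mask(ann: PatchAnnotationSet) -> np.ndarray:
    """Union of the annotation squares as a binary mask."""
    if not ann.positive_patches:
        raise ValueError("empty patch annotation set")
    mask = np.zeros(ann.image_size, bool)
    for (t, l, s) in ann.positive_patches:
        mask[t:t + s, l:l + s] = True
    return mask


def simulate_patch_annotations(cortex_mask: np.ndarray, coverage: float = 0.4,
                               size_frac: float = 0.15,
                               seed: int = 0) -> PatchAnnotationSet:
    """Emulate the rapid manual patch annotation on a known cortex mask:
    squares fully inside the cortex until ~``coverage`` of its area is marked."""
    rng = np.random.default_rng(seed)
    area = int(cortex_mask.sum())
    if area == 0:
        raise ValueError("cortex mask is empty")
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    size = max(8, int(round(size_frac * eq_diam)))
    cheb = ndi.distance_transform_cdt(cortex_mask, metric="chessboard")
    valid = np.argwhere(cheb > size // 2 + 1)
    if len(valid) == 0:
        size = max(4, int(2 * (cheb.max() - 1)))
        valid = np.argwhere(cheb > size // 2 + 1)
    patches, covered = [], np.zeros_like(cortex_mask)
    for _ in range(400):
        cy, cx = valid[rng.integers(len(valid))]
        t, l = int(cy - size // 2), int(cx - size // 2)
        patches.append((t, l, size))
        covered[t:t + size, l:l + size] = True
        if covered.sum() >= coverage * area:
            break
    return PatchAnnotationSet(positive_patches=patches,
                              image_size=cortex_mask.shape)


def sample_negative_patches(mask: np.ndarray, patch_size: int = NEG_PATCH_SIZE,
                            margin: int = NEG_MARGIN, seed: int = 0,
                            max_patches: int = 64) -> list:
    """Non-overlapping squares at least ``margin`` Chebyshev pixels from the
    positive mask — automatic negative examples for contrastive pre-training."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if h <= patch_size or w <= patch_size:
        raise ValueError("image smaller than the patch size")
    cheb = ndi.distance_transform_cdt(~mask, metric="chessboard")
    allowed = cheb >= margin if mask.any() else np.ones_like(mask)
    # a patch is valid iff its entire window is allowed
    ok = ndi.minimum_filter(allowed.astype(np.uint8), size=patch_size,
                            mode="constant", cval=0).astype(bool)
    # valid top-left corners (minimum_filter is centered)
    half = patch_size // 2
    corners = np.argwhere(ok[half:half + (h - patch_size + 1),
                             half:half + (w - patch_size + 1)])
    if len(corners) == 0:
        warnings.warn("no valid negative patch placement")
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corners))
    chosen = []
    occupied = np.zeros((h, w), bool)
    for idx in order:
        t, l = corners[idx]
        if occupied[t:t + patch_size, l:l + patch_size].any():
            continue
        chosen.append((int(t), int(l), patch_size))
        occupied[t:t + patch_size, l:l + patch_size] = True
        if len(chosen) >= max_patches:
            break
    return chosen


# --------------------------------------------------------- cortex refinement
def _fit_clusters(features: np.ndarray, k: int, seed: int):
    """K-means on a pixel subsample; returns the model fitted on <=20k pixels."""
    flat = features.reshape(-1, features.shape[-1])
    rng = np.random.default_rng(seed)
    n = min(len(flat), 20000)
    sub = flat[rng.choice(len(flat), n, replace=False)]
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    with warnings.catch_warnings():
        # duplicate pixels (uniform regions) can collapse clusters; harmless
        warnings.simplefilter("ignore")
        km.fit(sub)
    labels = km.predict(flat).reshape(features.shape[:-1])
    return km, labels


def refine_cortex_annotation(rgb: np.ndarray, patch_mask: np.ndarray,
                             k_clusters: int = 12,
                             centroid_percentile: float = 60.0,
                             seed: int = 0) -> np.ndarray:
    """Grow the patch annotation toward the true cortex boundary.

    K-means clusters the image in Lab color space; clusters present inside
    the annotation that are darker than the annotation's median luminance
    act as vessel-like propagators, clusters chromatically close to any
    in-annotation cluster are absorbed, and the annotation grows through the
    connected union of both until a fixed point. A final morphological
    closing fills holes. Monotone: the result contains the closing of the
    input mask.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    patch_mask = np.asarray(patch_mask, bool)
    if not patch_mask.any():
        raise ValueError("patch mask is empty")
    lab = rgb2lab(np.asarray(rgb, dtype=float))
    km, cluster_map = _fit_clusters(lab, k_clusters, seed)
    centroids = km.cluster_centers_

    in_mask_ids = np.unique(cluster_map[patch_mask])
    l_median = np.median(lab[..., 0][patch_mask])
    vessel_like = {int(c) for c in in_mask_ids if centroids[c, 0] < l_median}

    dists = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=-1)
    # Chromatic-similarity threshold: the color spread *within* the annotated
    # cortex, measured as a percentile of the pairwise distances among the
    # non-vessel-like in-annotation cluster centroids. A global percentile
    # over all clusters would reflect palette spread (background included)
    # and absorb everything.
    core_ids = [int(c) for c in in_mask_ids if int(c) not in vessel_like]
    if len(core_ids) >= 2:
        sub = dists[np.ix_(core_ids, core_ids)]
        iu = np.triu_indices(len(core_ids), k=1)
        threshold = np.percentile(sub[iu], centroid_percentile)
    else:
        threshold = 0.0
    cortex_like = {
        int(c) for c in range(k_clusters)
        if core_ids and min(dists[c, m] for m in core_ids) < threshold
    }
    candidates = vessel_like | cortex_like
    candidate_px = np.isin(cluster_map, sorted(candidates))
    region = ndi.binary_propagation(patch_mask, structure=_FOUR_CONN,
                                    mask=candidate_px | patch_mask)
    region = ndi.binary_closing(region, structure=disk(5))
    region = ndi.binary_fill_holes(region | patch_mask)
    return region


def approximate_perimeter(rgb: np.ndarray, refined_mask: np.ndarray,
                          min_edge_length: int = 15,
                          n_segments: int = 400,
                          compactness: float = 10.0,
                          canny_sigma: float = 1.5) -> np.ndarray:
    """Strongest contours near the refined mask boundary.

    Canny edges (thresholds 0.66/1.33 x median gradient magnitude) with short
    fragments dropped; the search band spans the 5%-eroded to 10%-dilated
    mask (fractions of its equivalent-circle diameter); SLIC superpixels grow
    outward from the eroded mask, each stopping when it meets a retained edge
    or leaves the band; the contour map keeps edges adjacent to the grown
    region.
    """
    refined_mask = np.asarray(refined_mask, bool)
    if not refined_mask.any():
        raise ValueError("refined mask is empty")
    gray = rgb2gray(np.asarray(rgb, dtype=float))
    med = np.median(sobel(gray))
    edges = canny(gray, sigma=canny_sigma,
                  low_threshold=0.66 * med, high_threshold=1.33 * med)
    if edges.any():
        edges = remove_small_objects(edges, max_size=min_edge_length - 1,
                                     connectivity=2)
    if not edges.any():
        return np.zeros_like(refined_mask)

    eq_diam = 2.0 * np.sqrt(refined_mask.sum() / np.pi)
    r_dil = max(1, int(round(0.10 * eq_diam)))
    r_ero = max(1, int(round(0.05 * eq_diam)))
    dilated = ndi.binary_dilation(refined_mask, structure=disk(r_dil))
    eroded = ndi.binary_erosion(refined_mask, structure=disk(r_ero))
    band = dilated & ~eroded

    segments = slic(np.asarray(rgb, dtype=float), n_segments=n_segments,
                    compactness=compactness, start_label=1,
                    channel_axis=-1 if rgb.ndim == 3 else None)
    n_sp = segments.max()
    sp_has_edge = np.zeros(n_sp + 1, bool)
    np.logical_or.at(sp_has_edge, segments[edges], True)
    sp_in_band = np.ones(n_sp + 1, bool)
    np.logical_and.at(sp_in_band, segments[~(band | eroded)], False)

    # adjacency between superpixels
    adj = {i: set() for i in range(1, n_sp + 1)}
    for a, b in ((segments[:-1, :], segments[1:, :]),
                 (segments[:, :-1], segments[:, 1:])):
        pairs = np.unique(np.stack([a.ravel(), b.ravel()], axis=1), axis=0)
        for u, v in pairs:
            if u != v:
                adj[int(u)].add(int(v))
                adj[int(v)].add(int(u))

    start = set(np.unique(segments[eroded]).tolist())
    accepted = set(start)
    frontier = list(start)
    while frontier:
        sp = frontier.pop()
        for nb in adj[sp]:
            if nb in accepted or sp_has_edge[nb] or not sp_in_band[nb]:
                continue
            accepted.add(nb)
            frontier.append(nb)

    region = eroded | np.isin(segments, sorted(accepted))
    near_region = ndi.binary_dilation(region, structure=disk(2))
    contour = edges & near_region & band
    return contour


# --------------------------------------------------------------- vessels
def _line_kernel(k: int, theta_deg: float, width: int) -> np.ndarray:
    """Zero-mean k x k kernel with a centered straight line at ``theta_deg``."""
    c = (k - 1) / 2.0
    yy, xx = np.mgrid[0:k, 0:k] - c
    th = np.deg2rad(theta_deg)
    d_perp = np.abs(-np.sin(th) * xx + np.cos(th) * yy)
    # tolerance keeps exact half-pixel ties (e.g. sin 30 deg = 0.5) stable
    # across orientations, so the bank is closed under 90-degree rotation
    line = d_perp <= (width / 2.0) + 1e-9
    kern = np.where(line, 1.0 / line.sum(), -1.0 / (~line).sum())
    return kern


def make_operator_bank(k_thin: int, k_thick: int, n: int = 12,
                       line_width: int = 1) -> LinearOperatorBank:
    """Oriented line-operator bank: ``n`` angles offset by 180/n degrees at
    two kernel sizes (thin capillaries vs thicker veins/arteries)."""
    for k in (k_thin, k_thick):
        if k < 3 or k % 2 == 0:
            raise ValueError("kernel sizes must be odd and >= 3")
    angles = [i * 180.0 / n for i in range(n)]
    kernels = {
        "thin": np.stack([_line_kernel(k_thin, a, line_width) for a in angles]),
        "thick": np.stack([_line_kernel(k_thick, a, line_width) for a in angles]),
    }
    return LinearOperatorBank(n_orientations=n,
                              kernel_sizes={"thin": k_thin, "thick": k_thick},
                              line_width=line_width, kernels=kernels)


def line_response(image: np.ndarray, bank: LinearOperatorBank,
                  window_normalized: bool = False) -> np.ndarray:
    """Maximum correlation of the inverted image with every kernel.

    With ``window_normalized`` the response follows the classic line-strength
    form: (mean on the line) - (mean of the window), divided by the window
    standard deviation.
    """
    inv = 1.0 - np.asarray(image, dtype=float)
    resp = np.full(inv.shape, -np.inf)
    for name, kset in bank.kernels.items():
        k = bank.kernel_sizes[name]
        half = k // 2
        padded = np.pad(inv, half, mode="reflect")
        if window_normalized:
            box = np.ones((k, k)) / (k * k)
            mu = fftconvolve(padded, box, mode="valid")
            mu2 = fftconvolve(padded ** 2, box, mode="valid")
            sd = np.sqrt(np.maximum(mu2 - mu ** 2, 1e-12))
        for kern in kset:
            r = fftconvolve(padded, kern[::-1, ::-1], mode="valid")
            if window_normalized:
                r = r / sd
            np.maximum(resp, r, out=resp)
    return resp


def detect_vessels(image: np.ndarray, bank: LinearOperatorBank,
                   threshold_quantile: float = 0.90,
                   min_area: int = 10,
                   window_normalized: bool = False) -> np.ndarray:
    """Vessel mask from the line-operator response of the inverted image.

    Pixels above the in-image response quantile are kept; components smaller
    than ``min_area`` are removed. Assumes dark vessels on lighter cortex.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return np.zeros(image.shape, bool)
    resp = line_response(image, bank, window_normalized=window_normalized)
    thr = np.quantile(resp, threshold_quantile)
    mask = resp > thr
    if mask.any() and min_area > 1:
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    return mask


# -------------------------------------------------- densification/background
def densify_gt(gt_sparse: np.ndarray) -> np.ndarray:
    """Per-class morphological closing (11x11 elliptical kernel) of the sparse
    ground truth; pixels claimed by two classes after closing become unlabeled,
    but original labels are never removed."""
    gt_sparse = np.asarray(gt_sparse)
    footprint = disk(5)  # 11x11 elliptical structuring element
    out = np.zeros_like(gt_sparse)
    claim_count = np.zeros(gt_sparse.shape, np.uint8)
    closed = {}
    for cls in (HEALTHY, TUMOR, VESSEL, DURA):
        m = gt_sparse == cls
        if not m.any():
            continue
        cm = ndi.binary_closing(m, structure=footprint) | m
        closed[cls] = cm
        claim_count += cm
    for cls, cm in closed.items():
        out[cm & (claim_count == 1)] = cls
    out[gt_sparse > 0] = gt_sparse[gt_sparse > 0]
    return out


def complement_background(features: np.ndarray, densified_gt: np.ndarray,
                          k_clusters: int = 12, n_background: int = 8,
                          seed: int = 0) -> np.ndarray:
    """Background mask from the ``n_background`` clusters most dissimilar to
    the cortical-labeled pixels. ``features`` is (H, W, C) — e.g. Lab color
    or the 25-band spectrum moved to the last axis."""
    if n_background == 0:
        return np.zeros(densified_gt.shape, bool)
    if k_clusters <= n_background:
        raise ValueError("k_clusters must exceed n_background")
    cortical = np.isin(densified_gt, CORTICAL)
    if not cortical.any():
        raise ValueError("densified ground truth has no cortical labels")
    km, cluster_map = _fit_clusters(np.asarray(features, float), k_clusters, seed)
    ref = np.asarray(features, float)[cortical].mean(axis=0)
    d = np.linalg.norm(km.cluster_centers_ - ref, axis=1)
    chosen = np.argsort(d)[::-1][:n_background]
    mask = np.isin(cluster_map, chosen)
    mask &= ~cortical
    return mask


def build_adjusted_gt(densified_gt: np.ndarray,
                      background_mask: np.ndarray) -> AdjustedGT:
    """Inner = filled concave hull of healthy/tumor/vessel labels; outer =
    (dura plus background) minus inner; the rest is unknown."""
    cortical_pts = np.argwhere(np.isin(densified_gt, CORTICAL))
    if len(cortical_pts) == 0:
        raise ValueError("no cortical labels present")
    inner = hull_region_of_points(cortical_pts, densified_gt.shape)
    inner |= np.isin(densified_gt, CORTICAL)
    outer = ((densified_gt == DURA) | np.asarray(background_mask, bool)) & ~inner
    labels = np.zeros(densified_gt.shape, np.uint8)
    labels[inner] = AdjustedGT.INNER
    labels[outer] = AdjustedGT.OUTER
    return AdjustedGT(labels=labels)


# --------------------------------------------------------- dataset adaptation
def adapt_rgb_dataset(rgb: np.ndarray, refined_mask: np.ndarray,
                      masks: dict | None = None, target: tuple = (217, 409),
                      mask_fraction: float = 0.20):
    """Crop around the refined annotation so it fills ``mask_fraction`` of the
    window (aspect matching ``target``), then resize everything to ``target``.

    Returns (image, {name: mask}) with the image in [0, 1].
    """
    refined_mask = np.asarray(refined_mask, bool)
    if not refined_mask.any():
        raise ValueError("refined mask is empty")
    H, W = refined_mask.shape
    th, tw = target
    aspect = tw / th
    area = refined_mask.sum()
    win_area = area / mask_fraction
    h_win = int(round(np.sqrt(win_area / aspect)))
    w_win = int(round(h_win * aspect))

    rows = np.any(refined_mask, axis=1).nonzero()[0]
    cols = np.any(refined_mask, axis=0).nonzero()[0]
    bbox_h, bbox_w = rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1
    if h_win < bbox_h or w_win < bbox_w:
        warnings.warn("mask larger than the target fraction window; "
                      "using the smallest aspect-correct window containing it")
        h_win = max(bbox_h, int(np.ceil(bbox_w / aspect)))
        w_win = int(round(h_win * aspect))
    if h_win > H or w_win > W:
        warnings.warn("target mask fraction not achievable within the frame; "
                      "window clipped to the image")
        h_win = min(H, int(W / aspect))
        w_win = min(W, int(round(h_win * aspect)))

    cy, cx = ndi.center_of_mass(refined_mask)
    top = int(round(cy - h_win / 2))
    left = int(round(cx - w_win / 2))
    top = max(0, min(top, H - h_win))
    left = max(0, min(left, W - w_win))

    img = np.asarray(rgb, dtype=float)[top:top + h_win, left:left + w_win]
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    img = resize(img, target, order=1, preserve_range=True,
                 anti_aliasing=True)
    out_masks = {}
    all_masks = {"refined": refined_mask}
    all_masks.update(masks or {})
    for name, m in all_masks.items():
        crop = np.asarray(m)[top:top + h_win, left:left + w_win]
        out_masks[name] = resize(crop.astype(float), target, order=0,
                                 preserve_range=True).astype(m.dtype)
    return np.clip(img, 0.0, 1.0), out_masks


# ------------------------------------------------------------- orchestration
def generate_rgb_pseudolabels(rgb: np.ndarray, ann: PatchAnnotationSet,
                              k_clusters: int = 12, seed: int = 0,
                              k_thin: int = 7, k_thick: int = 15,
                              threshold_quantile: float = 0.90,
                              min_area: int = 40) -> PseudoLabelSet:
    """Full RGB pseudo-label stack: refined cortex mask, contour map, vessel
    pseudo-labels (line operator restricted to the refined mask)."""
    patch_mask = build_patch_mask(ann)
    refined = refine_cortex_annotation(rgb, patch_mask,
                                       k_clusters=k_clusters, seed=seed)
    contour = approximate_perimeter(rgb, refined)
    bank = make_operator_bank(k_thin, k_thick)
    gray = rgb2gray(np.asarray(rgb, dtype=float))
    vessels = detect_vessels(gray, bank,
                             threshold_quantile=threshold_quantile,
                             min_area=min_area)
    vessels &= refined
    return PseudoLabelSet(cortex_mask=refined, contour_map=contour,
                          vessel_mask=vessels, provenance="rgb")
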