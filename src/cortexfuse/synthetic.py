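"""Craniotomy-like synthetic scenes.

Generates matched RGB image / HSI cube / raw mosaic frame triplets with known
dense truth so the whole pipeline is testable without clinical data. The scene
statistics emulate an exposed brain surface: one irregular cortex blob
occupying 10-25% of the frame, dark curvilinear vessels inside it (cortical
tissue appears lighter than vascular tissue), an optional tumor blob with its
own spectral signature, a dura ring hugging the cortex, and drape-like
textured surroundings. Sparse ground truth mimics the compact-blob style of
semi-automatic spectral-similarity labeling, and a controllable "flawed
classifier" produces 4-class probability maps with prescribed confusions for
fusion experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk
from skimage.transform import resize

from .preproc import HSICube, RawMosaicFrame, ReferencePair, HSI_SHAPE, N_BANDS, mosaic

# Class labels in every dense / sparse ground-truth map.
UNLABELED, HEALTHY, TUMOR, VESSEL, DURA = 0, 1, 2, 3, 4
CLASS_NAMES = {HEALTHY: "healthy", TUMOR: "tumor", VESSEL: "vessel", DURA: "dura"}

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _band_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, N_BANDS)


def default_signatures() -> dict:
    """Per-class 25-band reflectance signatures in [0, 1].

    The vessel signature sits well below the cortex signatures across the
    whole range (darkest in the visible-red band), dura is the brightest
    structure, and the tumor curve crosses the healthy one so the two are
    separable spectrally but similar in brightness.
    """
    t = _band_grid()
    return {
        "healthy": 0.46 + 0.16 * t,
        "tumor": 0.58 - 0.10 * t + 0.08 * np.exp(-((t - 0.45) ** 2) / 0.02),
        "vessel": 0.14 + 0.08 * t,
        "dura": 0.70 + 0.10 * t,
        "background": 0.38 + 0.04 * np.sin(2 * np.pi * t),
    }


# Display colors used to render the RGB modality (linear RGB in [0, 1]).
_RGB_PALETTE = {
    "healthy": (0.80, 0.58, 0.54),
    "tumor": (0.82, 0.66, 0.48),
    "vessel": (0.28, 0.07, 0.07),
    "dura": (0.88, 0.84, 0.68),
    "background": (0.33, 0.52, 0.52),
}
_LABEL_TO_NAME = {UNLABELED: "background", HEALTHY: "healthy", TUMOR: "tumor",
                  VESSEL: "vessel", DURA: "dura"}


@dataclass
class SceneConfig:
    seed: int = 0
    rgb_size: tuple = (1080, 1920)
    hsi_size: tuple = HSI_SHAPE
    n_vessels: int = 7
    vessel_width_range: tuple = (1, 8)
    tumor_present: bool = True
    class_signatures: dict = field(default_factory=default_signatures)
    noise_sd: float = 0.01
    sparse_fraction: float = 0.2

    def __post_init__(self):
        if tuple(self.hsi_size) != HSI_SHAPE:
            raise ValueError(f"hsi_size is fixed at {HSI_SHAPE}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.rgb_size) != 2 or min(self.rgb_size) < 32:
            raise ValueError("invalid rgb_size")
        for name, sig in self.class_signatures.items():
            sig = np.asarray(sig, dtype=float)
            if sig.shape != (N_BANDS,):
                raise ValueError(f"signature '{name}' must have {N_BANDS} bands")
            if sig.min() < 0 or sig.max() > 1:
                raise ValueError(f"signature '{name}' must lie in [0, 1]")


@dataclass
class ScenePack:
    rgb: np.ndarray                  # (H, W, 3) in [0, 1]
    cube: HSICube                    # calibrated reflectance
    raw: RawMosaicFrame              # sensor counts (round-trips via demosaic)
    gt_sparse: np.ndarray            # sparse 4-class labels on the HSI grid
    cortex_gold: np.ndarray          # dense binary cortex mask (HSI grid)
    vessel_truth: np.ndarray         # dense binary vessel mask (HSI grid)
    truth: np.ndarray                # dense label map (HSI grid)
    refs: ReferencePair              # white/dark pair matching ``raw``'s cube
    config: SceneConfig


# ----------------------------------------------------------------- primitives
def _smooth_field(rng, shape, sigma):
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-9)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndi.label(mask, structure=_FOUR_CONN)
    if n == 0:
        return mask
    sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _cortex_blob(rng, shape, area_frac_target):
    """Irregular single 4-connected blob of roughly the target area fraction."""
    h, w = shape
    field = _smooth_field(rng, shape, sigma=min(h, w) / 7)
    # bias toward a random off-center location and away from the frame border
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h * rng.uniform(0.35, 0.65)
    cx = w * rng.uniform(0.35, 0.65)
    r = min(h, w) * rng.uniform(0.55, 0.75)
    field = field - 2.5 * (((yy - cy) / r) ** 2 + ((xx - cx) / r) ** 2)
    margin = 14
    border = np.ones(shape, bool)
    border[margin:-margin, margin:-margin] = False
    field[border] = field.min() - 1
    # threshold search on area fraction
    best = None
    for q in np.linspace(0.70, 0.995, 40):
        mask = field > np.quantile(field, q)
        mask = ndi.binary_fill_holes(_largest_component(mask))
        frac = mask.mean()
        if best is None or abs(frac - area_frac_target) < best[0]:
            best = (abs(frac - area_frac_target), mask)
    mask = best[1]
    # light smoothing of the outline, keeping a single component
    mask = ndi.binary_closing(mask, structure=disk(3))
    mask = ndi.binary_fill_holes(_largest_component(mask))
    return mask


def _bezier_points(p0, p1, p2, n=400):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2)


def _rasterize_stroke(shape, pts, width):
    canvas = np.zeros(shape, bool)
    ij = np.round(pts).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
    canvas[ij[:, 0], ij[:, 1]] = True
    r = int(round((width - 1) / 2))
    if r > 0:
        canvas = dilation(canvas, disk(r))
    return canvas


def _draw_vessels(rng, cortex, n_vessels, width_range):
    """Random quadratic Bezier strokes with per-curve width, inside the cortex."""
    coords = np.argwhere(cortex)
    vessels = np.zeros(cortex.shape, bool)
    if coords.size == 0 or n_vessels <= 0:
        return vessels
    for _ in range(n_vessels):
        p0, p2 = coords[rng.integers(len(coords), size=2)].astype(float)
        mid = (p0 + p2) / 2
        d = p2 - p0
        perp = np.array([-d[1], d[0]])
        norm = np.hypot(*perp) + 1e-9
        p1 = mid + perp / norm * rng.uniform(-0.4, 0.4) * norm
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        stroke = _rasterize_stroke(cortex.shape, _bezier_points(p0, p1, p2), width)
        vessels |= stroke & cortex
    return vessels


def _draw_tumor(rng, cortex):
    interior = ndi.distance_transform_edt(cortex) >= 12
    coords = np.argwhere(interior)
    if len(coords) == 0:
        return np.zeros(cortex.shape, bool)
    cy, cx = coords[rng.integers(len(coords))]
    r = rng.uniform(9, 18)
    rr, cc = draw_disk((cy, cx), r, shape=cortex.shape)
    tumor = np.zeros(cortex.shape, bool)
    tumor[rr, cc] = True
    tumor = ndi.binary_dilation(tumor, disk(2),
                                mask=cortex)  # hug irregular borders
    bump = _smooth_field(rng, cortex.shape, sigma=4) > 0.3
    tumor = _largest_component((tumor | (bump & ndi.binary_dilation(tumor, disk(4)))) & cortex)
    return tumor


# -------------------------------------------------------------------- scene
def generate_scene(config: SceneConfig) -> ScenePack:
    """Deterministically generate one craniotomy-like scene pack."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.hsi_size)
    sigs = {k: np.asarray(v, dtype=float)
            for k, v in config.class_signatures.items()}

    target = rng.uniform(0.12, 0.22)
    cortex = _cortex_blob(rng, shape, target)
    vessels = _draw_vessels(rng, cortex, config.n_vessels,
                            config.vessel_width_range)
    tumor = _draw_tumor(rng, cortex) if config.tumor_present \
        else np.zeros(shape, bool)
    dura_width = int(rng.integers(8, 14))
    dura = dilation(cortex, disk(dura_width)) & ~cortex

    truth = np.zeros(shape, np.uint8)
    truth[dura] = DURA
    truth[cortex] = HEALTHY
    truth[tumor & cortex] = TUMOR
    truth[vessels] = VESSEL

    # ---- HSI cube: per-pixel class signature * texture + truncated noise
    tex = 1.0 + 0.06 * _smooth_field(rng, shape, sigma=20)
    sig_map = np.empty((N_BANDS,) + shape, dtype=np.float32)
    for lbl, name in _LABEL_TO_NAME.items():
        m = truth == lbl
        if m.any():
            sig_map[:, m] = sigs[name][:, None]
    noise = rng.standard_normal((N_BANDS,) + shape) * config.noise_sd
    if config.noise_sd > 0:
        np.clip(noise, -3 * config.noise_sd, 3 * config.noise_sd, out=noise)
    cube_data = np.clip(sig_map * tex[None] + noise, 0.0, None).astype(np.float32)
    cube = HSICube(data=cube_data, calibrated=True)

    # ---- raw mosaic frame: radiance = reflectance * (white - dark) + dark
    white = np.full(cube_data.shape, 0.92, np.float32)
    dark = np.full(cube_data.shape, 0.04, np.float32)
    radiance = cube_data * (white - dark) + dark
    raw = mosaic(HSICube(data=radiance, calibrated=False))
    refs = ReferencePair(white=white, dark=dark)

    # ---- RGB: palette render at the HSI grid, nearest-upscaled, noisy
    rgb_small = np.zeros(shape + (3,), np.float32)
    for lbl, name in _LABEL_TO_NAME.items():
        rgb_small[truth == lbl] = _RGB_PALETTE[name]
    rgb_small *= tex[..., None]
    rgb = resize(rgb_small, tuple(config.rgb_size), order=0,
                 preserve_range=True, anti_aliasing=False)
    rgb_noise = rng.standard_normal(rgb.shape) * config.noise_sd
    if config.noise_sd > 0:
        np.clip(rgb_noise, -3 * config.noise_sd, 3 * config.noise_sd,
                out=rgb_noise)
    rgb = np.clip(rgb + rgb_noise, 0.0, 1.0).astype(np.float32)

    gt_sparse = generate_sparse_gt_from_truth(
        truth, config.sparse_fraction,
        seed=int(rng.integers(0, 2 ** 31 - 1)))

    return ScenePack(rgb=rgb, cube=cube, raw=raw, gt_sparse=gt_sparse,
                     cortex_gold=cortex, vessel_truth=vessels, truth=truth,
                     refs=refs, config=config)


# ------------------------------------------------------------------ sparse GT
def generate_sparse_gt_from_truth(truth: np.ndarray, fraction: float,
                                  seed: int) -> np.ndarray:
    """Subsample each class into a few compact blobs covering ~``fraction``
    of that class's area — the shape of semi-automatic threshold labeling."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sparse = np.zeros_like(truth)
    if fraction == 1.0:
        return truth.copy()
    for cls in (HEALTHY, TUMOR, VESSEL, DURA):
        region = truth == cls
        area = int(region.sum())
        if area == 0:
            continue
        target = max(1, int(round(fraction * area)))
        coords = np.argwhere(region)
        n_blobs = int(rng.integers(2, 5))
        seeds = np.zeros_like(region)
        picks = coords[rng.integers(len(coords), size=n_blobs)]
        seeds[picks[:, 0], picks[:, 1]] = True
        blob = seeds.copy()
        # grow compact blobs inside the class region until the target is met
        while blob.sum() < target:
            grown = ndi.binary_dilation(blob, structure=disk(2), mask=region)
            if grown.sum() == blob.sum():  # saturated: add another seed
                remaining = region & ~blob
                rem = np.argwhere(remaining)
                if len(rem) == 0:
                    break
                p = rem[rng.integers(len(rem))]
                grown[p[0], p[1]] = True
            blob = grown
        sparse[blob] = cls
    return sparse


def generate_sparse_gt(pack: ScenePack, fraction: float, seed: int) -> np.ndarray:
    return generate_sparse_gt_from_truth(pack.truth, fraction, seed)


# --------------------------------------------------------------- flawed probs
def generate_flawed_probs(pack: ScenePack, confusion: np.ndarray,
                          seed: int) -> np.ndarray:
    """4-class probability map (healthy, tumor, vessel, dura) from a flawed
    classifier whose per-class behavior follows a row-stochastic confusion
    matrix. Per pixel, the favored class is sampled from the confusion row of
    the true class and receives probability > 0.5, so the argmax is the
    sampled class by construction. Background-truth pixels use the dura row
    (the classifier has no background class).
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (4, 4) or np.any(confusion < 0) or \
            not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("confusion must be a 4x4 row-stochastic matrix")
    rng = np.random.default_rng(seed)
    truth = pack.truth
    h, w = truth.shape
    # map truth labels to classifier rows 0..3 (h, t, v, d); background -> dura
    row_of = np.array([DURA - 1, 0, 1, 2, 3])
    rows = row_of[truth]
    u = rng.random((h, w))
    cum = np.cumsum(confusion, axis=1)
    sampled = (u[..., None] < cum[rows]).argmax(axis=-1)

    top = 0.5 + 0.4 * rng.random((h, w))
    rest = rng.dirichlet(np.ones(3), size=(h, w)) * (1.0 - top)[..., None]
    probs = np.empty((h, w, 4))
    mask = np.arange(4)[None, None, :] == sampled[..., None]
    probs[mask] = top.ravel()
    probs[~mask] = rest.ravel()
    return probs
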