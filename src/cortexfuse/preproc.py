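"""Snapshot-mosaic HSI preprocessing.

A 5x5 spectral filter array tiles the sensor, so one raw frame holds 25
interleaved bands; demosaicking rearranges it into a band-stacked cube at 1/5
spatial resolution (2045x1085 sensor -> 409x217 cube, 25 bands covering
665-960 nm). Reflectance calibration uses white/dark reference cubes, followed
by a vendor-style spectral correction matrix that compensates filter
cross-talk. A pseudo-RGB rendering picks the visible-red band directly and
approximates green/blue through second-harmonic wavelength matching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.exposure import equalize_hist
from skimage.transform import resize

N_BANDS = 25
PATTERN = 5
HSI_SHAPE = (217, 409)
EPS_DIV = 1e-6

#: Synthetic stand-in for the camera's per-filter peak wavelengths in sensor
#: (filter) order. Only three entries are published for the real sensor
#: (712.4 nm at band 4, 913.7 nm at band 20, 940.9 nm at band 23, 1-based);
#: the remaining values are plausible constructions consistent with the
#: 665-960 nm sensor range. Sensor order is not wavelength-sorted.
PAPER_SENSOR_WAVELENGTHS = np.array([
    665.0, 681.5, 698.0, 712.4,
    726.0, 737.7, 749.4, 761.1, 772.9, 784.6, 796.3, 808.0, 819.7,
    831.4, 843.1, 854.9, 866.6, 878.3, 890.0, 913.7,
    897.0, 905.0, 940.9, 908.2, 895.4,
])


def default_wavelengths() -> np.ndarray:
    """Ascending synthetic wavelength grid over the sensor's 665-960 nm range."""
    return np.linspace(665.0, 960.0, N_BANDS)


@dataclass
class RawMosaicFrame:
    """One raw sensor frame with the repeating 5x5 filter pattern."""

    pixels: np.ndarray
    pattern_size: int = PATTERN

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("raw frame must be 2-D")
        h, w = self.pixels.shape
        p = self.pattern_size
        if h % p or w % p:
            raise ValueError(
                f"frame dims {h}x{w} not divisible by pattern size {p}")


@dataclass
class HSICube:
    """Band-major hyperspectral cube (bands, height, width)."""

    data: np.ndarray
    wavelengths_nm: np.ndarray = field(default_factory=default_wavelengths)
    calibrated: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (bands, height, width)")
        if self.data.shape[0] != self.wavelengths_nm.size:
            raise ValueError("band count must equal wavelength count")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass
class ReferencePair:
    """Matched white/dark reference cubes for reflectance calibration."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=np.float32)
        self.dark = np.asarray(self.dark, dtype=np.float32)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        frac = np.mean(self.white > self.dark)
        if frac < 0.99:
            raise ValueError(
                f"white exceeds dark on only {frac:.1%} of pixels (need >=99%)")


@dataclass
class SpectralCorrectionMatrix:
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.shape != (N_BANDS, N_BANDS):
            raise ValueError("spectral correction matrix must be 25x25")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("spectral correction matrix has non-finite entries")


@dataclass
class NormalizationStats:
    """Per-band min/max used by the min-max scaling of training pixels."""

    xmin: np.ndarray
    xmax: np.ndarray

    def __post_init__(self):
        self.xmin = np.asarray(self.xmin, dtype=np.float32)
        self.xmax = np.asarray(self.xmax, dtype=np.float32)
        if np.any(self.xmax < self.xmin):
            raise ValueError("xmax must be >= xmin per band")


# --------------------------------------------------------------------- mosaic
def demosaic(frame: RawMosaicFrame,
             wavelengths_nm: np.ndarray | None = None) -> HSICube:
    """Rearrange a raw mosaic frame into a 25-band cube.

    Band order is row-major within each 5x5 tile (top-left filter = band 0);
    band ``b`` at output (i, j) is input pixel (5i + b//5, 5j + b%5).
    """
    p = frame.pattern_size
    h, w = frame.pixels.shape
    ho, wo = h // p, w // p
    data = (frame.pixels.reshape(ho, p, wo, p)
            .transpose(1, 3, 0, 2)
            .reshape(p * p, ho, wo))
    wl = default_wavelengths() if wavelengths_nm is None else wavelengths_nm
    return HSICube(data=data, wavelengths_nm=wl, calibrated=False)


def mosaic(cube: HSICube) -> RawMosaicFrame:
    """Inverse of :func:`demosaic` (exact round trip)."""
    p = PATTERN
    b, ho, wo = cube.data.shape
    if b != p * p:
        raise ValueError("cube must have 25 bands")
    pixels = (cube.data.reshape(p, p, ho, wo)
              .transpose(2, 0, 3, 1)
              .reshape(ho * p, wo * p))
    return RawMosaicFrame(pixels=pixels)


# ---------------------------------------------------------------- calibration
def calibrate_reflectance(cube: HSICube, ref: ReferencePair) -> HSICube:
    """(cube - dark) / (white - dark), divisor clamped below by 1e-6."""
    if ref.white.shape != cube.data.shape:
        raise ValueError("reference shape does not match cube shape")
    denom = np.maximum(ref.white - ref.dark, EPS_DIV)
    out = (cube.data - ref.dark) / denom
    return HSICube(data=out, wavelengths_nm=cube.wavelengths_nm, calibrated=True)


def apply_spectral_correction(cube: HSICube,
                              scm: SpectralCorrectionMatrix) -> HSICube:
    """Replace every pixel's 25-vector by ``scm @ vector``.

    Applied after white/dark calibration, matching the vendor workflow.
    """
    if not cube.calibrated:
        raise ValueError("spectral correction requires a calibrated cube")
    out = np.einsum("bc,chw->bhw", scm.matrix, cube.data)
    return HSICube(data=out, wavelengths_nm=cube.wavelengths_nm, calibrated=True)


# -------------------------------------------------------------------- pseudo-RGB
def second_harmonic(wavelength_nm: float) -> float:
    """Half wavelength, rounded half-up to 0.1 nm (940.9 -> 470.5)."""
    return math.floor(wavelength_nm / 2.0 * 10.0 + 0.5) / 10.0


def _interval_distance(x: float, rng: tuple) -> float:
    lo, hi = rng
    if x < lo:
        return lo - x
    if x > hi:
        return x - hi
    return 0.0


def select_rgb_bands_by_harmonic(
    wavelengths_nm: np.ndarray,
    red_range: tuple = (700.0, 750.0),
    green_range: tuple = (495.0, 570.0),
    blue_range: tuple = (450.0, 495.0),
    max_harmonic_distance: float = 40.0,
) -> tuple:
    """Pick (red, green, blue) band indices (0-based).

    Red is the first band whose wavelength lies in the visible-red extension
    ``red_range``. Green and blue are the bands whose second harmonic falls
    nearest the stated green/blue ranges, ties broken toward the longer
    wavelength; a NIR camera has no harmonic strictly inside the green range,
    so a proximity tolerance ``max_harmonic_distance`` bounds how far outside
    the range the winning harmonic may fall.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    red_candidates = [i for i, w in enumerate(wl)
                      if red_range[0] <= w <= red_range[1]]
    if not red_candidates:
        raise ValueError(f"no band inside red range {red_range}")
    r_idx = red_candidates[0]

    harmonics = np.array([second_harmonic(w) for w in wl])

    def pick(rng, excluded):
        best, best_key = None, None
        for i, h in enumerate(harmonics):
            if i in excluded:
                continue
            key = (_interval_distance(h, rng), -wl[i])
            if best_key is None or key < best_key:
                best, best_key = i, key
        if best is None or best_key[0] > max_harmonic_distance:
            raise ValueError(
                f"no band with second harmonic within {max_harmonic_distance}"
                f" nm of range {rng}")
        return best

    g_idx = pick(green_range, {r_idx})
    b_idx = pick(blue_range, {r_idx, g_idx})
    return (r_idx, g_idx, b_idx)


def reconstruct_prgb(cube: HSICube, band_indices: tuple) -> np.ndarray:
    """Pseudo-RGB image from selected bands.

    Each channel is histogram-equalized independently, then a global linear
    contrast stretch maps the [1st, 99th] percentile of the stacked image to
    [0, 1]. Constant bands become flat 0.5 channels (with a warning).
    """
    if not cube.calibrated:
        raise ValueError("pseudo-RGB needs a calibrated cube")
    channels = []
    for idx in band_indices:
        band = cube.data[idx]
        if np.ptp(band) == 0:
            warnings.warn(f"band {idx} is constant; channel set to 0.5")
            channels.append(np.full(band.shape, 0.5, dtype=np.float64))
        else:
            channels.append(equalize_hist(band))
    img = np.stack(channels, axis=-1)
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi > lo:
        img = (img - lo) / (hi - lo)
    return np.clip(img, 0.0, 1.0)


# ------------------------------------------------------------- normalization
def fit_minmax(cubes) -> NormalizationStats:
    """Per-band min/max over the training+validation cubes."""
    cubes = list(cubes)
    if not cubes:
        raise ValueError("need at least one cube")
    xmin = np.min([c.data.min(axis=(1, 2)) for c in cubes], axis=0)
    xmax = np.max([c.data.max(axis=(1, 2)) for c in cubes], axis=0)
    return NormalizationStats(xmin=xmin, xmax=xmax)


def apply_minmax(cube: HSICube, stats: NormalizationStats) -> HSICube:
    """Per-band affine map (x - xmin) / (xmax - xmin); no clipping, so test
    pixels outside the fitted range may exceed [0, 1]. Constant bands map to 0."""
    span = stats.xmax - stats.xmin
    degenerate = span <= 0
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} constant band(s) mapped to 0")
    safe = np.where(degenerate, 1.0, span)
    out = (cube.data - stats.xmin[:, None, None]) / safe[:, None, None]
    out[degenerate] = 0.0
    return HSICube(data=out, wavelengths_nm=cube.wavelengths_nm,
                   calibrated=cube.calibrated)


# --------------------------------------------------------- spatial adaptation
def adapt_spatial(cube: HSICube, target: tuple = HSI_SHAPE):
    """Fit a foreign-sized cube into the fixed network grid.

    Rotate 90 degrees when the height exceeds the width, downscale (bilinear,
    aspect preserved) when the height still exceeds the target height, then
    zero-pad right/bottom. Returns the adapted cube and a recipe that
    :func:`restore_spatial` inverts.
    """
    th, tw = target
    data = cube.data
    h, w = data.shape[1:]
    rotated = h > w
    if rotated:
        data = np.rot90(data, k=1, axes=(1, 2))
        h, w = w, h
    scale = 1.0
    if h > th:
        scale = th / h
    if round(w * scale) > tw:
        scale = tw / w
        warnings.warn("width-limited scaling applied")
    if scale != 1.0:
        sh, sw = max(1, round(h * scale)), max(1, round(w * scale))
        data = np.stack([
            resize(band, (sh, sw), order=1, anti_aliasing=True,
                   preserve_range=True)
            for band in data]).astype(np.float32)
    sh, sw = data.shape[1:]
    if sh > th or sw > tw:
        raise ValueError(f"scaled shape {sh}x{sw} exceeds target {target}")
    padded = np.zeros((data.shape[0], th, tw), dtype=np.float32)
    padded[:, :sh, :sw] = data
    recipe = {
        "orig_shape": tuple(cube.data.shape[1:]),
        "rotated": rotated,
        "scaled_shape": (sh, sw),
        "target": (th, tw),
    }
    out = HSICube(data=padded, wavelengths_nm=cube.wavelengths_nm,
                  calibrated=cube.calibrated)
    return out, recipe


def restore_spatial(mask: np.ndarray, recipe: dict) -> np.ndarray:
    """Invert :func:`adapt_spatial` on a 2-D mask (crop, nearest upscale,
    rotate back). Pad-only recipes restore values bit-exactly."""
    sh, sw = recipe["scaled_shape"]
    out = np.asarray(mask)[:sh, :sw]
    oh, ow = recipe["orig_shape"]
    pre_rot = (ow, oh) if recipe["rotated"] else (oh, ow)
    if (sh, sw) != pre_rot:
        out = resize(out.astype(float), pre_rot, order=0,
                     preserve_range=True).astype(mask.dtype)
    if recipe["rotated"]:
        out = np.rot90(out, k=-1)
    return out
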