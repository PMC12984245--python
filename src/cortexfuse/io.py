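"""File formats: NPZ cubes, ENVI BSQ cubes, PNG masks and label maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .preproc import HSICube

#: palette for label PNGs: 0 unlabeled/unknown, 1 healthy/inner, 2 tumor/outer,
#: 3 vessel, 4 dura — colors follow the common rendering convention
LABEL_PALETTE = {
    0: (0, 0, 0),
    1: (0, 153, 51),
    2: (204, 0, 0),
    3: (0, 51, 204),
    4: (230, 150, 180),
}


# ---------------------------------------------------------------------- cubes
def save_cube_npz(path, cube: HSICube) -> None:
    np.savez(path, data=cube.data.astype(np.float32),
             wavelengths_nm=cube.wavelengths_nm,
             calibrated=np.array(cube.calibrated))


def load_cube_npz(path) -> HSICube:
    with np.load(path) as z:
        return HSICube(data=z["data"].astype(np.float32),
                       wavelengths_nm=z["wavelengths_nm"],
                       calibrated=bool(z["calibrated"]))


def save_cube_envi_pair(path_stem, cube: HSICube) -> tuple:
    """Write ``<stem>.hdr`` + ``<stem>.raw`` (BSQ, float32, band-major)."""
    stem = Path(path_stem)
    raw_path = stem.with_suffix(".raw")
    hdr_path = stem.with_suffix(".hdr")
    bands, lines, samples = cube.data.shape
    cube.data.astype("<f4").tofile(raw_path)
    wl = ", ".join(f"{w:.1f}" for w in cube.wavelengths_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        f"calibrated = {int(cube.calibrated)}\n"
        f"wavelength = {{ {wl} }}\n", encoding="utf-8")
    return hdr_path, raw_path


def load_cube_envi_pair(path_stem) -> HSICube:
    stem = Path(path_stem)
    fields = {}
    text = stem.with_suffix(".hdr").read_text(encoding="utf-8")
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    bands = int(fields["bands"])
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    data = np.fromfile(stem.with_suffix(".raw"), dtype="<f4")
    data = data.reshape(bands, lines, samples)
    wl = fields.get("wavelength", "").strip("{} ")
    wavelengths = np.array([float(v) for v in wl.split(",")]) if wl else None
    return HSICube(data=data, wavelengths_nm=wavelengths,
                   calibrated=bool(int(fields.get("calibrated", "1"))))


# ----------------------------------------------------------------------- PNGs
def save_rgb_png(path, image) -> None:
    """Save an (H, W, 3) float [0, 1] or uint8 image."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_rgb_png(path) -> np.ndarray:
    """Load a PNG as (H, W, 3) float32 in [0, 1]."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_mask_png(path, mask) -> None:
    Image.fromarray(np.asarray(mask, bool).astype(np.uint8) * 255).save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def save_label_png(path, labels) -> None:
    """Single-channel palette PNG whose pixel values are the class labels."""
    arr = np.asarray(labels, dtype=np.uint8)
    img = Image.fromarray(arr, mode="P")
    palette = np.zeros((256, 3), np.uint8)
    for value, color in LABEL_PALETTE.items():
        palette[value] = color
    img.putpalette(palette.ravel().tolist())
    img.save(path)


def load_label_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L"):
        raise ValueError("label PNGs must be single-channel")
    return np.asarray(img, dtype=np.uint8)


def save_prob_png(path, prob) -> None:
    """Probability mask in [0, 1] stored as 8-bit grayscale."""
    arr = (np.clip(np.asarray(prob, float), 0.0, 1.0) * 255.0 + 0.5)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def load_prob_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0
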