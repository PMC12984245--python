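"""Concave-hull regions of binary masks and point sets.

The shape losses and the inner/outer ground-truth adjustment both need the
filled region enclosed by a tight, possibly non-convex hull of a pixel set.
Hulls are computed with GEOS (``shapely.concave_hull``) on the boundary
pixels of the mask; point sets with fewer than 10 points fall back to the
convex hull.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from shapely import MultiPoint, concave_hull
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

#: Default hull tightness (0 = maximally concave, 1 = convex hull).
DEFAULT_RATIO = 0.3

_MAX_POINTS = 1500


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    er = ndi.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    pts = np.argwhere(mask & ~er)
    return pts


def _fill_polygon(poly, shape) -> np.ndarray:
    out = np.zeros(shape, bool)
    if poly.is_empty:
        return out
    geoms = poly.geoms if poly.geom_type.startswith("Multi") else [poly]
    for g in geoms:
        if g.geom_type != "Polygon":
            g = g.buffer(0.7)
            if g.geom_type != "Polygon":
                continue
        rr, cc = np.array(g.exterior.coords).T
        r, c = draw_polygon(rr, cc, shape=shape)
        out[r, c] = True
    return out


def hull_region_of_points(points: np.ndarray, shape: tuple,
                          ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """Filled concave-hull region of (row, col) points as a boolean mask."""
    points = np.asarray(points)
    if len(points) == 0:
        return np.zeros(shape, bool)
    if len(points) <= 2:
        out = np.zeros(shape, bool)
        out[points[:, 0], points[:, 1]] = True
        return out
    if len(points) > _MAX_POINTS:
        idx = np.linspace(0, len(points) - 1, _MAX_POINTS).astype(int)
        points = points[idx]
    mp = MultiPoint([(float(r), float(c)) for r, c in points])
    if len(points) < 10:
        poly = mp.convex_hull
        if not isinstance(poly, Polygon):
            poly = poly.buffer(0.7)
    else:
        poly = concave_hull(mp, ratio=ratio)
        if not isinstance(poly, Polygon):
            poly = mp.convex_hull.buffer(0.0)
    region = _fill_polygon(poly, shape)
    region[points[:, 0], points[:, 1]] = True
    return region


def hull_region(mask: np.ndarray, ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """Filled concave-hull region of a binary mask (computed on its boundary)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, bool)
    pts = _boundary_points(mask)
    region = hull_region_of_points(pts, mask.shape, ratio=ratio)
    return region | mask
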