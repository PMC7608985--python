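"""Rotation-invariant uniform local binary patterns (LBP).

For a scale ``(R, P)`` the LBP code of a pixel compares ``P`` neighbours,
evenly spaced on a circle of radius ``R``, against the centre value (bit set
when neighbour >= centre; non-integer neighbour positions are bilinearly
interpolated).  A pattern is *uniform* when its circular bit string has at
most two 0/1 transitions; the rotation-invariant uniform mapping assigns
uniform patterns their number of set bits (0..P) and all the rest a single
non-uniform label, giving ``P + 2`` histogram bins per scale.

The texture descriptor of a cyst region is the concatenation of the per-scale
histograms accumulated over the region's interior pixels, each histogram
normalised to sum 1, so the feature is independent of the region size.  With
the default scales (1,8), (2,16), (3,24) the descriptor has
(8+2)+(16+2)+(24+2) = 54 features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contours import polygon_mask
from .raster import CystContour, as_grey_image

__all__ = ["LbpConfig", "RegionUnsupportedError", "lbp_codes", "compute_lbp_features"]

DEFAULT_SCALES = ((1, 8), (2, 16), (3, 24))


class RegionUnsupportedError(ValueError):
    """Raised when a region has no pixel with a full LBP neighbourhood."""


@dataclass(frozen=True)
class LbpConfig:
    """LBP scales as (radius R, number of neighbours P) pairs."""

    scales: tuple = DEFAULT_SCALES

    def __post_init__(self):
        scales = tuple((int(r), int(p)) for r, p in self.scales)
        if not scales:
            raise ValueError("at least one (R, P) scale is required")
        for r, p in scales:
            if r < 1 or p < 4:
                raise ValueError("each scale needs R >= 1 and P >= 4")
        object.__setattr__(self, "scales", scales)

    @property
    def n_features(self) -> int:
        return sum(p + 2 for _, p in self.scales)


def neighbor_offsets(radius: int, n_points: int) -> list[tuple[float, float]]:
    """(dy, dx) sampling offsets on the circle; near-integer values snapped."""
    offsets = []
    for k in range(n_points):
        angle = 2.0 * math.pi * k / n_points
        dy = -radius * math.sin(angle)
        dx = radius * math.cos(angle)
        if abs(dy - round(dy)) < 1e-8:
            dy = float(round(dy))
        if abs(dx - round(dx)) < 1e-8:
            dx = float(round(dx))
        offsets.append((dy, dx))
    return offsets


def _bilinear(img: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Bilinear sample at float coordinates (must lie inside the image)."""
    y0 = np.floor(y).astype(np.int64)
    x0 = np.floor(x).astype(np.int64)
    y1 = np.minimum(y0 + 1, img.shape[0] - 1)
    x1 = np.minimum(x0 + 1, img.shape[1] - 1)
    wy = y - y0
    wx = x - x0
    top = (1.0 - wx) * img[y0, x0] + wx * img[y0, x1]
    bot = (1.0 - wx) * img[y1, x0] + wx * img[y1, x1]
    return (1.0 - wy) * top + wy * bot


def lbp_codes(grey: np.ndarray, radius: int, n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-invariant uniform LBP code of every pixel at one scale.

    Returns ``(codes, valid)`` where ``codes`` holds values ``0..P+1``
    (``P+1`` = non-uniform) and ``valid`` marks pixels whose whole circular
    neighbourhood lies inside the image.
    """
    grey = as_grey_image(grey)
    g = grey.astype(np.float64)
    h, w = g.shape
    valid = np.zeros((h, w), dtype=bool)
    if h > 2 * radius and w > 2 * radius:
        valid[radius : h - radius, radius : w - radius] = True
    codes = np.full((h, w), n_points + 1, dtype=np.int64)
    if not valid.any():
        return codes, valid

    yy, xx = np.nonzero(valid)
    center = g[yy, xx]
    bits = np.empty((n_points, yy.size), dtype=bool)
    for k, (dy, dx) in enumerate(neighbor_offsets(radius, n_points)):
        sample = _bilinear(g, yy + dy, xx + dx)
        bits[k] = sample >= center
    transitions = np.sum(bits != np.roll(bits, -1, axis=0), axis=0)
    ones = bits.sum(axis=0)
    vals = np.where(transitions <= 2, ones, n_points + 1)
    codes[yy, xx] = vals
    return codes, valid


def compute_lbp_features(
    grey: np.ndarray,
    region: CystContour | np.ndarray,
    config: LbpConfig = LbpConfig(),
) -> np.ndarray:
    """Concatenated normalised LBP histograms over a cyst region.

    ``region`` is a :class:`~cystquant.raster.CystContour` (its filled polygon
    is used) or a boolean mask.  For each scale the histogram is accumulated
    over the region pixels whose full neighbourhood at that radius lies inside
    the image and normalised to sum 1.

    Raises
    ------
    RegionUnsupportedError
        If, at any scale, no region pixel has a complete neighbourhood.
    """
    grey = as_grey_image(grey)
    if isinstance(region, CystContour):
        mask = polygon_mask(region.polygon, grey.shape)
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != grey.shape:
            raise ValueError("region mask shape must match the image")
    if not mask.any():
        raise RegionUnsupportedError("region is empty")
    # restrict to the region's bounding box padded by the largest radius;
    # every neighbourhood sample of a region pixel lies inside the crop, so
    # the features are identical to a whole-image computation
    r_max = max(r for r, _ in config.scales)
    ys, xs = np.nonzero(mask)
    y0 = max(int(ys.min()) - r_max, 0)
    y1 = min(int(ys.max()) + r_max + 1, grey.shape[0])
    x0 = max(int(xs.min()) - r_max, 0)
    x1 = min(int(xs.max()) + r_max + 1, grey.shape[1])
    # an inner crop border marks pixels near it invalid exactly when a full
    # image border would not; only clip-free sides need that margin kept
    grey = grey[y0:y1, x0:x1]
    mask = mask[y0:y1, x0:x1]
    blocks = []
    for radius, n_points in config.scales:
        codes, valid = lbp_codes(grey, radius, n_points)
        sel = mask & valid
        if not sel.any():
            raise RegionUnsupportedError(
                f"region has no interior pixel with a full (R={radius}, P={n_points}) neighbourhood"
            )
        hist = np.bincount(codes[sel], minlength=n_points + 2).astype(np.float64)
        blocks.append(hist / hist.sum())
    return np.concatenate(blocks)
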