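"""Raster conventions and core geometric types.

Images are plain numpy arrays, following scikit-image conventions:

* RGB image  -- ``uint8`` array of shape ``(H, W, 3)``, channel order R, G, B.
* grey image -- ``uint8`` array of shape ``(H, W)``.
* binary mask -- ``bool`` array of shape ``(H, W)``; ``True`` marks
  cyst-candidate foreground.

Coordinates are 0-based with ``x`` = column and ``y`` = row.  Polygons are
``(N, 2)`` integer arrays of ``(x, y)`` vertices describing a closed chain
(the edge from the last vertex back to the first is implicit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "as_rgb_image",
    "as_grey_image",
    "as_binary_mask",
    "rgb_to_grey",
    "Calibration",
    "DiameterRange",
    "CystContour",
    "CystSet",
    "SegmentationTrace",
]


def as_rgb_image(image) -> np.ndarray:
    """Validate and return an RGB image array (uint8, H x W x 3).

    Greyscale input (2-D) is promoted to RGB by channel replication.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("RGB image must be 8-bit per channel")
    return arr


def as_grey_image(image) -> np.ndarray:
    """Validate and return a grey image array (uint8, H x W)."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) grey array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("grey image must be 8-bit")
    return arr


def as_binary_mask(mask, shape=None) -> np.ndarray:
    """Validate and return a boolean mask (H x W)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) mask, got shape {arr.shape}")
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match expected {tuple(shape)}")
    return arr


def rgb_to_grey(image) -> np.ndarray:
    """Standard luminance conversion 0.299 R + 0.587 G + 0.114 B, rounded."""
    rgb = as_rgb_image(image).astype(np.float64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class Calibration:
    """Spatial resolution of the digitised image, in micrometers per pixel."""

    micrometers_per_pixel: float = 1.0

    def __post_init__(self):
        if not self.micrometers_per_pixel > 0:
            raise ValueError("calibration must be a positive number of um/px")

    def um_to_px(self, micrometers: float) -> float:
        return micrometers / self.micrometers_per_pixel

    def px_to_um(self, pixels: float) -> float:
        return pixels * self.micrometers_per_pixel


@dataclass(frozen=True)
class DiameterRange:
    """Inclusive range [dmin, dmax] of cyst diameters, stored in pixels."""

    dmin: float
    dmax: float

    def __post_init__(self):
        if not (0 < self.dmin < self.dmax):
            raise ValueError("diameter range requires 0 < dmin < dmax")

    @classmethod
    def from_micrometers(cls, dmin_um: float, dmax_um: float, calibration: Calibration) -> "DiameterRange":
        return cls(calibration.um_to_px(dmin_um), calibration.um_to_px(dmax_um))

    def contains(self, diameter_px: float) -> bool:
        return self.dmin <= diameter_px <= self.dmax


VALID_ORIGINS = ("auto", "manual", "derived")


@dataclass(frozen=True)
class CystContour:
    """A recognised or drawn cyst: closed pixel polygon plus filled area.

    ``polygon`` is an ``(N, 2)`` int array of ``(x, y)`` vertices.  For
    automatically traced cysts the vertices are the ordered outer-border
    pixels of the connected component; for manual cysts they are the drawn
    vertices.  ``area_px`` counts the pixels of the filled region (holes
    included), which is exactly the region reconstructed by
    :func:`cystquant.contours.polygon_mask`.
    """

    id: int
    polygon: np.ndarray
    origin: str
    area_px: int

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=np.int64)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 1:
            raise ValueError("polygon must be an (N, 2) array of vertices")
        object.__setattr__(self, "polygon", poly)
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"origin must be one of {VALID_ORIGINS}")
        if not self.area_px > 0:
            raise ValueError("cyst area must be positive")

    @property
    def equiv_diameter_px(self) -> float:
        """Equivalent-circle diameter 2*sqrt(A/pi)."""
        return 2.0 * math.sqrt(self.area_px / math.pi)


@dataclass(frozen=True)
class CystSet:
    """All cysts recognised/edited on one image."""

    width: int
    height: int
    organ: str
    calibration: Calibration = field(default_factory=Calibration)
    cysts: tuple = ()

    def __post_init__(self):
        if self.organ not in ("kidney", "liver"):
            raise ValueError("organ must be 'kidney' or 'liver'")
        cysts = tuple(self.cysts)
        ids = [c.id for c in cysts]
        if len(ids) != len(set(ids)):
            raise ValueError("cyst ids must be unique")
        for c in cysts:
            x, y = c.polygon[:, 0], c.polygon[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= self.width or y.max() >= self.height:
                raise ValueError(f"cyst {c.id} polygon lies outside the image bounds")
        object.__setattr__(self, "cysts", cysts)

    def __len__(self):
        return len(self.cysts)

    def __iter__(self):
        return iter(self.cysts)

    def ids(self) -> set:
        return {c.id for c in self.cysts}

    def get(self, cyst_id: int) -> CystContour:
        for c in self.cysts:
            if c.id == cyst_id:
                return c
        raise KeyError(f"no cyst with id {cyst_id}")

    def with_cysts(self, cysts) -> "CystSet":
        return replace(self, cysts=tuple(cysts))

    def shape(self):
        return (self.height, self.width)


@dataclass(frozen=True)
class SegmentationTrace:
    """Intermediate rasters of the recognition pipeline.

    ``green`` is the extracted green channel, ``mean_level`` its (real-valued)
    global mean, ``thresholded`` the mean-threshold mask, ``kmeans_refined``
    the k-means-refined mask and ``opened`` the morphologically opened mask.
    """

    green: np.ndarray
    mean_level: float
    thresholded: np.ndarray
    kmeans_refined: np.ndarray
    opened: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.mean_level <= 255.0):
            raise ValueError("mean grey level must lie in [0, 255]")
        shape = self.green.shape
        for name in ("thresholded", "kmeans_refined", "opened"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"trace raster '{name}' does not match green-channel shape")
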