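"""Automatic cyst recognition.

The recognition pipeline turns an RGB histology image into a set of cyst
contours in six deterministic steps:

1. extract the green channel ``IG`` (cyst lumens are bright in H&E, and the
   green channel carries the strongest lumen/tissue contrast);
2. compute the global mean grey level ``mu_G`` of ``IG``;
3. threshold ``IG`` at ``mu_G`` (foreground = strictly brighter), giving the
   binary image ``IB``;
4. refine ``IB`` with two-cluster k-means on the pixel intensities,
   initialised from the threshold labels, giving ``Ik``;
5. remove small noise regions with a morphological opening (disk element:
   3 px diameter for liver, ~``dmin`` diameter for kidney), giving ``Io``;
6. extract the outer contour of every 8-connected component of ``Io`` and
   keep those whose equivalent diameter falls in ``[dmin, dmax]``.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk, opening

from .contours import contours_from_mask
from .raster import (
    Calibration,
    CystContour,
    CystSet,
    DiameterRange,
    SegmentationTrace,
    as_binary_mask,
    as_grey_image,
    as_rgb_image,
)

__all__ = [
    "extract_green",
    "global_mean_threshold",
    "kmeans_refine",
    "opening_footprint",
    "denoise_open",
    "extract_contours",
    "filter_by_diameter",
    "recognize_cysts",
]


def extract_green(image: np.ndarray) -> np.ndarray:
    """Green channel of an RGB image (step 1)."""
    return as_rgb_image(image)[..., 1].copy()


def global_mean_threshold(grey: np.ndarray) -> tuple[np.ndarray, float]:
    """Threshold at the global mean grey level (steps 2-3).

    Returns ``(mask, mean_level)`` where ``mean_level`` is the real-valued
    arithmetic mean of all pixels and foreground means *strictly* brighter
    than the mean (so a constant image yields an empty mask).
    """
    grey = as_grey_image(grey)
    mean_level = float(grey.mean(dtype=np.float64))
    return grey > mean_level, mean_level


def kmeans_refine(
    grey: np.ndarray,
    init: np.ndarray,
    tol: float = 0.5,
    max_iter: int = 10,
) -> np.ndarray:
    """Two-cluster 1-D Lloyd's k-means on intensities, seeded by a mask (step 4).

    The initial cluster assignment is the mask itself.  Lloyd iterations
    alternate centroid means and nearest-centroid reassignment until both
    centroids move less than ``tol`` grey levels or ``max_iter`` iterations.
    Foreground of the result is the cluster with the higher final centroid.
    A degenerate initialisation (all pixels one label) is returned unchanged.
    """
    grey = as_grey_image(grey)
    labels = as_binary_mask(init, shape=grey.shape).copy()
    if labels.all() or not labels.any():
        return labels
    g = grey.astype(np.float64)
    c_fg = g[labels].mean()
    c_bg = g[~labels].mean()
    for _ in range(max_iter):
        # assign to the nearest centroid; ties go to the brighter cluster
        new_labels = np.abs(g - c_fg) <= np.abs(g - c_bg)
        if c_fg < c_bg:
            new_labels = ~new_labels
        if new_labels.all() or not new_labels.any():
            break  # a cluster emptied; keep the previous stable assignment
        labels = new_labels
        n_fg = g[labels].mean()
        n_bg = g[~labels].mean()
        moved = max(abs(n_fg - c_fg), abs(n_bg - c_bg))
        c_fg, c_bg = n_fg, n_bg
        if moved < tol:
            break
    if c_fg >= c_bg:
        return labels
    return ~labels


def opening_footprint(organ: str, diameters: DiameterRange | None = None) -> np.ndarray:
    """Disk structuring element of the denoising opening.

    Liver: constant 3-px diameter.  Kidney: odd diameter nearest
    ``max(3, round(dmin))`` so objects smaller than the smallest cyst of
    interest are removed.
    """
    if organ == "liver":
        return disk(1)
    if organ == "kidney":
        if diameters is None:
            raise ValueError("kidney opening requires the diameter range")
        d = max(3, int(round(diameters.dmin)))
        return disk(max(1, d // 2))
    raise ValueError("organ must be 'kidney' or 'liver'")


def denoise_open(
    mask: np.ndarray, organ: str, diameters: DiameterRange | None = None
) -> np.ndarray:
    """Morphological opening that removes sub-cyst noise regions (step 5)."""
    mask = as_binary_mask(mask)
    return opening(mask, opening_footprint(organ, diameters))


def extract_contours(mask: np.ndarray) -> list[CystContour]:
    """Outer-border contour of every 8-connected component (step 6)."""
    return contours_from_mask(as_binary_mask(mask))


def filter_by_diameter(
    cysts: list[CystContour], diameters: DiameterRange
) -> list[CystContour]:
    """Keep cysts whose equivalent diameter lies in [dmin, dmax] (inclusive)."""
    return [c for c in cysts if diameters.contains(c.equiv_diameter_px)]


def recognize_cysts(
    image: np.ndarray,
    organ: str,
    diameters: DiameterRange,
    calibration: Calibration | None = None,
) -> tuple[CystSet, SegmentationTrace]:
    """Run the full six-step recognition pipeline on an RGB image."""
    rgb = as_rgb_image(image)
    calibration = calibration or Calibration()
    green = extract_green(rgb)
    thresholded, mean_level = global_mean_threshold(green)
    refined = kmeans_refine(green, thresholded)
    opened = denoise_open(refined, organ, diameters)
    cysts = filter_by_diameter(extract_contours(opened), diameters)
    trace = SegmentationTrace(
        green=green,
        mean_level=mean_level,
        thresholded=thresholded,
        kmeans_refined=refined,
        opened=opened,
    )
    cyst_set = CystSet(
        width=rgb.shape[1],
        height=rgb.shape[0],
        organ=organ,
        calibration=calibration,
        cysts=tuple(cysts),
    )
    return cyst_set, trace
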