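"""Border following and polygon rasterisation.

The pipeline treats a cyst as an 8-connected foreground component.  Its
contour is the ordered chain of outer-border pixels, traced with
Moore-neighbour border following (the classical outer-border variant of the
Suzuki-Abe family); holes are ignored, so the region a contour describes is
the filled component.

Rasterisation is the exact inverse: the closed vertex chain is drawn with
Bresenham lines and the enclosed background filled (4-connected hole fill).
For chains produced by the tracer this reconstructs the filled component
pixel-for-pixel, so ``area_px`` derived from a polygon always equals the
mask-derived area.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import line as _line
from skimage.measure import label as _label

from .raster import CystContour, as_binary_mask

__all__ = [
    "trace_outer_border",
    "polygon_mask",
    "rasterize_polyline",
    "contours_from_mask",
    "validate_simple_polygon",
]

# clockwise Moore neighbourhood in (dy, dx), starting east
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_outer_border(mask: np.ndarray) -> np.ndarray:
    """Trace the outer border of a single foreground component.

    Returns the ordered ``(N, 2)`` array of ``(x, y)`` border pixels,
    clockwise in image coordinates (counter-clockwise in conventional
    y-up coordinates).  The component is assumed 8-connected; holes are
    irrelevant because only the outer border is followed.
    """
    mask = as_binary_mask(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot trace an empty mask")
    # topmost-leftmost foreground pixel; its west neighbour is background
    start = (int(ys[0]), int(xs[0]))
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))

    h, w = mask.shape

    def fg(p):
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    def step(cur, backtrack_dir):
        # scan clockwise starting just after the backtrack direction
        for k in range(1, 9):
            d = (backtrack_dir + k) % 8
            nb = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(nb):
                return d, nb
        return None

    # initial backtrack: west of start (background by construction)
    first = step(start, 4)
    if first is None:  # isolated pixel
        return np.array([(start[1], start[0])], dtype=np.int64)

    # Follow the deterministic (pixel, backtrack) walk until the state right
    # after the first move repeats; the pixels in between are one full period
    # of the outer border (robust even when the border crosses a pixel twice).
    d0, p1 = first
    state0 = (p1, (d0 + 4) % 8)
    chain = [start, p1]
    cur, backtrack_dir = state0
    max_steps = 8 * (int(mask.sum()) + 1) * 4
    for _ in range(max_steps):
        d, nxt = step(cur, backtrack_dir)  # a border walk never dead-ends here
        cur, backtrack_dir = nxt, (d + 4) % 8
        if (cur, backtrack_dir) == state0:
            break
        chain.append(nxt)
    else:
        raise RuntimeError("border following failed to close")
    period = chain[1:]  # one full cycle of border pixels, starting at p1
    # rotate so the chain starts at the scan-order start pixel
    i0 = period.index(start)
    period = period[i0:] + period[:i0]
    return np.array([(x, y) for (y, x) in period], dtype=np.int64)


def rasterize_polyline(vertices: np.ndarray, shape, closed: bool = False) -> np.ndarray:
    """Draw a 1-px polyline (Bresenham) onto a boolean raster."""
    verts = np.asarray(vertices, dtype=np.int64)
    out = np.zeros(shape, dtype=bool)
    n = len(verts)
    if n == 1:
        x, y = verts[0]
        out[y, x] = True
        return out
    last = n if closed else n - 1
    for i in range(last):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        rr, cc = _line(int(y0), int(x0), int(y1), int(x1))
        out[rr, cc] = True
    return out


def polygon_mask(polygon: np.ndarray, shape) -> np.ndarray:
    """Filled region of a closed vertex chain: boundary plus enclosed pixels."""
    boundary = rasterize_polyline(polygon, shape, closed=True)
    return ndimage.binary_fill_holes(boundary)


def contours_from_mask(mask: np.ndarray, start_id: int = 1) -> list[CystContour]:
    """One outer-border contour per 8-connected foreground component.

    Components are numbered in raster-scan order.  ``area_px`` is the pixel
    count of the filled component (holes counted as cyst area).
    """
    mask = as_binary_mask(mask)
    labels, n = _label(mask, connectivity=2, return_num=True)
    contours = []
    objects = ndimage.find_objects(labels)
    for i in range(1, n + 1):
        sl = objects[i - 1]
        comp = labels[sl] == i
        filled = ndimage.binary_fill_holes(comp)
        chain_local = trace_outer_border(filled)
        chain = chain_local + np.array([sl[1].start, sl[0].start], dtype=np.int64)
        contours.append(
            CystContour(
                id=start_id + i - 1,
                polygon=chain,
                origin="auto",
                area_px=int(filled.sum()),
            )
        )
    return contours


def validate_simple_polygon(polygon: np.ndarray, shape) -> np.ndarray:
    """Check a user-drawn polygon: >= 3 vertices, simple, inside the image."""
    verts = np.asarray(polygon, dtype=np.int64)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("polygon must be an (N, 2) array of (x, y) vertices")
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    h, w = shape
    if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or verts[:, 0].max() >= w or verts[:, 1].max() >= h:
        raise ValueError("polygon lies outside the image bounds")
    poly = _ShapelyPolygon(verts)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("polygon must be simple (non-self-intersecting) with positive area")
    return verts
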