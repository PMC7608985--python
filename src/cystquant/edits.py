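"""Supervised post-processing of an automatically recognised cyst set.

Headless equivalents of the review tools a pathologist uses after automatic
recognition: delete, draw, complete, split, merge, remove cysts inside a
manually drawn container, and automatically add very small cysts vetted by
the texture classifier.  Every operation appends exactly one
:class:`EditRecord` to an :class:`EditLog`; a record stores the resulting
created polygons, so replaying a log from the initial set reproduces the
final set exactly without needing the image or classifier.  Undo/redo move a
cursor over the log and replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _label
from skimage.morphology import disk

from .contours import (
    polygon_mask,
    rasterize_polyline,
    trace_outer_border,
    validate_simple_polygon,
)
from .raster import CystContour, CystSet, DiameterRange, as_rgb_image

__all__ = [
    "EditRecord",
    "EditLog",
    "SupervisionSession",
    "replay",
    "EDIT_KINDS",
]

EDIT_KINDS = ("delete", "add", "complete", "split", "merge", "remove_inner", "add_smaller")


@dataclass(frozen=True)
class EditRecord:
    """One supervision action: targets retired, cysts created, user payload."""

    kind: str
    target_ids: tuple = ()
    created: tuple = ()  # tuple of (id, origin, polygon array, area_px)
    payload: tuple = ()  # the user-drawn polygon/polyline vertices, if any
    index: int = 0

    def __post_init__(self):
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        object.__setattr__(self, "target_ids", tuple(int(i) for i in self.target_ids))

    @property
    def created_ids(self) -> tuple:
        return tuple(c[0] for c in self.created)


@dataclass
class EditLog:
    """Ordered, replayable record of supervision operations."""

    records: list = field(default_factory=list)
    cursor: int = 0  # records[:cursor] are active; the rest are undone

    def active(self) -> list:
        return self.records[: self.cursor]

    def append(self, record: EditRecord) -> None:
        del self.records[self.cursor :]  # a fresh edit discards the redo tail
        self.records.append(record)
        self.cursor += 1

    def __len__(self):
        return len(self.records)


def _apply(cyst_set: CystSet, record: EditRecord) -> CystSet:
    """Apply one record: retire targets, append created cysts."""
    remaining = [c for c in cyst_set if c.id not in record.target_ids]
    for cid, origin, polygon, area in record.created:
        remaining.append(CystContour(id=cid, polygon=np.asarray(polygon), origin=origin, area_px=int(area)))
    return cyst_set.with_cysts(remaining)


def replay(initial: CystSet, log: EditLog) -> CystSet:
    """Final cyst set as a pure function of (initial set, active log records)."""
    current = initial
    for record in log.active():
        missing = set(record.target_ids) - current.ids()
        if missing:
            raise ValueError(f"log inconsistent with set: unknown target ids {sorted(missing)}")
        current = _apply(current, record)
    return current


class SupervisionSession:
    """Mutable editing session over an initial (usually automatic) cyst set."""

    def __init__(self, initial: CystSet, merge_gap_tolerance: int = 8):
        self.initial = initial
        self.log = EditLog()
        self.merge_gap_tolerance = int(merge_gap_tolerance)
        self._id_counter = max((c.id for c in initial), default=0)

    # -- bookkeeping ---------------------------------------------------

    @property
    def current(self) -> CystSet:
        return replay(self.initial, self.log)

    def _fresh_id(self) -> int:
        self._id_counter += 1
        return self._id_counter

    def _commit(self, record: EditRecord) -> CystSet:
        _apply(self.current, record)  # validates targets before committing
        self.log.append(record)
        return self.current

    def _record(self, kind, target_ids=(), created=(), payload=()) -> EditRecord:
        return EditRecord(
            kind=kind,
            target_ids=target_ids,
            created=created,
            payload=payload,
            index=len(self.log.records),
        )

    def _made(self, polygon: np.ndarray, origin: str) -> tuple:
        shape = (self.initial.height, self.initial.width)
        area = int(polygon_mask(polygon, shape).sum())
        if area <= 0:
            raise ValueError("polygon encloses no pixels")
        return (self._fresh_id(), origin, np.asarray(polygon, dtype=np.int64), area)

    # -- the editing tools ---------------------------------------------

    def delete_cyst(self, cyst_id: int) -> CystSet:
        self.current.get(cyst_id)  # raises KeyError for unknown ids
        return self._commit(self._record("delete", target_ids=(cyst_id,)))

    def add_cyst(self, polygon) -> CystSet:
        verts = validate_simple_polygon(polygon, (self.initial.height, self.initial.width))
        made = self._made(verts, "manual")
        return self._commit(self._record("add", created=(made,), payload=tuple(map(tuple, verts))))

    def complete_cyst(self, cyst_id: int, polygon) -> CystSet:
        """Replace a mistraced outline; the old detection is retired (FP+FN)."""
        self.current.get(cyst_id)
        verts = validate_simple_polygon(polygon, (self.initial.height, self.initial.width))
        made = self._made(verts, "derived")
        return self._commit(
            self._record("complete", target_ids=(cyst_id,), created=(made,), payload=tuple(map(tuple, verts)))
        )

    def split_cyst(self, cyst_id: int, polyline) -> CystSet:
        """Cut one wrongly fused cyst in two along a drawn polyline."""
        target = self.current.get(cyst_id)
        verts = np.asarray(polyline, dtype=np.int64)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 2:
            raise ValueError("split polyline needs at least 2 (x, y) vertices")
        shape = (self.initial.height, self.initial.width)
        region = polygon_mask(target.polygon, shape)
        cut = rasterize_polyline(verts, shape, closed=False)
        remainder = region & ~cut
        labels, n = _label(remainder, connectivity=2, return_num=True)
        if n != 2:
            raise ValueError(f"split line must divide the cyst into exactly 2 parts (got {n})")
        created = []
        for i in (1, 2):
            part = ndimage.binary_fill_holes(labels == i)
            created.append((self._fresh_id(), "derived", trace_outer_border(part), int(part.sum())))
        return self._commit(
            self._record("split", target_ids=(cyst_id,), created=tuple(created), payload=tuple(map(tuple, verts)))
        )

    def merge_cysts(self, cyst_ids) -> CystSet:
        """Fuse fragments of one over-segmented cyst into a single contour."""
        ids = tuple(int(i) for i in cyst_ids)
        if len(ids) < 2:
            raise ValueError("merge requires at least 2 cyst ids")
        current = self.current
        parts = [current.get(i) for i in ids]
        shape = (self.initial.height, self.initial.width)
        union = np.zeros(shape, dtype=bool)
        for part in parts:
            union |= polygon_mask(part.polygon, shape)
        # close with a disk whose radius equals the gap tolerance so nearby
        # fragments bridge; pad so closing is not clipped at the image border
        r = self.merge_gap_tolerance
        padded = np.pad(union, r)
        closed = ndimage.binary_closing(padded, structure=disk(r))[r:-r, r:-r]
        closed |= union
        labels, n = _label(closed, connectivity=2, return_num=True)
        if n != 1:
            raise ValueError("cysts are too far apart to merge (result is not one region)")
        merged = ndimage.binary_fill_holes(closed)
        made = (self._fresh_id(), "derived", trace_outer_border(merged), int(merged.sum()))
        return self._commit(self._record("merge", target_ids=ids, created=(made,)))

    def remove_inner_cysts(self, container_id: int) -> CystSet:
        """Delete automatic cysts falling entirely inside a manual container."""
        current = self.current
        container = current.get(container_id)
        if container.origin != "manual":
            raise ValueError("the container cyst must be manually drawn")
        shape = (self.initial.height, self.initial.width)
        container_mask = polygon_mask(container.polygon, shape)
        inner = []
        for cyst in current:
            if cyst.id == container_id or cyst.origin != "auto":
                continue
            mask = polygon_mask(cyst.polygon, shape)
            if not (mask & ~container_mask).any():
                inner.append(cyst.id)
        return self._commit(self._record("remove_inner", target_ids=tuple(inner)))

    def add_smaller_cysts(
        self,
        image: np.ndarray,
        model,
        small_range: DiameterRange,
        lbp_grey: np.ndarray | None = None,
    ) -> CystSet:
        """Recover very small cysts the size filter discarded.

        Re-runs the recognition pipeline with the fine (3-px, liver-style)
        opening, keeps sub-``dmin`` candidates that do not overlap existing
        cysts, and appends those the texture classifier accepts as true
        cysts.
        """
        from .classifier import TrainedClassifier, classify_candidates
        from .raster import rgb_to_grey
        from .segmentation import (
            extract_contours,
            extract_green,
            filter_by_diameter,
            global_mean_threshold,
            kmeans_refine,
            denoise_open,
        )

        if not isinstance(model, TrainedClassifier):
            raise TypeError("add_smaller_cysts requires a trained classifier")
        rgb = as_rgb_image(image)
        if rgb.shape[:2] != (self.initial.height, self.initial.width):
            raise ValueError("image shape does not match the annotated set")
        green = extract_green(rgb)
        thresholded, _ = global_mean_threshold(green)
        refined = kmeans_refine(green, thresholded)
        opened = denoise_open(refined, "liver")  # fine 3-px opening regardless of organ
        candidates = filter_by_diameter(extract_contours(opened), small_range)

        shape = (self.initial.height, self.initial.width)
        existing = np.zeros(shape, dtype=bool)
        for cyst in self.current:
            existing |= polygon_mask(cyst.polygon, shape)
        fresh = [c for c in candidates if not (polygon_mask(c.polygon, shape) & existing).any()]

        cand_set = self.current.with_cysts(
            [CystContour(id=i + 1, polygon=c.polygon, origin="auto", area_px=c.area_px) for i, c in enumerate(fresh)]
        )
        grey = lbp_grey if lbp_grey is not None else rgb_to_grey(rgb)
        accepted, _rejected = classify_candidates(cand_set, grey, model)
        created = tuple(
            (self._fresh_id(), "derived", c.polygon, c.area_px) for c in accepted
        )
        return self._commit(self._record("add_smaller", created=created))

    # -- undo / redo ---------------------------------------------------

    def undo(self) -> CystSet:
        if self.log.cursor == 0:
            raise ValueError("nothing to undo")
        self.log.cursor -= 1
        return self.current

    def redo(self) -> CystSet:
        if self.log.cursor >= len(self.log.records):
            raise ValueError("nothing to redo")
        self.log.cursor += 1
        return self.current
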