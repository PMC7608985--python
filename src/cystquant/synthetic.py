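"""Seeded synthetic H&E-like histology with exact ground truth.

Real cystic kidney/liver sections are not redistributable, so every part of
the package is exercised on generated images that emulate the features the
pipeline keys on: eosin-pink tissue with nuclear speckle, near-white cyst
lumens whose green channel sits far above the tissue green level, and
non-cyst bright distractors (renal tubules, bile ducts/vessels) that share
the lumen brightness but carry a fine speckled texture a smooth cyst lumen
lacks -- which is exactly the cue the LBP classifier uses.

Cysts are ellipses, so the ground-truth equivalent diameter is analytic and
the ground-truth cystic index is an exact pixel count.  All randomness is
driven by a mandatory seed; identical specs produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _ellipse

from .classifier import FALSE_POSITIVE, TRUE_CYST, LabeledDataset
from .contours import polygon_mask, trace_outer_border
from .edits import EditLog, EditRecord, SupervisionSession
from .metrics import EvalCounts
from .raster import Calibration, CystContour, CystSet, rgb_to_grey
from .texture import LbpConfig, compute_lbp_features

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_histology_image",
    "easy_spec",
    "distractor_spec",
    "match_to_ground_truth",
    "generate_lbp_training_set",
    "generate_separable_features",
    "generate_edit_scenario",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic histology image.

    Diameters are equivalent-circle diameters in pixels; colors are 8-bit
    RGB.  The tissue green level sits at least ``contrast_margin`` grey
    levels below the lumen green level.
    """

    seed: int
    width: int = 1020
    height: int = 768
    organ: str = "kidney"
    n_cysts: int = 25
    cyst_diameter: tuple = (24.0, 90.0)
    n_small_cysts: int = 0
    small_cyst_diameter: tuple = (9.0, 15.0)
    n_tubules: int = 0
    tubule_diameter: tuple = (9.0, 15.0)
    n_ducts: int = 0
    duct_diameter: tuple = (28.0, 60.0)
    tissue_rgb: tuple = (200, 120, 165)
    lumen_rgb: tuple = (243, 240, 246)
    noise_sigma: float = 5.0
    speckle_amplitude: float = 22.0
    min_separation: float = 12.0
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        margin = self.lumen_rgb[1] - self.tissue_rgb[1]
        if margin < 60:
            raise ValueError("lumen green must exceed tissue green by >= 60 grey levels")

    @property
    def contrast_margin(self) -> int:
        return self.lumen_rgb[1] - self.tissue_rgb[1]


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-object truth for one generated image."""

    cysts: CystSet  # the true cysts (main size range)
    small_cysts: tuple = ()  # CystContour below the main dmin
    distractors: tuple = ()  # (kind, CystContour) with kind in {tubule, duct}
    cystic_index: float = 0.0  # exact CI of the main cysts, percent

    def diameters(self) -> np.ndarray:
        return np.array([c.equiv_diameter_px for c in self.cysts])


def _place_objects(rng, spec, diam_ranges):
    """Rejection-sample non-overlapping ellipses.

    ``diam_ranges`` is a list of (kind, n, (d_lo, d_hi)).  Returns a list of
    (kind, cy, cx, a, b, rotation).  Objects keep ``min_separation`` between
    bounding circles and off the image border.
    """
    placed = []
    n_total = sum(n for _, n, _ in diam_ranges)
    budget = max(100, 10 * n_total)
    sep = spec.min_separation
    for kind, n, (d_lo, d_hi) in diam_ranges:
        for _ in range(n):
            for attempt in range(budget):
                d = rng.uniform(d_lo, d_hi)
                q = rng.uniform(0.75, 1.0)  # aspect ratio b/a
                a = (d / 2.0) / np.sqrt(q)
                b = (d / 2.0) * np.sqrt(q)
                rot = rng.uniform(0.0, np.pi)
                r_bound = a + sep / 2.0
                cx = rng.uniform(r_bound + 1, spec.width - r_bound - 2)
                cy = rng.uniform(r_bound + 1, spec.height - r_bound - 2)
                ok = True
                for _, pcy, pcx, pa, _, _ in placed:
                    if np.hypot(cy - pcy, cx - pcx) < (a + pa + sep):
                        ok = False
                        break
                if ok:
                    placed.append((kind, cy, cx, a, b, rot))
                    break
            else:
                raise RuntimeError(
                    f"infeasible packing: could not place object {len(placed) + 1} "
                    f"within {budget} attempts"
                )
    return placed


def _ellipse_mask(shape, cy, cx, a, b, rot):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = _ellipse(cy, cx, b, a, shape=shape, rotation=rot)
    mask[rr, cc] = True
    return mask


def _paint_smooth(img, mask, rgb, rng, sigma=2.5):
    vals = np.asarray(rgb, dtype=np.float64) + rng.normal(0.0, sigma, size=(int(mask.sum()), 3))
    img[mask] = vals


def _paint_speckled(img, mask, rgb, rng, amplitude=40.0):
    """Bright but textured fill: speckle at the 1-3 px scale LBP resolves."""
    ys, xs = np.nonzero(mask)
    # 2-px-block speckle field (coarser than pixel noise, finer than the rim)
    field = rng.uniform(-amplitude, amplitude, size=((img.shape[0] + 1) // 2, (img.shape[1] + 1) // 2))
    speckle = field[ys // 2, xs // 2] + rng.uniform(-amplitude / 2, amplitude / 2, size=ys.size)
    vals = np.asarray(rgb, dtype=np.float64) + speckle[:, None]
    vals += rng.normal(0.0, 4.0, size=(ys.size, 3))
    img[ys, xs] = vals


def generate_histology_image(spec: FixtureSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic section and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    # eosin-pink tissue with nuclear speckle
    img = np.empty((*shape, 3), dtype=np.float64)
    img[...] = np.asarray(spec.tissue_rgb, dtype=np.float64)
    img += rng.normal(0.0, spec.speckle_amplitude / 2.0, size=(*shape, 1))
    nuclei = rng.random(shape) < 0.03  # scattered hematoxylin-dark nuclei
    img[nuclei] -= np.array([70.0, 45.0, 25.0])

    placed = _place_objects(
        rng,
        spec,
        [
            ("cyst", spec.n_cysts, spec.cyst_diameter),
            ("small_cyst", spec.n_small_cysts, spec.small_cyst_diameter),
            ("tubule", spec.n_tubules, spec.tubule_diameter),
            ("duct", spec.n_ducts, spec.duct_diameter),
        ],
    )

    cyst_contours, small_contours, distractors = [], [], []
    cyst_union = np.zeros(shape, dtype=bool)
    next_id = 1
    for kind, cy, cx, a, b, rot in placed:
        mask = _ellipse_mask(shape, cy, cx, a, b, rot)
        if not mask.any():
            continue
        contour = CystContour(
            id=next_id, polygon=trace_outer_border(mask), origin="auto", area_px=int(mask.sum())
        )
        next_id += 1
        if kind in ("cyst", "small_cyst"):
            _paint_smooth(img, mask, spec.lumen_rgb, rng)
            if kind == "cyst":
                cyst_contours.append(contour)
                cyst_union |= mask
            else:
                small_contours.append(contour)
        else:
            # bright but textured: same mean brightness family as a lumen,
            # plus strong fine speckle and a darker rim ring
            base = tuple(v - 12 for v in spec.lumen_rgb)
            _paint_speckled(img, mask, base, rng, amplitude=42.0)
            rim = mask & ~_ellipse_mask(shape, cy, cx, max(a - 2.0, 1.0), max(b - 2.0, 1.0), rot)
            img[rim] -= 55.0
            distractors.append((kind, contour))

    img += rng.normal(0.0, spec.noise_sigma, size=(*shape, 3))
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        cysts=CystSet(
            width=spec.width,
            height=spec.height,
            organ=spec.organ,
            calibration=spec.calibration,
            cysts=tuple(cyst_contours),
        ),
        small_cysts=tuple(small_contours),
        distractors=tuple(distractors),
        cystic_index=100.0 * float(cyst_union.sum()) / (spec.width * spec.height),
    )
    return rgb, truth


def easy_spec(seed: int, n_cysts: int | None = None, **overrides) -> FixtureSpec:
    """High-contrast, distractor-free study condition (10-50 separated cysts)."""
    rng = np.random.default_rng(seed)
    if n_cysts is None:
        n_cysts = int(rng.integers(10, 51))
    return FixtureSpec(seed=seed, n_cysts=n_cysts, **overrides)


def distractor_spec(seed: int, **overrides) -> FixtureSpec:
    """Study condition with bright non-cyst structures present."""
    defaults = dict(n_cysts=12, n_tubules=25, n_ducts=6)
    defaults.update(overrides)
    return FixtureSpec(seed=seed, **defaults)


def match_to_ground_truth(
    recognized: CystSet, truth: GroundTruth, iou_threshold: float = 0.5
) -> dict:
    """Greedy one-to-one matching of recognised cysts to ground-truth cysts.

    Each recognised cyst is matched to the ground-truth cyst it overlaps
    most (ground-truth objects are disjoint, so a pixel-majority label
    image resolves the candidate); a match counts when IoU >= threshold.
    Returns recall, precision and the per-match area errors.
    """
    shape = recognized.shape()
    gt_label = np.zeros(shape, dtype=np.int32)
    gt_area = {}
    for gt in truth.cysts:
        mask = polygon_mask(gt.polygon, shape)
        gt_label[mask] = gt.id
        gt_area[gt.id] = int(mask.sum())
    matched = {}
    n_unmatched = 0
    for cyst in recognized:
        mask = polygon_mask(cyst.polygon, shape)
        labels, counts = np.unique(gt_label[mask], return_counts=True)
        nz = labels != 0
        if not nz.any():
            n_unmatched += 1
            continue
        best = labels[nz][np.argmax(counts[nz])]
        inter = int(counts[nz][np.argmax(counts[nz])])
        union = int(mask.sum()) + gt_area[int(best)] - inter
        iou = inter / union
        if iou >= iou_threshold and int(best) not in matched:
            matched[int(best)] = (cyst.id, iou, cyst.area_px / gt_area[int(best)])
        else:
            n_unmatched += 1
    n_truth = len(truth.cysts)
    n_rec = len(recognized)
    n_match = len(matched)
    return {
        "n_truth": n_truth,
        "n_recognized": n_rec,
        "n_matched": n_match,
        "recall": n_match / n_truth if n_truth else 1.0,
        "precision": n_match / n_rec if n_rec else 1.0,
        "area_ratios": [v[2] for v in matched.values()],
    }


def _segmented_region(rgb: np.ndarray, truth_mask: np.ndarray) -> np.ndarray:
    """The candidate region the recogniser would propose for one object.

    Runs the fine-opening segmentation on the patch and returns the
    component overlapping the rendered object; falls back to the exact
    mask when segmentation drops the object entirely.
    """
    from scipy import ndimage as _ndi

    from .segmentation import denoise_open, extract_green, global_mean_threshold, kmeans_refine

    green = extract_green(rgb)
    thresholded, _ = global_mean_threshold(green)
    opened = denoise_open(kmeans_refine(green, thresholded), "liver")
    labels, n = _ndi.label(opened, structure=np.ones((3, 3), dtype=int))
    best, best_overlap = None, 0
    for i in range(1, n + 1):
        overlap = int(np.sum((labels == i) & truth_mask))
        if overlap > best_overlap:
            best, best_overlap = i, overlap
    if best is None:
        return truth_mask
    return _ndi.binary_fill_holes(labels == best)


def generate_lbp_training_set(
    n_per_class: int,
    seed: int,
    config: LbpConfig = LbpConfig(),
    patch_size: int = 64,
    diameter: tuple = (12.0, 22.0),
) -> LabeledDataset:
    """Balanced LBP features from generated small-cyst and tubule patches.

    Each sample is one object rendered at the centre of a small tissue
    patch.  The descriptor region is not the ground-truth mask but the
    region the recognition pipeline itself segments (mean threshold,
    k-means refinement, fine opening), mirroring how false examples arise
    in practice -- candidate regions proposed by the recogniser -- so the
    training distribution matches what the classifier sees at prediction
    time.  Features are the region's LBP descriptor on the luminance image.
    """
    if n_per_class < 20:
        raise ValueError("need at least 20 samples per class")
    rng = np.random.default_rng(seed)
    feats, labels, provenance = [], [], []
    base = FixtureSpec(seed=seed)
    for i in range(2 * n_per_class):
        is_cyst = i % 2 == 0
        shape = (patch_size, patch_size)
        img = np.empty((*shape, 3), dtype=np.float64)
        img[...] = np.asarray(base.tissue_rgb, dtype=np.float64)
        img += rng.normal(0.0, base.speckle_amplitude / 2.0, size=(*shape, 1))
        nuclei = rng.random(shape) < 0.03
        img[nuclei] -= np.array([70.0, 45.0, 25.0])
        d = rng.uniform(*diameter)
        q = rng.uniform(0.75, 1.0)
        a, b = (d / 2.0) / np.sqrt(q), (d / 2.0) * np.sqrt(q)
        rot = rng.uniform(0.0, np.pi)
        cy = patch_size / 2.0 + rng.uniform(-2, 2)
        cx = patch_size / 2.0 + rng.uniform(-2, 2)
        mask = _ellipse_mask(shape, cy, cx, a, b, rot)
        if is_cyst:
            _paint_smooth(img, mask, base.lumen_rgb, rng)
        else:
            _paint_speckled(img, mask, tuple(v - 12 for v in base.lumen_rgb), rng, amplitude=42.0)
            rim = mask & ~_ellipse_mask(shape, cy, cx, max(a - 2.0, 1.0), max(b - 2.0, 1.0), rot)
            img[rim] -= 55.0
        img += rng.normal(0.0, base.noise_sigma, size=(*shape, 3))
        rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        region = _segmented_region(rgb, mask)
        feats.append(compute_lbp_features(rgb_to_grey(rgb), region, config))
        labels.append(TRUE_CYST if is_cyst else FALSE_POSITIVE)
        provenance.append(f"{'cyst' if is_cyst else 'tubule'}_{i}")
    return LabeledDataset(features=np.array(feats), labels=tuple(labels), provenance=tuple(provenance))


def generate_separable_features(
    n: int = 400, seed: int = 7, n_features: int = 54, separation: float = 6.0
) -> LabeledDataset:
    """Two unit-variance Gaussian blobs with means ``separation`` sigma apart."""
    rng = np.random.default_rng(seed)
    half = n // 2
    offset = np.zeros(n_features)
    offset[0] = separation
    x0 = rng.normal(0.0, 1.0, size=(half, n_features))
    x1 = rng.normal(0.0, 1.0, size=(n - half, n_features)) + offset
    feats = np.vstack([x0, x1])
    labels = (FALSE_POSITIVE,) * half + (TRUE_CYST,) * (n - half)
    perm = rng.permutation(n)
    return LabeledDataset(
        features=feats[perm],
        labels=tuple(np.array(labels, dtype=object)[perm]),
        provenance=tuple(f"blob_{i}" for i in perm),
    )


# ---------------------------------------------------------------------------
# random supervision scenarios with an independently tallied expectation
# ---------------------------------------------------------------------------

_CELL = 60


def _cell_rect(row, col, margin):
    x0, y0 = col * _CELL + margin, row * _CELL + margin
    x1, y1 = (col + 1) * _CELL - margin - 1, (row + 1) * _CELL - margin - 1
    return np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], dtype=np.int64)


def generate_edit_scenario(seed: int, n_edits: int | None = None):
    """A random but replayable supervision scenario with expected error counts.

    Places automatic rectangle "cysts" on a cell grid, applies a random
    sequence of the seven edit kinds (each automatic cyst touched at most
    once; derived/manual cysts never re-edited), and tallies the expected
    TP/FP/FN per edit by the published rules: delete -> 1 FP; add -> 1 FN;
    split -> 1 FP + 2 FN; merge of k -> k FP + 1 FN; complete -> 1 FP +
    1 FN; remove-inner -> 1 FP per removed cyst; small-cyst additions ->
    1 FN each.

    Returns ``(initial CystSet, EditLog, expected EvalCounts)``.
    """
    rng = np.random.default_rng(seed)
    grid = 6
    size = grid * _CELL
    cells = [(r, c) for r in range(grid) for c in range(grid)]
    rng.shuffle(cells)

    n_single = int(rng.integers(8, 14))
    n_pair = int(rng.integers(1, 4))
    singles = cells[:n_single]
    pairs = cells[n_single : n_single + n_pair]
    free = cells[n_single + n_pair :]

    cysts = []
    next_id = 1
    single_ids = {}
    pair_ids = {}

    def make(poly):
        nonlocal next_id
        area = int(polygon_mask(poly, (size, size)).sum())
        c = CystContour(id=next_id, polygon=poly, origin="auto", area_px=area)
        next_id += 1
        return c

    for cell in singles:
        c = make(_cell_rect(*cell, margin=12))
        single_ids[cell] = c.id
        cysts.append(c)
    for cell in pairs:
        r, col = cell
        x0, y0 = col * _CELL + 8, r * _CELL + 14
        left = np.array([(x0, y0), (x0 + 18, y0), (x0 + 18, y0 + 24), (x0, y0 + 24)], dtype=np.int64)
        right = left + np.array([24, 0])  # 6-px gap, within the bridge reach
        ca, cb = make(left), make(right)
        pair_ids[cell] = (ca.id, cb.id)
        cysts.extend([ca, cb])

    initial = CystSet(width=size, height=size, organ="kidney", cysts=tuple(cysts))
    session = SupervisionSession(initial)
    exp_fp = exp_fn = 0
    untouched_singles = list(singles)
    untouched_pairs = list(pairs)
    free_cells = list(free)

    if n_edits is None:
        n_edits = int(rng.integers(5, 13))
    for _ in range(n_edits):
        feasible = []
        if untouched_singles:
            feasible += ["delete", "complete", "split", "remove_inner"]
        if untouched_pairs:
            feasible.append("merge")
        if free_cells:
            feasible += ["add", "add_smaller"]
        if not feasible:
            break
        kind = feasible[int(rng.integers(len(feasible)))]
        if kind == "delete":
            cell = untouched_singles.pop(int(rng.integers(len(untouched_singles))))
            session.delete_cyst(single_ids[cell])
            exp_fp += 1
        elif kind == "add":
            cell = free_cells.pop(int(rng.integers(len(free_cells))))
            session.add_cyst(_cell_rect(*cell, margin=14))
            exp_fn += 1
        elif kind == "complete":
            cell = untouched_singles.pop(int(rng.integers(len(untouched_singles))))
            session.complete_cyst(single_ids[cell], _cell_rect(*cell, margin=8))
            exp_fp += 1
            exp_fn += 1
        elif kind == "split":
            cell = untouched_singles.pop(int(rng.integers(len(untouched_singles))))
            r, col = cell
            xmid = col * _CELL + _CELL // 2
            polyline = np.array([(xmid, r * _CELL + 2), (xmid, (r + 1) * _CELL - 3)], dtype=np.int64)
            session.split_cyst(single_ids[cell], polyline)
            exp_fp += 1
            exp_fn += 2
        elif kind == "merge":
            cell = untouched_pairs.pop(int(rng.integers(len(untouched_pairs))))
            session.merge_cysts(pair_ids[cell])
            exp_fp += 2
            exp_fn += 1
        elif kind == "remove_inner":
            cell = untouched_singles.pop(int(rng.integers(len(untouched_singles))))
            session.add_cyst(_cell_rect(*cell, margin=4))  # manual container over the auto cyst
            container_id = max(session.current.ids())
            exp_fn += 1
            session.remove_inner_cysts(container_id)
            exp_fp += 1
        elif kind == "add_smaller":
            cell = free_cells.pop(int(rng.integers(len(free_cells))))
            r, col = cell
            k = int(rng.integers(1, 3))
            created = []
            for j in range(k):
                x0 = col * _CELL + 6 + 20 * j
                y0 = r * _CELL + 6
                poly = np.array(
                    [(x0, y0), (x0 + 7, y0), (x0 + 7, y0 + 7), (x0, y0 + 7)], dtype=np.int64
                )
                area = int(polygon_mask(poly, (size, size)).sum())
                created.append((session._fresh_id(), "derived", poly, area))
            session.log.append(
                EditRecord(kind="add_smaller", created=tuple(created), index=len(session.log.records))
            )
            exp_fn += k
    exp_tp = len(initial) - exp_fp
    return initial, session.log, EvalCounts(TP=exp_tp, FP=exp_fp, FN=exp_fn)
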