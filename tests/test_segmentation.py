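"""Unit and property tests for the six-step recognition pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage
from skimage.draw import disk as draw_disk

import cystquant as cq
from cystquant.raster import DiameterRange
from cystquant.segmentation import (
    denoise_open,
    extract_contours,
    extract_green,
    filter_by_diameter,
    global_mean_threshold,
    kmeans_refine,
    opening_footprint,
    recognize_cysts,
)
from cystquant.synthetic import easy_spec, generate_histology_image, match_to_ground_truth

grey_images = hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=24))


# --- step 1: green channel -------------------------------------------------


def test_extract_green_selects_channel():
    img = np.zeros((2, 2, 3), np.uint8)
    img[0, 0] = (10, 200, 30)
    assert extract_green(img)[0, 0] == 200


def test_extract_green_identity_on_grey_rgb(rng):
    grey = rng.integers(0, 256, size=(7, 9)).astype(np.uint8)
    rgb = np.stack([grey] * 3, axis=-1)
    assert np.array_equal(extract_green(rgb), grey)


def test_extract_green_matches_slicing_oracle(rng):
    rgb = rng.integers(0, 256, size=(13, 17, 3)).astype(np.uint8)
    oracle = np.empty((13, 17), np.uint8)
    for y in range(13):
        for x in range(17):
            oracle[y, x] = rgb[y, x][1]
    assert np.array_equal(extract_green(rgb), oracle)


# --- steps 2-3: global mean threshold --------------------------------------


def test_threshold_constant_image_is_empty():
    mask, mean = global_mean_threshold(np.full((5, 5), 100, np.uint8))
    assert mean == 100.0
    assert not mask.any()


def test_threshold_two_valued_image():
    grey = np.zeros((4, 4), np.uint8)
    grey[:2] = 200
    mask, mean = global_mean_threshold(grey)
    assert mean == 100.0
    assert np.array_equal(mask, grey == 200)


@given(grey_images)
def test_threshold_matches_double_loop_oracle(grey):
    mask, mean = global_mean_threshold(grey)
    total = 0
    for y in range(grey.shape[0]):
        for x in range(grey.shape[1]):
            total += int(grey[y, x])
    mean_oracle = total / grey.size
    assert mean == pytest.approx(mean_oracle)
    for y in range(grey.shape[0]):
        for x in range(grey.shape[1]):
            assert mask[y, x] == (grey[y, x] > mean_oracle)


# --- step 4: k-means refinement --------------------------------------------


def _exhaustive_two_means(grey):
    """Global optimum over all 255 cut points (min within-cluster SSE)."""
    v = grey.astype(np.float64).ravel()
    best, best_sse = None, np.inf
    for t in range(255):
        fg = v > t
        if not fg.any() or fg.all():
            continue
        sse = ((v[fg] - v[fg].mean()) ** 2).sum() + ((v[~fg] - v[~fg].mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, t
    return grey > best


def test_kmeans_two_valued_fixed_point():
    grey = np.zeros((10, 10), np.uint8)
    grey[:, 5:] = 200
    init = grey > 100
    assert np.array_equal(kmeans_refine(grey, init), init)


def test_kmeans_degenerate_init_returned_unchanged():
    grey = np.full((6, 6), 42, np.uint8)
    all_fg = np.ones((6, 6), bool)
    assert np.array_equal(kmeans_refine(grey, all_fg), all_fg)
    none_fg = np.zeros((6, 6), bool)
    assert np.array_equal(kmeans_refine(grey, none_fg), none_fg)


@pytest.mark.parametrize("seed", range(10))
def test_kmeans_matches_exhaustive_cut_oracle(seed):
    rng = np.random.default_rng(seed)
    lo = rng.normal(60, 12, size=(40, 40))
    hi = rng.normal(180, 15, size=(40, 40))
    grey = np.clip(np.where(rng.random((40, 40)) < 0.35, hi, lo), 0, 255).astype(np.uint8)
    init, _ = global_mean_threshold(grey)
    assert np.array_equal(kmeans_refine(grey, init), _exhaustive_two_means(grey))


# --- step 5: morphological opening -----------------------------------------


def test_opening_removes_isolated_pixel_liver():
    mask = np.zeros((9, 9), bool)
    mask[4, 4] = True
    assert not denoise_open(mask, "liver").any()


def test_opening_empty_mask():
    assert not denoise_open(np.zeros((5, 5), bool), "liver").any()


def test_kidney_opening_matches_erode_dilate_oracle():
    diameters = DiameterRange(8.0, 60.0)
    mask = np.zeros((60, 60), bool)
    rr, cc = draw_disk((30, 30), (diameters.dmin + 6) / 2, shape=mask.shape)
    mask[rr, cc] = True
    opened = denoise_open(mask, "kidney", diameters)
    fp = opening_footprint("kidney", diameters)
    oracle = ndimage.binary_dilation(ndimage.binary_erosion(mask, fp), fp)
    assert np.array_equal(opened, oracle)
    assert opened.any()  # a disk larger than the element survives


@given(hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=24)))
def test_opening_is_anti_extensive(mask):
    opened = denoise_open(mask, "liver")
    assert not (opened & ~mask).any()


# --- step 6: contour extraction --------------------------------------------


def test_contour_of_filled_rectangle():
    mask = np.zeros((20, 30), bool)
    mask[5:15, 10:20] = True
    (contour,) = extract_contours(mask)
    assert contour.area_px == 100
    assert contour.origin == "auto"


def test_contour_of_annulus_counts_hole_as_area():
    mask = np.zeros((30, 30), bool)
    rr, cc = draw_disk((15, 15), 10, shape=mask.shape)
    mask[rr, cc] = True
    hole_rr, hole_cc = draw_disk((15, 15), 4, shape=mask.shape)
    full_area = int(mask.sum())
    mask[hole_rr, hole_cc] = False
    contours = extract_contours(mask)
    assert len(contours) == 1
    assert contours[0].area_px == full_area


def _flood_fill_components(mask):
    """8-connected labelling + filled areas by BFS, independent of the tracer."""
    h, w = mask.shape
    labels = np.zeros((h, w), np.int32)
    areas = []
    nxt = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and labels[sy, sx] == 0:
                nxt += 1
                stack = [(sy, sx)]
                labels[sy, sx] = nxt
                comp = []
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx_ = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx_ < w and mask[ny, nx_] and labels[ny, nx_] == 0:
                                labels[ny, nx_] = nxt
                                stack.append((ny, nx_))
                comp_mask = labels == nxt
                areas.append(int(ndimage.binary_fill_holes(comp_mask).sum()))
    return nxt, sorted(areas)


@pytest.mark.parametrize("seed", range(10))
def test_contours_match_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((64, 64)) < rng.uniform(0.15, 0.6)
    contours = extract_contours(mask)
    n_oracle, areas_oracle = _flood_fill_components(mask)
    assert len(contours) == n_oracle
    assert sorted(c.area_px for c in contours) == areas_oracle


@pytest.mark.parametrize("seed", [3, 11])
def test_contour_polygons_reconstruct_components_exactly(seed):
    from cystquant.contours import polygon_mask

    rng = np.random.default_rng(seed)
    mask = rng.random((48, 48)) < 0.45
    filled_union = np.zeros_like(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    for i in range(1, n + 1):
        filled_union |= ndimage.binary_fill_holes(labels == i)
    rec = np.zeros_like(mask)
    for contour in extract_contours(mask):
        rec |= polygon_mask(contour.polygon, mask.shape)
    assert np.array_equal(rec, filled_union)


def test_contour_area_sum_bounded_by_foreground(rng):
    mask = rng.random((50, 50)) < 0.4
    total = sum(c.area_px for c in extract_contours(mask))
    assert total >= int(mask.sum())  # holes counted as area
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    no_holes = all(
        int(ndimage.binary_fill_holes(labels == i).sum()) == int((labels == i).sum())
        for i in range(1, n + 1)
    )
    if no_holes:
        assert total == int(mask.sum())


# --- diameter filter --------------------------------------------------------


def _circle_contour(radius, shape=(64, 64)):
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk((32, 32), radius, shape=shape)
    mask[rr, cc] = True
    return extract_contours(mask)[0]


def test_filter_keeps_in_range_circle():
    c = _circle_contour(10)  # equivalent diameter ~20
    assert filter_by_diameter([c], DiameterRange(15, 50)) == [c]
    assert filter_by_diameter([c], DiameterRange(25, 50)) == []


def test_filter_matches_per_element_oracle(rng):
    cysts = [_circle_contour(r) for r in rng.integers(2, 25, size=30)]
    cysts = [
        cq.CystContour(id=i, polygon=c.polygon, origin="auto", area_px=c.area_px)
        for i, c in enumerate(cysts)
    ]
    diameters = DiameterRange(10, 30)
    survivors = filter_by_diameter(cysts, diameters)
    oracle = [c for c in cysts if diameters.dmin <= c.equiv_diameter_px <= diameters.dmax]
    assert [c.id for c in survivors] == [c.id for c in oracle]


@given(
    st.lists(st.integers(2, 30), min_size=1, max_size=12),
    st.floats(5, 30),
    st.floats(1, 20),
    st.floats(1, 20),
)
def test_filter_is_monotone_under_narrowing(radii, lo, d_outer, d_inner):
    cysts = [
        cq.CystContour(
            id=i,
            polygon=np.array([(0, 0), (1, 0), (1, 1)]),
            origin="auto",
            area_px=int(np.pi * r * r),
        )
        for i, r in enumerate(radii)
    ]
    wide = DiameterRange(lo, lo + d_inner + d_outer)
    narrow = DiameterRange(lo + d_outer / 2, lo + d_outer / 2 + d_inner)
    assert len(filter_by_diameter(cysts, narrow)) <= len(filter_by_diameter(cysts, wide))


# --- full pipeline ----------------------------------------------------------


def test_pipeline_recovers_well_separated_ellipses():
    spec = easy_spec(seed=21, n_cysts=12)
    image, truth = generate_histology_image(spec)
    cyst_set, trace = recognize_cysts(image, "kidney", DiameterRange(18.0, 120.0))
    assert len(cyst_set) == 12
    match = match_to_ground_truth(cyst_set, truth)
    assert match["n_matched"] == 12
    for ratio in match["area_ratios"]:
        assert ratio == pytest.approx(1.0, abs=0.05)
    # anti-extensivity of the opening within the pipeline trace
    assert not (trace.opened & ~trace.kmeans_refined).any()


def test_pipeline_blank_tissue_yields_no_cysts():
    spec = easy_spec(seed=4, n_cysts=0)
    image, _ = generate_histology_image(spec)
    cyst_set, _ = recognize_cysts(image, "kidney", DiameterRange(18.0, 120.0))
    assert len(cyst_set) == 0


def test_pipeline_is_deterministic():
    spec = easy_spec(seed=9, n_cysts=15)
    image, _ = generate_histology_image(spec)
    a, _ = recognize_cysts(image, "liver", DiameterRange(18.0, 120.0))
    b, _ = recognize_cysts(image, "liver", DiameterRange(18.0, 120.0))
    assert len(a) == len(b)
    for ca, cb in zip(a, b):
        assert ca.id == cb.id and ca.area_px == cb.area_px
        assert np.array_equal(ca.polygon, cb.polygon)
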