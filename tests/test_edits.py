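"""Supervision tools: editing operations, the log and undo/redo."""

import numpy as np
import pytest

import cystquant as cq
from cystquant.contours import polygon_mask
from cystquant.edits import SupervisionSession, replay
from cystquant.synthetic import generate_edit_scenario


def _rect(x0, y0, x1, y1):
    return np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1)], dtype=np.int64)


def _make_set(*rects, width=100, height=100, origins=None):
    cysts = []
    for i, r in enumerate(rects, start=1):
        area = int(polygon_mask(r, (height, width)).sum())
        origin = origins[i - 1] if origins else "auto"
        cysts.append(cq.CystContour(id=i, polygon=r, origin=origin, area_px=area))
    return cq.CystSet(width=width, height=height, organ="kidney", cysts=tuple(cysts))


@pytest.fixture()
def session():
    return SupervisionSession(_make_set(_rect(10, 10, 30, 30), _rect(50, 50, 80, 80)))


# --- delete / add / complete ------------------------------------------------


def test_delete_only_cyst_empties_set():
    sess = SupervisionSession(_make_set(_rect(10, 10, 30, 30)))
    assert len(sess.delete_cyst(1)) == 0


def test_delete_unknown_id_raises(session):
    with pytest.raises(KeyError):
        session.delete_cyst(99)


def test_delete_then_undo_restores_set(session):
    before = session.current
    session.delete_cyst(1)
    restored = session.undo()
    assert restored.ids() == before.ids()
    for cyst in restored:
        assert np.array_equal(cyst.polygon, before.get(cyst.id).polygon)


def test_add_square_cyst(session):
    out = session.add_cyst(_rect(5, 60, 14, 69))
    assert len(out) == 3
    added = out.get(max(out.ids()))
    assert added.origin == "manual"
    assert added.area_px == 100


def test_add_degenerate_polygon_raises(session):
    with pytest.raises(ValueError):
        session.add_cyst(np.array([(0, 0), (5, 5)]))
    with pytest.raises(ValueError):  # self-intersecting bow-tie
        session.add_cyst(np.array([(0, 0), (10, 10), (10, 0), (0, 10)]))


def test_add_then_delete_recovers_original(session):
    before_ids = session.current.ids()
    out = session.add_cyst(_rect(5, 60, 14, 69))
    new_id = max(out.ids())
    assert session.delete_cyst(new_id).ids() == before_ids


def test_complete_replaces_polygon_with_fresh_id(session):
    out = session.complete_cyst(1, _rect(8, 8, 35, 35))
    assert 1 not in out.ids()
    new = out.get(max(out.ids()))
    assert new.origin == "derived"
    assert new.area_px == 28 * 28
    assert new.area_px > session.initial.get(1).area_px


def test_complete_with_identical_polygon_still_reissues_id(session):
    out = session.complete_cyst(1, _rect(10, 10, 30, 30))
    new = out.get(max(out.ids()))
    assert new.area_px == session.initial.get(1).area_px
    counts = cq.counts_from_log(session.initial, session.log)
    assert (counts.FP, counts.FN) == (1, 1)  # accounting is edit-based


def test_complete_unknown_id_raises(session):
    with pytest.raises(KeyError):
        session.complete_cyst(42, _rect(0, 0, 5, 5))


# --- split ------------------------------------------------------------------


def test_split_rectangle_down_the_middle():
    sess = SupervisionSession(_make_set(_rect(10, 10, 29, 19)))
    parent_area = sess.initial.get(1).area_px
    out = sess.split_cyst(1, np.array([(20, 8), (20, 21)]))
    assert len(out) == 2
    areas = sorted(c.area_px for c in out)
    cut_pixels = 10  # 1-px vertical line through a 10-row rectangle
    assert sum(areas) == parent_area - cut_pixels
    assert all(c.origin == "derived" for c in out)


def test_split_line_outside_cyst_raises(session):
    with pytest.raises(ValueError):
        session.split_cyst(1, np.array([(90, 90), (99, 99)]))


def test_split_then_merge_roundtrip():
    sess = SupervisionSession(_make_set(_rect(10, 10, 29, 19)))
    parent_area = sess.initial.get(1).area_px
    sess.split_cyst(1, np.array([(20, 8), (20, 21)]))
    ids = sorted(sess.current.ids())
    out = sess.merge_cysts(ids)
    merged = out.get(max(out.ids()))
    assert len(out) == 1
    # area recovered to within the cut-line pixel count (closing bridges the cut)
    assert parent_area - 10 <= merged.area_px <= parent_area


# --- merge ------------------------------------------------------------------


def test_merge_overlapping_disks_gives_union_area():
    from skimage.draw import disk as draw_disk

    shape = (100, 100)
    m1 = np.zeros(shape, bool)
    m2 = np.zeros(shape, bool)
    rr, cc = draw_disk((50, 40), 12, shape=shape)
    m1[rr, cc] = True
    rr, cc = draw_disk((50, 55), 12, shape=shape)
    m2[rr, cc] = True
    from cystquant.contours import trace_outer_border

    cysts = tuple(
        cq.CystContour(id=i, polygon=trace_outer_border(m), origin="auto", area_px=int(m.sum()))
        for i, m in ((1, m1), (2, m2))
    )
    sess = SupervisionSession(cq.CystSet(width=100, height=100, organ="kidney", cysts=cysts))
    out = sess.merge_cysts([1, 2])
    merged = out.get(max(out.ids()))
    assert len(out) == 1
    assert merged.area_px >= int((m1 | m2).sum())  # closing is extensive on the union
    assert merged.area_px >= max(int(m1.sum()), int(m2.sum()))


def test_merge_single_id_raises(session):
    with pytest.raises(ValueError):
        session.merge_cysts([1])


def test_merge_far_apart_cysts_raises():
    sess = SupervisionSession(_make_set(_rect(0, 0, 9, 9), _rect(90, 90, 99, 99)))
    with pytest.raises(ValueError):
        sess.merge_cysts([1, 2])


# --- remove inner -----------------------------------------------------------


def test_remove_inner_deletes_contained_auto_cysts():
    sess = SupervisionSession(_make_set(_rect(20, 20, 30, 30), _rect(60, 60, 70, 70)))
    sess.add_cyst(_rect(10, 10, 40, 40))  # manual container around cyst 1
    container_id = max(sess.current.ids())
    out = sess.remove_inner_cysts(container_id)
    assert 1 not in out.ids()
    assert 2 in out.ids()


def test_remove_inner_keeps_boundary_crossers():
    sess = SupervisionSession(_make_set(_rect(20, 20, 50, 30)))
    sess.add_cyst(_rect(10, 10, 40, 40))  # cyst 1 sticks out on the right
    container_id = max(sess.current.ids())
    out = sess.remove_inner_cysts(container_id)
    assert 1 in out.ids()


def test_remove_inner_requires_manual_container(session):
    with pytest.raises(ValueError):
        session.remove_inner_cysts(1)  # auto cyst cannot be the container


# --- add smaller ------------------------------------------------------------


def test_add_smaller_recovers_small_cysts(lbp_model):
    from cystquant.synthetic import FixtureSpec, generate_histology_image

    spec = FixtureSpec(seed=42, n_cysts=10, n_small_cysts=5, n_tubules=8)
    image, truth = generate_histology_image(spec)
    cyst_set, _ = cq.recognize_cysts(image, "kidney", cq.DiameterRange(18.0, 120.0))
    sess = SupervisionSession(cyst_set)
    out = sess.add_smaller_cysts(image, lbp_model, cq.DiameterRange(6.0, 17.0))
    added = [c for c in out if c.origin == "derived"]
    shape = (spec.height, spec.width)
    small_union = np.zeros(shape, bool)
    for c in truth.small_cysts:
        small_union |= polygon_mask(c.polygon, shape)
    tubule_union = np.zeros(shape, bool)
    for _, c in truth.distractors:
        tubule_union |= polygon_mask(c.polygon, shape)
    n_small = sum(1 for c in added if (polygon_mask(c.polygon, shape) & small_union).any())
    n_tubule = sum(1 for c in added if (polygon_mask(c.polygon, shape) & tubule_union).any())
    assert n_small >= 4
    assert n_tubule <= 1
    # idempotence: the overlap exclusion blocks a second pass
    before = len(out)
    out2 = sess.add_smaller_cysts(image, lbp_model, cq.DiameterRange(6.0, 17.0))
    assert len(out2) == before


def test_add_smaller_no_small_regions_is_noop(lbp_model):
    from cystquant.synthetic import easy_spec, generate_histology_image

    image, _ = generate_histology_image(easy_spec(seed=6, n_cysts=8))
    cyst_set, _ = cq.recognize_cysts(image, "kidney", cq.DiameterRange(18.0, 120.0))
    sess = SupervisionSession(cyst_set)
    out = sess.add_smaller_cysts(image, lbp_model, cq.DiameterRange(4.0, 8.0))
    assert out.ids() == cyst_set.ids()


def test_add_smaller_requires_trained_model():
    sess = SupervisionSession(_make_set(_rect(10, 10, 30, 30)))
    with pytest.raises(TypeError):
        sess.add_smaller_cysts(np.zeros((100, 100, 3), np.uint8), object(), cq.DiameterRange(4.0, 8.0))


# --- log, undo/redo, replay -------------------------------------------------


def test_every_edit_appends_one_record(session):
    session.delete_cyst(1)
    session.add_cyst(_rect(5, 60, 14, 69))
    session.complete_cyst(2, _rect(48, 48, 82, 82))
    assert len(session.log.records) == 3
    assert [r.kind for r in session.log.records] == ["delete", "add", "complete"]


def test_undo_redo_cycle(session):
    session.add_cyst(_rect(5, 60, 14, 69))
    after_add = session.current.ids()
    session.undo()
    assert session.current.ids() == session.initial.ids()
    session.redo()
    assert session.current.ids() == after_add
    with pytest.raises(ValueError):
        session.redo()


def test_undo_on_empty_log_raises(session):
    with pytest.raises(ValueError):
        session.undo()


def test_new_edit_discards_redo_tail(session):
    session.delete_cyst(1)
    session.undo()
    session.delete_cyst(2)
    assert len(session.log.records) == 1
    assert session.log.records[0].target_ids == (2,)


@pytest.mark.parametrize("seed", range(12))
def test_full_undo_returns_initial_state(seed):
    initial, log, _ = generate_edit_scenario(seed)
    sess = SupervisionSession(initial)
    sess.log = log
    k = log.cursor
    for _ in range(k):
        sess.undo()
    assert sess.current.ids() == initial.ids()


@pytest.mark.parametrize("seed", [0, 5, 17])
def test_replay_is_deterministic(seed):
    initial, log, _ = generate_edit_scenario(seed)
    a = replay(initial, log)
    b = replay(initial, log)
    assert a.ids() == b.ids()
    for cyst in a:
        other = b.get(cyst.id)
        assert np.array_equal(cyst.polygon, other.polygon)
        assert cyst.area_px == other.area_px and cyst.origin == other.origin
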