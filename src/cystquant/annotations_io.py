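"""Annotation persistence: XML export/import and image loading.

The XML dialect is project-defined: a root element carrying the image
metadata (organ, calibration, size), one ``<cyst>`` element per contour with
its id, origin and vertex list, and the edit log (records plus undo cursor)
so a supervision session can be resumed exactly where it stopped.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from .edits import EditLog, EditRecord
from .raster import Calibration, CystContour, CystSet, as_rgb_image

__all__ = ["export_xml", "import_xml", "load_image"]

_SCHEMA_VERSION = "1"


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as 8-bit RGB (grey promoted, alpha dropped)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return as_rgb_image(arr)


def _vertices_el(parent, tag, vertices):
    el = etree.SubElement(parent, tag)
    for x, y in np.asarray(vertices, dtype=np.int64):
        etree.SubElement(el, "v", x=str(int(x)), y=str(int(y)))
    return el


def _read_vertices(el) -> np.ndarray:
    verts = [(int(v.get("x")), int(v.get("y"))) for v in el.findall("v")]
    return np.asarray(verts, dtype=np.int64).reshape(-1, 2)


def _cyst_el(parent, cyst_id, origin, polygon, area):
    el = etree.SubElement(parent, "cyst", id=str(cyst_id), origin=origin, area_px=str(int(area)))
    _vertices_el(el, "polygon", polygon)
    return el


def _read_cyst(el) -> CystContour:
    return CystContour(
        id=int(el.get("id")),
        polygon=_read_vertices(el.find("polygon")),
        origin=el.get("origin"),
        area_px=int(el.get("area_px")),
    )


def export_xml(cyst_set: CystSet, path, log: EditLog | None = None) -> None:
    """Write a cyst set (and optionally its edit log) to an annotation XML."""
    root = etree.Element(
        "cyst_annotations",
        version=_SCHEMA_VERSION,
        organ=cyst_set.organ,
        um_per_px=repr(cyst_set.calibration.micrometers_per_pixel),
        width=str(cyst_set.width),
        height=str(cyst_set.height),
    )
    cysts_el = etree.SubElement(root, "cysts")
    for cyst in cyst_set:
        _cyst_el(cysts_el, cyst.id, cyst.origin, cyst.polygon, cyst.area_px)
    if log is not None:
        edits_el = etree.SubElement(root, "edits", cursor=str(log.cursor))
        for record in log.records:
            rec_el = etree.SubElement(edits_el, "edit", kind=record.kind, index=str(record.index))
            targets_el = etree.SubElement(rec_el, "targets")
            for tid in record.target_ids:
                etree.SubElement(targets_el, "t", id=str(tid))
            created_el = etree.SubElement(rec_el, "created")
            for cid, origin, polygon, area in record.created:
                _cyst_el(created_el, cid, origin, polygon, area)
            if len(record.payload):
                _vertices_el(rec_el, "payload", record.payload)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def import_xml(path) -> tuple[CystSet, EditLog]:
    """Read an annotation XML back into a (CystSet, EditLog) pair.

    Malformed files raise :class:`lxml.etree.XMLSyntaxError` (which carries
    the offending line) or :class:`ValueError` for schema violations.
    """
    tree = etree.parse(str(path))  # raises XMLSyntaxError with line info
    root = tree.getroot()
    if root.tag != "cyst_annotations":
        raise ValueError(f"not a cyst annotation file (root element <{root.tag}>)")
    if root.get("version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported annotation schema version {root.get('version')!r}")
    cyst_set = CystSet(
        width=int(root.get("width")),
        height=int(root.get("height")),
        organ=root.get("organ"),
        calibration=Calibration(float(root.get("um_per_px"))),
        cysts=tuple(_read_cyst(el) for el in root.find("cysts").findall("cyst")),
    )
    log = EditLog()
    edits_el = root.find("edits")
    if edits_el is not None:
        for rec_el in edits_el.findall("edit"):
            created = tuple(
                (c.id, c.origin, c.polygon, c.area_px)
                for c in (_read_cyst(el) for el in rec_el.find("created").findall("cyst"))
            )
            payload_el = rec_el.find("payload")
            payload = tuple(map(tuple, _read_vertices(payload_el))) if payload_el is not None else ()
            log.records.append(
                EditRecord(
                    kind=rec_el.get("kind"),
                    target_ids=tuple(int(t.get("id")) for t in rec_el.find("targets").findall("t")),
                    created=created,
                    payload=payload,
                    index=int(rec_el.get("index")),
                )
            )
        log.cursor = int(edits_el.get("cursor"))
        if not 0 <= log.cursor <= len(log.records):
            raise ValueError("edit cursor outside the log")
    return cyst_set, log
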