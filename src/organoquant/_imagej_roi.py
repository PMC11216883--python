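"""Minimal codec for the ImageJ ``.roi`` binary format (polygon ROIs only).

The format is a fixed 64-byte big-endian header ("Iout" magic), followed by
point coordinates as int16 offsets from the bounding box, optionally followed
by a second header that carries the ROI name.  Only the closed-outline types
(polygon, freehand, traced) are accepted; lines, points and composite ROIs
are rejected by the reader.
"""

from __future__ import annotations

import struct
import zipfile
from pathlib import Path

MAGIC = b"Iout"

# ROI type byte at offset 6
TYPE_POLYGON = 0
TYPE_RECT = 1
TYPE_OVAL = 2
TYPE_LINE = 3
TYPE_FREELINE = 4
TYPE_POLYLINE = 5
TYPE_NO_ROI = 6
TYPE_FREEHAND = 7
TYPE_TRACED = 8
TYPE_ANGLE = 9
TYPE_POINT = 10

_CLOSED_TYPES = {TYPE_POLYGON, TYPE_FREEHAND, TYPE_TRACED}

_TYPE_NAMES = {
    TYPE_LINE: "line",
    TYPE_FREELINE: "freeline",
    TYPE_POLYLINE: "polyline",
    TYPE_POINT: "point",
    TYPE_ANGLE: "angle",
    TYPE_RECT: "rect",
    TYPE_OVAL: "oval",
    TYPE_NO_ROI: "none",
}


def decode_roi_bytes(data: bytes) -> tuple[str | None, list[tuple[float, float]]]:
    """Decode one ``.roi`` blob into ``(name, [(x, y), ...])`` pixel vertices.

    Raises ``ValueError`` for non-polygon ROI types or malformed blobs.
    """
    if len(data) < 64 or data[:4] != MAGIC:
        raise ValueError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _CLOSED_TYPES:
        kind = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise ValueError(f"unsupported ROI type {kind!r}: only closed polygons are accepted")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    if n < 3:
        raise ValueError(f"polygon ROI needs >= 3 vertices, found {n}")
    coords = struct.unpack(f">{2 * n}h", data[64 : 64 + 4 * n])
    xs = [left + c for c in coords[:n]]
    ys = [top + c for c in coords[n:]]
    name = _decode_name(data)
    return name, list(zip((float(x) for x in xs), (float(y) for y in ys)))


def _decode_name(data: bytes) -> str | None:
    # header2 offset lives at byte 60; name offset/length at header2+16/+20
    (h2,) = struct.unpack(">i", data[60:64])
    if h2 <= 0 or h2 + 24 > len(data):
        return None
    name_off, name_len = struct.unpack(">2i", data[h2 + 16 : h2 + 24])
    if name_off <= 0 or name_len <= 0 or name_off + 2 * name_len > len(data):
        return None
    raw = data[name_off : name_off + 2 * name_len]
    return raw.decode("utf-16-be", errors="replace")


def encode_polygon(vertices: list[tuple[float, float]], name: str | None = None) -> bytes:
    """Encode integer-rounded pixel vertices as a polygon ``.roi`` blob."""
    xs = [int(round(x)) for x, _ in vertices]
    ys = [int(round(y)) for _, y in vertices]
    left, top = min(xs), min(ys)
    right, bottom = max(xs) + 1, max(ys) + 1
    n = len(xs)
    header = bytearray(64)
    header[:4] = MAGIC
    struct.pack_into(">h", header, 4, 228)  # version, matches modern ImageJ
    header[6] = TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = struct.pack(f">{n}h", *(x - left for x in xs)) + struct.pack(
        f">{n}h", *(y - top for y in ys)
    )
    blob = bytes(header) + body
    if name:
        h2_off = len(blob)
        encoded = name.encode("utf-16-be")
        header2 = bytearray(64)
        struct.pack_into(">2i", header2, 16, h2_off + 64, len(name))
        struct.pack_into(">i", blob_header := bytearray(blob), 60, h2_off)
        blob = bytes(blob_header) + bytes(header2) + encoded
    return blob


def write_roi_zip(path: str | Path, rois: dict[str, list[tuple[float, float]]]) -> None:
    """Write a named set of polygons as an ImageJ ROI zip archive."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, verts in rois.items():
            zf.writestr(f"{name}.roi", encode_polygon(verts, name=name))
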