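"""Minimal ESRI Shapefile I/O for polygon layers (.shp/.shx/.dbf).

Covers shape type 5 (Polygon) with dBase III attributes of types N
(numeric), C (character) and D (date, YYYYMMDD). Outer rings are written
clockwise and holes counter-clockwise per the shapefile convention; on
read, ring winding separates outers from holes and each hole is attached
to the outer ring that contains it.
"""

from __future__ import annotations

import datetime
import struct
from pathlib import Path

import shapely
from shapely.geometry import polygon as _polygon_mod
from shapely.geometry.base import BaseGeometry

_SHAPE_POLYGON = 5
_SHAPE_NULL = 0


def _rings_of(geom: BaseGeometry) -> list[list[tuple[float, float]]]:
    """Oriented rings of a (multi)polygon: outers CW, holes CCW."""
    polys = list(geom.geoms) if isinstance(geom, shapely.MultiPolygon) else [geom]
    rings = []
    for poly in polys:
        oriented = _polygon_mod.orient(poly, sign=-1.0)  # exterior CW
        rings.append(list(oriented.exterior.coords))
        rings.extend(list(hole.coords) for hole in oriented.interiors)
    return rings


def _polygon_record(geom: BaseGeometry) -> bytes:
    rings = _rings_of(geom)
    points = [pt for ring in rings for pt in ring]
    parts = []
    start = 0
    for ring in rings:
        parts.append(start)
        start += len(ring)
    minx, miny, maxx, maxy = geom.bounds
    buf = struct.pack("<i4d2i", _SHAPE_POLYGON, minx, miny, maxx, maxy, len(rings), len(points))
    buf += struct.pack(f"<{len(parts)}i", *parts)
    for x, y in points:
        buf += struct.pack("<2d", x, y)
    return buf


def _shoelace(ring: list[tuple[float, float]]) -> float:
    area = 0.0
    for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:]):
        area += x1 * y2 - x2 * y1
    return area / 2.0


def _assemble(rings: list[list[tuple[float, float]]]) -> BaseGeometry:
    outers = [r for r in rings if _shoelace(r) <= 0]  # CW = outer
    holes = [r for r in rings if _shoelace(r) > 0]
    if not outers:  # degenerate writer; treat everything as outer
        outers, holes = rings, []
    shells = [shapely.Polygon(r) for r in outers]
    assigned: list[list] = [[] for _ in shells]
    for hole in holes:
        pt = shapely.Point(hole[0])
        candidates = [
            (shell.area, k) for k, shell in enumerate(shells)
            if shell.contains(pt) or shell.boundary.distance(pt) == 0
        ]
        if candidates:
            assigned[min(candidates)[1]].append(hole)
    polys = [shapely.Polygon(r, holes=hs) for r, hs in zip(outers, assigned)]
    return polys[0] if len(polys) == 1 else shapely.MultiPolygon(polys)


def _main_header(shape_type: int, file_words: int, bounds) -> bytes:
    minx, miny, maxx, maxy = bounds
    head = struct.pack(">i", 9994) + b"\x00" * 20
    head += struct.pack(">i", file_words)
    head += struct.pack("<2i", 1000, shape_type)
    head += struct.pack("<8d", minx, miny, maxx, maxy, 0, 0, 0, 0)
    return head


# DBF field spec: (name, type, length, decimals); types N, C, D
FieldSpec = tuple[str, str, int, int]


def _dbf_encode(value, typ: str, length: int, decimals: int) -> bytes:
    if typ == "D":
        s = value.strftime("%Y%m%d") if value is not None else " " * 8
    elif typ == "N":
        if value is None:
            s = ""
        elif decimals:
            s = f"{float(value):.{decimals}f}"
        else:
            s = str(int(value))
        s = s.rjust(length)
    else:
        s = "" if value is None else str(value)
        s = s.ljust(length)
    raw = s.encode("ascii", "replace")[:length]
    return raw.ljust(length, b" ")


def _dbf_decode(raw: bytes, typ: str):
    s = raw.decode("ascii", "replace").strip()
    if not s:
        return None
    if typ == "D":
        return datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    if typ == "N":
        return float(s) if ("." in s or "e" in s.lower()) else int(s)
    return s


def write_shapefile(
    basepath: str | Path,
    geoms: list[BaseGeometry],
    fields: list[FieldSpec],
    records: list[dict],
) -> None:
    """Write ``basepath``.shp/.shx/.dbf for a polygon layer."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)

    contents = [_polygon_record(g) if not g.is_empty else struct.pack("<i", _SHAPE_NULL)
                for g in geoms]
    if geoms:
        bounds = tuple(float(v) for v in shapely.total_bounds(geoms))
    else:
        bounds = (0.0, 0.0, 0.0, 0.0)

    shp_words = 50 + sum(4 + len(c) // 2 for c in contents)
    with open(base.with_suffix(".shp"), "wb") as f:
        f.write(_main_header(_SHAPE_POLYGON, shp_words, bounds))
        for num, content in enumerate(contents, start=1):
            f.write(struct.pack(">2i", num, len(content) // 2))
            f.write(content)

    with open(base.with_suffix(".shx"), "wb") as f:
        f.write(_main_header(_SHAPE_POLYGON, 50 + 4 * len(contents), bounds))
        offset = 50
        for content in contents:
            f.write(struct.pack(">2i", offset, len(content) // 2))
            offset += 4 + len(content) // 2

    reclen = 1 + sum(length for _, _, length, _ in fields)
    headerlen = 32 + 32 * len(fields) + 1
    today = datetime.date.today()
    with open(base.with_suffix(".dbf"), "wb") as f:
        f.write(
            struct.pack(
                "<4BIHH20x",
                0x03, today.year - 1900, today.month, today.day,
                len(records), headerlen, reclen,
            )
        )
        for name, typ, length, decimals in fields:
            f.write(struct.pack("<11sc4xBB14x", name.encode("ascii")[:11], typ.encode(), length, decimals))
        f.write(b"\x0d")
        for rec in records:
            f.write(b" ")
            for name, typ, length, decimals in fields:
                f.write(_dbf_encode(rec.get(name), typ, length, decimals))
        f.write(b"\x1a")


def read_shapefile(basepath: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    base = Path(basepath)
    geoms: list[BaseGeometry] = []
    with open(base.with_suffix(".shp"), "rb") as f:
        data = f.read()
    pos = 100
    while pos < len(data):
        _num, words = struct.unpack_from(">2i", data, pos)
        pos += 8
        shape_type = struct.unpack_from("<i", data, pos)[0]
        if shape_type == _SHAPE_NULL:
            geoms.append(shapely.Polygon())
        elif shape_type == _SHAPE_POLYGON:
            nparts, npoints = struct.unpack_from("<2i", data, pos + 36)
            parts = list(struct.unpack_from(f"<{nparts}i", data, pos + 44))
            pts_off = pos + 44 + 4 * nparts
            flat = struct.unpack_from(f"<{2 * npoints}d", data, pts_off)
            pts = list(zip(flat[::2], flat[1::2]))
            bounds_parts = parts + [npoints]
            rings = [pts[bounds_parts[k]:bounds_parts[k + 1]] for k in range(nparts)]
            geoms.append(_assemble(rings))
        else:
            raise ValueError(f"unsupported shape type {shape_type}")
        pos += 2 * words

    with open(base.with_suffix(".dbf"), "rb") as f:
        dbf = f.read()
    nrec, headerlen, reclen = struct.unpack_from("<IHH", dbf, 4)
    fields: list[FieldSpec] = []
    fpos = 32
    while dbf[fpos] != 0x0D:
        name, typ, length, decimals = struct.unpack_from("<11sc4xBB14x", dbf, fpos)
        fields.append((name.split(b"\x00")[0].decode("ascii"), typ.decode(), length, decimals))
        fpos += 32
    records = []
    for k in range(nrec):
        rpos = headerlen + k * reclen + 1  # skip deletion flag
        rec = {}
        for name, typ, length, _dec in fields:
            rec[name] = _dbf_decode(dbf[rpos:rpos + length], typ)
            rpos += length
        records.append(rec)
    return geoms, records


def read_features(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    """Shapefile layer as (geometry, attributes) features."""
    geoms, records = read_shapefile(Path(path).with_suffix(""))
    return list(zip(geoms, records))
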