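"""Minimal GeoPackage (SQLite) feature I/O for WGS84 polygon layers.

Implements just enough of the OGC GeoPackage encoding — the required
metadata tables plus the standard geometry blob header (magic ``GP``,
flags, srs_id, XY envelope, then WKB) — to write and read the layers this
package produces.
"""

from __future__ import annotations

import sqlite3
import struct
from pathlib import Path

import shapely
from shapely.geometry.base import BaseGeometry

_APPLICATION_ID = 0x47504B47  # "GPKG"
_USER_VERSION = 10300  # GeoPackage 1.3

_SRS_ROWS = [
    ("WGS 84 geodetic", 4326, "EPSG", 4326,
     'GEOGCS["WGS 84",DATUM["WGS_1984",SPHEROID["WGS 84",6378137,298.257223563]],'
     'PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433]]',
     "WGS84"),
    ("Undefined cartesian SRS", -1, "NONE", -1, "undefined", "undefined cartesian"),
    ("Undefined geographic SRS", 0, "NONE", 0, "undefined", "undefined geographic"),
]


def _encode_geometry(geom: BaseGeometry, srs_id: int = 4326) -> bytes:
    minx, miny, maxx, maxy = geom.bounds
    # flags: bit 0 = little-endian header, envelope indicator 1 (XY) in bits 1-3
    header = struct.pack("<2sBBi", b"GP", 0, 0b00000011, srs_id)
    envelope = struct.pack("<4d", minx, maxx, miny, maxy)
    return header + envelope + shapely.to_wkb(geom)


_ENVELOPE_DOUBLES = {0: 0, 1: 4, 2: 6, 3: 6, 4: 8}


def _decode_geometry(blob: bytes) -> BaseGeometry:
    magic, version, flags, _srs = struct.unpack_from("<2sBBi", blob, 0)
    if magic != b"GP":
        raise ValueError("not a GeoPackage geometry blob")
    env = (flags >> 1) & 0b111
    offset = 8 + 8 * _ENVELOPE_DOUBLES[env]
    return shapely.from_wkb(blob[offset:])


def _init_gpkg(con: sqlite3.Connection) -> None:
    con.execute(f"PRAGMA application_id = {_APPLICATION_ID}")
    con.execute(f"PRAGMA user_version = {_USER_VERSION}")
    con.execute(
        """CREATE TABLE IF NOT EXISTS gpkg_spatial_ref_sys (
            srs_name TEXT NOT NULL, srs_id INTEGER PRIMARY KEY,
            organization TEXT NOT NULL, organization_coordsys_id INTEGER NOT NULL,
            definition TEXT NOT NULL, description TEXT)"""
    )
    con.executemany(
        "INSERT OR IGNORE INTO gpkg_spatial_ref_sys VALUES (?,?,?,?,?,?)", _SRS_ROWS
    )
    con.execute(
        """CREATE TABLE IF NOT EXISTS gpkg_contents (
            table_name TEXT PRIMARY KEY, data_type TEXT NOT NULL,
            identifier TEXT UNIQUE, description TEXT DEFAULT '',
            last_change DATETIME DEFAULT (strftime('%Y-%m-%dT%H:%M:%fZ','now')),
            min_x DOUBLE, min_y DOUBLE, max_x DOUBLE, max_y DOUBLE,
            srs_id INTEGER)"""
    )
    con.execute(
        """CREATE TABLE IF NOT EXISTS gpkg_geometry_columns (
            table_name TEXT PRIMARY KEY, column_name TEXT NOT NULL,
            geometry_type_name TEXT NOT NULL, srs_id INTEGER NOT NULL,
            z TINYINT NOT NULL, m TINYINT NOT NULL)"""
    )


_SQL_TYPES = {int: "INTEGER", float: "REAL", str: "TEXT"}


def write_layer(
    path: str | Path,
    layer: str,
    schema: list[tuple[str, type]],
    features: list[tuple[BaseGeometry, dict]],
) -> None:
    """Append/replace one feature layer. ``schema`` is [(field, type), ...]."""
    path = Path(path)
    con = sqlite3.connect(path)
    try:
        _init_gpkg(con)
        cols = ", ".join(f'"{name}" {_SQL_TYPES[typ]}' for name, typ in schema)
        con.execute(f'DROP TABLE IF EXISTS "{layer}"')
        con.execute(
            f'CREATE TABLE "{layer}" '
            f"(fid INTEGER PRIMARY KEY AUTOINCREMENT, geom BLOB{', ' + cols if cols else ''})"
        )
        names = [name for name, _ in schema]
        placeholders = ", ".join("?" * (1 + len(names)))
        rows = [
            (_encode_geometry(geom), *[attrs.get(n) for n in names])
            for geom, attrs in features
        ]
        collist = ", ".join(['geom'] + [f'"{n}"' for n in names])
        con.executemany(f'INSERT INTO "{layer}" ({collist}) VALUES ({placeholders})', rows)
        if features:
            bounds = shapely.total_bounds([g for g, _ in features])
            minx, miny, maxx, maxy = (float(v) for v in bounds)
        else:
            minx = miny = maxx = maxy = None
        con.execute("DELETE FROM gpkg_contents WHERE table_name = ?", (layer,))
        con.execute(
            "INSERT INTO gpkg_contents "
            "(table_name, data_type, identifier, min_x, min_y, max_x, max_y, srs_id) "
            "VALUES (?, 'features', ?, ?, ?, ?, ?, 4326)",
            (layer, layer, minx, miny, maxx, maxy),
        )
        con.execute("DELETE FROM gpkg_geometry_columns WHERE table_name = ?", (layer,))
        con.execute(
            "INSERT INTO gpkg_geometry_columns VALUES (?, 'geom', 'MULTIPOLYGON', 4326, 0, 0)",
            (layer,),
        )
        con.commit()
    finally:
        con.close()


def list_layers(path: str | Path) -> list[str]:
    con = sqlite3.connect(Path(path))
    try:
        rows = con.execute(
            "SELECT table_name FROM gpkg_contents WHERE data_type = 'features' "
            "ORDER BY table_name"
        ).fetchall()
    finally:
        con.close()
    return [r[0] for r in rows]


def read_features(path: str | Path, layer: str) -> list[tuple[BaseGeometry, dict]]:
    con = sqlite3.connect(Path(path))
    con.row_factory = sqlite3.Row
    try:
        rows = con.execute(f'SELECT * FROM "{layer}" ORDER BY fid').fetchall()
    finally:
        con.close()
    out = []
    for row in rows:
        attrs = {k: row[k] for k in row.keys() if k not in ("fid", "geom")}
        out.append((_decode_geometry(row["geom"]), attrs))
    return out
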