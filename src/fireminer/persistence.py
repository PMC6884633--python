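"""Lossless simplification, the two-table yearly schema, and vector I/O.

Events are published as two record streams: *final* records (one row per
event: id, initial/final dates, final perimeter) and *daily* records (one
row per event-day, keyed by the event id). Both are partitioned by the
year of the event's INITIAL date, so a December→January fire sits wholly
in the earlier year's partition.

Before writing, geometries are simplified without information loss:
intermediate vertices lying on the same straight line are removed, which
is where most of the vertex budget of unioned raster cells goes.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import shapely
from shapely.geometry.base import BaseGeometry

from .event_core import EventSet, FireEvent, MinerState
from . import _gpkg, _shp

#: Absolute cross-product tolerance (degree coordinates) below which three
#: consecutive vertices count as collinear.
COLLINEAR_TOL = 1e-12


def _simplify_ring(coords: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Drop collinear intermediate vertices of a closed ring (circularly).

    A vertex is removed when the cross product of its incident edges is
    within tolerance AND the edges continue in the same direction (so
    zero-area spikes, which would change the perimeter, are kept).
    """
    pts = [tuple(c) for c in coords[:-1]]  # open ring
    # collapse consecutive duplicates first
    dedup = [p for k, p in enumerate(pts) if p != pts[k - 1]]
    pts = dedup if len(dedup) >= 3 else pts
    changed = True
    while changed and len(pts) > 3:
        changed = False
        kept = []
        n = len(pts)
        skip_next = False
        for k in range(n):
            if skip_next:
                skip_next = False
                kept.append(pts[k])
                continue
            ax, ay = pts[k - 1]
            bx, by = pts[k]
            cx, cy = pts[(k + 1) % n]
            ux, uy = bx - ax, by - ay
            vx, vy = cx - bx, cy - by
            cross = ux * vy - uy * vx
            dot = ux * vx + uy * vy
            if abs(cross) <= COLLINEAR_TOL and dot > 0:
                changed = True  # drop pts[k]
            else:
                kept.append(pts[k])
        if changed:
            pts = kept
            if len(pts) < 3:
                return [tuple(c) for c in coords]
    return pts + [pts[0]]


def simplify_lossless(geom: BaseGeometry) -> BaseGeometry:
    """Remove vertices not required to describe a polygonal geometry.

    Area and perimeter are preserved (removal of exactly-collinear points
    is exact up to floating-point round-off); vertex count never grows;
    idempotent.
    """
    if geom.is_empty:
        return geom

    def fix_poly(poly: shapely.Polygon) -> shapely.Polygon:
        shell = _simplify_ring(list(poly.exterior.coords))
        holes = [_simplify_ring(list(h.coords)) for h in poly.interiors]
        return shapely.Polygon(shell, holes)

    if isinstance(geom, shapely.Polygon):
        return fix_poly(geom)
    if isinstance(geom, shapely.MultiPolygon):
        return shapely.MultiPolygon([fix_poly(p) for p in geom.geoms])
    return geom


@dataclass(frozen=True)
class FinalRecord:
    """One row of the final-burnt-area table."""

    id: int
    initial_date: datetime.date
    final_date: datetime.date
    geom: BaseGeometry

    def __post_init__(self):
        if self.initial_date > self.final_date:
            raise ValueError("initial_date after final_date")
        if self.geom.is_empty:
            raise ValueError("empty final geometry")


@dataclass(frozen=True)
class DailyRecord:
    """One row of the daily-burnt-area table (id keys into FinalRecord)."""

    id: int
    day: datetime.date
    geom: BaseGeometry


class IntegrityError(ValueError):
    pass


def _as_multipolygon(geom: BaseGeometry) -> shapely.MultiPolygon:
    if isinstance(geom, shapely.Polygon):
        return shapely.MultiPolygon([geom])
    if isinstance(geom, shapely.MultiPolygon):
        return geom
    raise IntegrityError(f"non-polygonal geometry: {geom.geom_type}")


def to_tables(
    events: EventSet,
) -> tuple[dict[int, list[FinalRecord]], dict[int, list[DailyRecord]]]:
    """Final + daily records, each partitioned by the event's initial year."""
    seen: set[int] = set()
    finals: dict[int, list[FinalRecord]] = {}
    dailies: dict[int, list[DailyRecord]] = {}
    for event in events:
        if event.id in seen:
            raise IntegrityError(f"duplicate event id {event.id}")
        seen.add(event.id)
        year = event.initial_date.year
        final_geom = _as_multipolygon(simplify_lossless(event.final_geometry))
        finals.setdefault(year, []).append(
            FinalRecord(
                id=event.id,
                initial_date=event.initial_date,
                final_date=event.final_date,
                geom=final_geom,
            )
        )
        for day in event.dates():
            dailies.setdefault(year, []).append(
                DailyRecord(
                    id=event.id,
                    day=day,
                    geom=_as_multipolygon(simplify_lossless(event.daily[day])),
                )
            )
    return finals, dailies


_GPKG_SCHEMA = [("Id", int), ("InitialDate", str), ("FinalDate", str), ("IsDaily", int), ("Day", str)]
_SHP_FIELDS: list[_shp.FieldSpec] = [
    ("Id", "N", 18, 0),
    ("InitialDat", "D", 8, 0),
    ("FinalDate", "D", 8, 0),
    ("IsDaily", "N", 1, 0),
    ("Day", "D", 8, 0),
]


def write_vector(
    tables: tuple[dict[int, list[FinalRecord]], dict[int, list[DailyRecord]]],
    path: str | Path,
    format: str = "geopackage",
) -> None:
    """Write yearly layers ``final_<year>`` / ``daily_<year>``.

    GeoPackage (canonical): ``path`` is one .gpkg file holding every layer.
    Shapefile: ``path`` is a directory holding one .shp per layer (date
    attribute names are truncated to the 10-character DBF limit).
    """
    finals, dailies = tables
    date_by_id = {
        r.id: (r.initial_date, r.final_date) for recs in finals.values() for r in recs
    }
    if format in ("geopackage", "gpkg"):
        path = Path(path)
        if path.exists():
            path.unlink()
        for year in sorted(finals):
            feats = [
                (r.geom, {"Id": r.id, "InitialDate": r.initial_date.isoformat(),
                          "FinalDate": r.final_date.isoformat(), "IsDaily": 0, "Day": None})
                for r in finals[year]
            ]
            _gpkg.write_layer(path, f"final_{year}", _GPKG_SCHEMA, feats)
        for year in sorted(dailies):
            feats = [
                (r.geom, {"Id": r.id,
                          "InitialDate": date_by_id[r.id][0].isoformat(),
                          "FinalDate": date_by_id[r.id][1].isoformat(),
                          "IsDaily": 1, "Day": r.day.isoformat()})
                for r in dailies[year]
            ]
            _gpkg.write_layer(path, f"daily_{year}", _GPKG_SCHEMA, feats)
    elif format in ("shapefile", "shp"):
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        for year in sorted(finals):
            geoms = [r.geom for r in finals[year]]
            recs = [
                {"Id": r.id, "InitialDat": r.initial_date, "FinalDate": r.final_date,
                 "IsDaily": 0, "Day": None}
                for r in finals[year]
            ]
            _shp.write_shapefile(outdir / f"final_{year}", geoms, _SHP_FIELDS, recs)
        for year in sorted(dailies):
            geoms = [r.geom for r in dailies[year]]
            recs = [
                {"Id": r.id, "InitialDat": date_by_id[r.id][0],
                 "FinalDate": date_by_id[r.id][1], "IsDaily": 1, "Day": r.day}
                for r in dailies[year]
            ]
            _shp.write_shapefile(outdir / f"daily_{year}", geoms, _SHP_FIELDS, recs)
    else:
        raise ValueError(f"unknown format {format!r}")


def _parse_date(value) -> datetime.date:
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def read_vector(path: str | Path) -> EventSet:
    """Reconstruct an EventSet from layers written by :func:`write_vector`."""
    path = Path(path)
    features: list[tuple[BaseGeometry, dict]] = []
    if path.is_dir():
        for shp in sorted(path.glob("*.shp")):
            features.extend(_shp.read_features(shp))
    else:
        for layer in _gpkg.list_layers(path):
            features.extend(_gpkg.read_features(path, layer))

    daily: dict[int, dict[datetime.date, BaseGeometry]] = {}
    for geom, attrs in features:
        # DBF truncates "InitialDate"; accept either spelling
        is_daily = int(attrs.get("IsDaily") or 0)
        if not is_daily:
            continue
        eid = int(attrs["Id"])
        day = _parse_date(attrs["Day"])
        daily.setdefault(eid, {})[day] = geom
    events = [
        FireEvent(id=eid, daily=dmap, active=False) for eid, dmap in sorted(daily.items())
    ]
    return EventSet(events=events)


def save_state(state: MinerState, path: str | Path) -> None:
    """Checkpoint the active-fire array between executions (JSON container,
    geometries as WKB hex, dates ISO-8601)."""
    def event_obj(e: FireEvent) -> dict:
        return {
            "id": e.id,
            "active": e.active,
            "patch_uids": e.patch_uids,
            "daily": {
                d.isoformat(): shapely.to_wkb(g).hex() for d, g in sorted(e.daily.items())
            },
        }

    doc = {
        "format": "fireminer-state",
        "version": 1,
        "next_id": state.next_id,
        "last_period_end": state.last_period_end.isoformat() if state.last_period_end else None,
        "active_fires": [event_obj(e) for e in state.active_fires],
        "archived": [event_obj(e) for e in state.archived],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_state(path: str | Path) -> MinerState:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "fireminer-state":
        raise ValueError("not a fireminer state checkpoint")

    def event_from(obj: dict) -> FireEvent:
        return FireEvent(
            id=obj["id"],
            active=obj["active"],
            patch_uids=list(obj.get("patch_uids", [])),
            daily={
                datetime.date.fromisoformat(d): shapely.from_wkb(bytes.fromhex(w))
                for d, w in obj["daily"].items()
            },
        )

    return MinerState(
        active_fires=[event_from(o) for o in doc["active_fires"]],
        archived=[event_from(o) for o in doc["archived"]],
        next_id=doc["next_id"],
        last_period_end=(
            datetime.date.fromisoformat(doc["last_period_end"])
            if doc["last_period_end"]
            else None
        ),
    )
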