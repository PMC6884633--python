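"""Read burned-area products into normalized, deduplicated patch deliveries.

A *patch* is the atomic clustering element: a maximal set of touching
same-date burned pixels, polygonized. Vector products (e.g. the MCD64A1
Collection 6 Shapefile dialect, where ``BurnDate`` holds an ordinal
day-of-year) already ship patches as features; raster products ship a grid
of per-pixel burn-date codes that this module polygonizes itself.

All geometry is kept in geographic lon/lat degrees (WGS84): the clustering
threshold downstream is expressed in degrees, so no projection happens here.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

#: Burn-date codes at or below this value mean "not burned" (0 = unburned,
#: negative codes = unmapped / water in MCD64A1-style products).
UNBURNED_MAX_CODE = 0

_POLYGONAL = (shapely.Polygon, shapely.MultiPolygon)


class FormatError(ValueError):
    """Input file or grid does not satisfy the reader's contract."""


def canonical_wkb(geom: BaseGeometry) -> bytes:
    """Deterministic byte encoding of a geometry (normalized WKB).

    Used both for deduplication and as the tie-break in the Delivery sort
    order, so that event-id assignment is reproducible run to run.
    """
    return shapely.to_wkb(shapely.normalize(geom))


@dataclass(frozen=True)
class BurntPatch:
    """One dated burned polygon — the atomic clustering element.

    Parameters
    ----------
    geometry
        Polygon or multipolygon in lon/lat degrees; must be valid with
        strictly positive area (``normalize_patches`` enforces this).
    burn_date
        Concrete calendar date of the burn.
    source_tag
        Free string identifying the product/delivery of origin.
    uid
        Optional caller-assigned identity, preserved through the miner so
        that event membership of each input patch can be traced.
    """

    geometry: BaseGeometry
    burn_date: datetime.date
    source_tag: str = ""
    uid: int | None = None

    def sort_key(self) -> tuple:
        return (self.burn_date.toordinal(), canonical_wkb(self.geometry))


@dataclass(frozen=True)
class Delivery:
    """A temporally bounded, ordered batch of patches (one product release)."""

    patches: tuple[BurntPatch, ...]
    period_start: datetime.date
    period_end: datetime.date

    def __post_init__(self):
        if self.period_start > self.period_end:
            raise ValueError("period_start after period_end")
        for p in self.patches:
            if not (self.period_start <= p.burn_date <= self.period_end):
                raise ValueError(
                    f"patch dated {p.burn_date} outside delivery period "
                    f"[{self.period_start}, {self.period_end}]"
                )

    @property
    def is_empty(self) -> bool:
        return not self.patches


def _doy_to_date(doy: int, year: int) -> datetime.date:
    return datetime.date(year, 1, 1) + datetime.timedelta(days=int(doy) - 1)


def read_vector_burned_area(
    path: str | Path,
    date_field: str = "BurnDate",
    year: int | None = None,
    dialect: str = "mcd64a1_doy",
    source_tag: str | None = None,
) -> Delivery:
    """Read a polygon burned-area layer (Shapefile or GeoPackage) as a Delivery.

    ``dialect="mcd64a1_doy"`` interprets the date attribute as an ordinal
    day-of-year of ``year`` (the MCD64A1 vector convention); codes ≤ 0 mean
    unburned/invalid and those features are dropped. ``dialect="iso_date"``
    expects an ISO-8601 date string. The delivery period is the [min, max]
    of the retained dates; a file with zero retained features yields an
    empty delivery spanning ``year`` (or an empty unit period).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("mcd64a1_doy", "iso_date"):
        raise FormatError(f"unknown dialect {dialect!r}")
    if dialect == "mcd64a1_doy" and year is None:
        raise FormatError("dialect mcd64a1_doy requires a year")

    if path.suffix.lower() == ".gpkg":
        from . import _gpkg

        features = []
        for layer in _gpkg.list_layers(path):
            features.extend(_gpkg.read_features(path, layer))
    elif path.suffix.lower() == ".shp":
        from . import _shp

        features = _shp.read_features(path)
    else:
        raise FormatError(f"unsupported vector format: {path.suffix!r}")

    tag = source_tag if source_tag is not None else path.name
    patches = []
    for geom, attrs in features:
        if date_field not in attrs:
            raise FormatError(f"attribute {date_field!r} missing from feature")
        raw = attrs[date_field]
        if dialect == "mcd64a1_doy":
            code = int(raw)
            if code <= UNBURNED_MAX_CODE:
                continue
            date = _doy_to_date(code, year)
        else:
            date = raw if isinstance(raw, datetime.date) else datetime.date.fromisoformat(str(raw))
        patches.append(BurntPatch(geometry=geom, burn_date=date, source_tag=tag))

    patches = normalize_patches(patches)
    if not patches:
        day = datetime.date(year, 1, 1) if year else datetime.date(1970, 1, 1)
        return Delivery(patches=(), period_start=day, period_end=day)
    dates = [p.burn_date for p in patches]
    return Delivery(patches=tuple(patches), period_start=min(dates), period_end=max(dates))


def _cell_polygon(gt: Sequence[float], col0: int, row0: int, col1: int, row1: int) -> shapely.Polygon:
    """Polygon footprint of the cell block [col0,col1)x[row0,row1) under a
    GDAL-style geotransform (x0, dx, rxy, y0, ryx, dy)."""
    corners = []
    for c, r in ((col0, row0), (col1, row0), (col1, row1), (col0, row1)):
        x = gt[0] + gt[1] * c + gt[2] * r
        y = gt[3] + gt[4] * c + gt[5] * r
        corners.append((x, y))
    return shapely.Polygon(corners)


# 8-connectivity: corner contact joins pixels into one patch, matching the
# polygon "touches" predicate used downstream (corner contact is touching).
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def patches_from_raster(
    date_grid: np.ndarray,
    geotransform: Sequence[float],
    year: int,
    source_tag: str = "",
) -> list[BurntPatch]:
    """Polygonize a burn-date grid into per-date connected-component patches.

    Grid codes ≤ 0 mean not burned; positive codes are ordinal days of
    ``year``. Cells of the SAME date that touch under 8-connectivity form
    one patch whose geometry is the union of the cell footprints.
    """
    grid = np.asarray(date_grid)
    if grid.ndim != 2:
        raise FormatError("date_grid must be 2-D")
    gt = tuple(float(v) for v in geotransform)
    if len(gt) != 6:
        raise FormatError("geotransform must have 6 coefficients")
    det = gt[1] * gt[5] - gt[2] * gt[4]
    if det == 0:
        raise FormatError("non-invertible geotransform")

    patches: list[BurntPatch] = []
    for code in np.unique(grid):
        if code <= UNBURNED_MAX_CODE:
            continue
        mask = grid == code
        labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
        date = _doy_to_date(int(code), year)
        for comp in range(1, n + 1):
            rows, cols = np.nonzero(labels == comp)
            cells = [
                _cell_polygon(gt, c, r, c + 1, r + 1) for r, c in zip(rows.tolist(), cols.tolist())
            ]
            geom = shapely.unary_union(cells)
            patches.append(BurntPatch(geometry=geom, burn_date=date, source_tag=source_tag))
    return normalize_patches(patches)


def read_raster_burned_area(
    path: str | Path, year: int, source_tag: str | None = None
) -> list[BurntPatch]:
    """Read a single-band georeferenced GeoTIFF burn-date grid.

    The geotransform is taken from the GeoTIFF ModelPixelScale/ModelTiepoint
    tags; a grid without geotags gets the identity transform (one cell = one
    degree), which is mostly useful for tests.
    """
    import tifffile

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        gt = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
        if "ModelPixelScaleTag" in tags and "ModelTiepointTag" in tags:
            sx, sy, _ = tags["ModelPixelScaleTag"].value[:3]
            tie = tags["ModelTiepointTag"].value
            # tiepoint: (i, j, k, x, y, z) anchors raster (i, j) at model (x, y)
            i, j, _, x, y, _ = tie[:6]
            gt = (x - i * sx, sx, 0.0, y + j * sy, 0.0, -sy)
    tag = source_tag if source_tag is not None else path.name
    return patches_from_raster(grid, gt, year, source_tag=tag)


def normalize_patches(patches: Iterable[BurntPatch]) -> list[BurntPatch]:
    """Repair, deduplicate and deterministically order patches.

    Invalid geometries are repaired with :func:`shapely.make_valid`;
    anything non-polygonal or empty after repair is dropped with a logged
    warning. Exact duplicates (same burn date, same canonical WKB) collapse
    to one. Output is sorted by (burn_date, canonical WKB) — the Delivery
    ordering invariant. Idempotent.
    """
    out: list[BurntPatch] = []
    seen: set[tuple[int, bytes]] = set()
    for p in patches:
        geom = p.geometry
        if not geom.is_valid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                geom = shapely.make_valid(geom)
        if isinstance(geom, shapely.GeometryCollection):
            polys = [g for g in geom.geoms if isinstance(g, _POLYGONAL)]
            geom = shapely.unary_union(polys) if polys else shapely.Polygon()
        if geom.is_empty or not isinstance(geom, _POLYGONAL) or geom.area <= 0:
            logger.warning("dropping irreparable/degenerate patch dated %s", p.burn_date)
            continue
        key = (p.burn_date.toordinal(), canonical_wkb(geom))
        if key in seen:
            continue
        seen.add(key)
        out.append(replace(p, geometry=geom))
    out.sort(key=BurntPatch.sort_key)
    return out


def make_delivery(patches: Iterable[BurntPatch],
                  period_start: datetime.date | None = None,
                  period_end: datetime.date | None = None) -> Delivery:
    """Normalize patches and wrap them in a Delivery.

    The period defaults to the [min, max] of the patch dates.
    """
    norm = normalize_patches(patches)
    if not norm:
        if period_start is None or period_end is None:
            raise ValueError("empty patch set needs an explicit period")
        return Delivery(patches=(), period_start=period_start, period_end=period_end)
    dates = [p.burn_date for p in norm]
    return Delivery(
        patches=tuple(norm),
        period_start=period_start or min(dates),
        period_end=period_end or max(dates),
    )
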