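"""Seeded synthetic burned-area scenarios with known ground truth.

Patches are axis-aligned grid-cell rectangles in degrees (default cell
0.005° ≈ MODIS 500 m at the equator), so truth labels are provable by
construction and areas are exact. Generators cover the behaviours an
event miner must get right: daily spread, spotting (disjoint parts within
eps), rekindling (same footprint days apart), and two ignitions growing
together. A scenario packs patches into monthly-style deliveries and can
optionally be re-cut along an arbitrary rectangular tiling — the failure
mode of per-tile event identification — without changing the truth.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

from .ingest import BurntPatch, Delivery, normalize_patches

#: Default synthetic cell size in degrees (≈ MODIS 500 m at the equator).
CELL_DEG = 0.005

#: Default miner thresholds the generators' truth labels are built for.
TRUTH_EPS_DEG = 0.01
TRUTH_T_JOIN_DAYS = 5

Date = datetime.date
_POLYGONAL = (shapely.Polygon, shapely.MultiPolygon)


def _box(x0: float, y0: float, w: float, h: float) -> shapely.Polygon:
    return shapely.box(x0, y0, x0 + w, y0 + h)


def make_spreading_fire(
    origin: tuple[float, float],
    start_date: Date,
    n_days: int = 3,
    cells_per_day: int = 3,
    cell_size_deg: float = CELL_DEG,
) -> tuple[list[BurntPatch], list[int]]:
    """One fire spreading as daily strips; consecutive-day patches touch.

    Day k burns a row of ``cells_per_day`` cells stacked edge-to-edge on
    top of day k−1's row. Returns (patches, per-patch truth labels) — all
    zeros: a single event.
    """
    x0, y0 = origin
    s = cell_size_deg
    patches = [
        BurntPatch(
            geometry=_box(x0, y0 + k * s, cells_per_day * s, s),
            burn_date=start_date + datetime.timedelta(days=k),
            source_tag="synthetic",
        )
        for k in range(n_days)
    ]
    return patches, [0] * n_days


def make_spotting_fire(
    origin: tuple[float, float],
    start_date: Date,
    gap_deg: float = 0.005,
    date_offset_days: int = 0,
    cell_size_deg: float = CELL_DEG,
) -> tuple[list[BurntPatch], list[int]]:
    """A fire plus a disjoint spot separated by ``gap_deg``.

    Truth: one event when the gap is within the default eps (0.01°) and
    the dates within the default 5-day join window; two otherwise.
    """
    x0, y0 = origin
    s = cell_size_deg
    main = BurntPatch(_box(x0, y0, s, s), start_date, "synthetic")
    spot = BurntPatch(
        _box(x0 + s + gap_deg, y0, s, s),
        start_date + datetime.timedelta(days=date_offset_days),
        "synthetic",
    )
    joined = gap_deg <= TRUTH_EPS_DEG and abs(date_offset_days) <= TRUTH_T_JOIN_DAYS
    return [main, spot], [0, 0 if joined else 1]


def make_rekindle(
    origin: tuple[float, float],
    date1: Date,
    date2: Date,
    cell_size_deg: float = CELL_DEG,
) -> tuple[list[BurntPatch], list[int]]:
    """The same footprint burned twice; one event iff |date2−date1| ≤ 5."""
    x0, y0 = origin
    footprint = _box(x0, y0, 2 * cell_size_deg, 2 * cell_size_deg)
    joined = abs((date2 - date1).days) <= TRUTH_T_JOIN_DAYS
    return (
        [BurntPatch(footprint, date1, "synthetic"), BurntPatch(footprint, date2, "synthetic")],
        [0, 0 if joined else 1],
    )


def make_merging_fires(
    origin: tuple[float, float],
    start_date: Date,
    meet_day: int = 2,
    stop_a_after: int | None = None,
    cell_size_deg: float = CELL_DEG,
) -> tuple[list[BurntPatch], list[int]]:
    """Two ignitions growing toward each other along a line.

    Each fire advances three cell columns per day (so the closing gap
    stays above eps until the fronts actually meet). With both fires
    burning, the fronts touch on ``meet_day``: one event. With
    ``stop_a_after`` days, the left fire stops early and the right fire
    keeps marching into its footprint; truth is a single event only if the
    contact happens within the 5-day join window of the stopped front.
    """
    x0, y0 = origin
    s = cell_size_deg
    m = meet_day
    M = 6 * m + 5  # total column span; fronts touch exactly on meet_day
    n_a = (m + 1) if stop_a_after is None else stop_a_after
    if n_a < 1 or n_a > m + 1:
        raise ValueError("stop_a_after must be in [1, meet_day+1]")
    n_b = (m + 1) if stop_a_after is None else (2 * m - n_a + 2)

    fire_a = [
        BurntPatch(
            _box(x0 + 3 * i * s, y0, 3 * s, s),
            start_date + datetime.timedelta(days=i),
            "synthetic",
        )
        for i in range(n_a)
    ]
    fire_b = [
        BurntPatch(
            _box(x0 + (M - 3 * j - 2) * s, y0, 3 * s, s),
            start_date + datetime.timedelta(days=j),
            "synthetic",
        )
        for j in range(n_b)
    ]
    # truth from the two designed fronts: joined iff some patch pair is
    # simultaneously within eps and within the join window
    joined = any(
        shapely.distance(pa.geometry, pb.geometry) <= TRUTH_EPS_DEG
        and abs((pa.burn_date - pb.burn_date).days) <= TRUTH_T_JOIN_DAYS
        for pa in fire_a
        for pb in fire_b
    )
    labels = [0] * len(fire_a) + ([0] * len(fire_b) if joined else [1] * len(fire_b))
    return fire_a + fire_b, labels


GENERATORS = {
    "spread": make_spreading_fire,
    "spotting": make_spotting_fire,
    "rekindle": make_rekindle,
    "merging": make_merging_fires,
}


@dataclass
class Scenario:
    """Deliveries plus ground truth (patch uid → event label) and the seed."""

    deliveries: list[Delivery]
    truth: dict[int, int] | None
    seed: int

    @property
    def patches(self) -> list[BurntPatch]:
        return [p for d in self.deliveries for p in d.patches]

    def fingerprint(self) -> bytes:
        """Deterministic byte serialization (regeneration must reproduce it)."""
        parts = []
        for d in self.deliveries:
            parts.append(d.period_start.isoformat().encode())
            parts.append(d.period_end.isoformat().encode())
            for p in d.patches:
                parts.append(p.burn_date.isoformat().encode())
                parts.append(shapely.to_wkb(shapely.normalize(p.geometry)))
                parts.append(str(p.uid).encode())
        if self.truth is not None:
            parts.append(repr(sorted(self.truth.items())).encode())
        return b"\x00".join(parts)


def _clip_to_tiles(
    patches: list[BurntPatch],
    labels: list[int],
    tiling: tuple[int, int],
) -> tuple[list[BurntPatch], list[int]]:
    nx, ny = tiling
    xs = shapely.total_bounds([p.geometry for p in patches])
    minx, miny, maxx, maxy = xs
    pad = 1e-6
    minx, miny, maxx, maxy = minx - pad, miny - pad, maxx + pad, maxy + pad
    xedges = np.linspace(minx, maxx, nx + 1)
    yedges = np.linspace(miny, maxy, ny + 1)
    out_p: list[BurntPatch] = []
    out_l: list[int] = []
    for patch, lab in zip(patches, labels):
        for i in range(nx):
            for j in range(ny):
                tile = shapely.box(xedges[i], yedges[j], xedges[i + 1], yedges[j + 1])
                piece = patch.geometry.intersection(tile)
                if piece.is_empty:
                    continue
                if isinstance(piece, shapely.GeometryCollection):
                    polys = [g for g in piece.geoms if isinstance(g, _POLYGONAL)]
                    if not polys:
                        continue
                    piece = shapely.unary_union(polys)
                if not isinstance(piece, _POLYGONAL) or piece.area <= 0:
                    continue
                out_p.append(
                    BurntPatch(piece, patch.burn_date, patch.source_tag, uid=None)
                )
                out_l.append(lab)
    return out_p, out_l


def make_scenario(
    specs: Sequence[tuple[str, dict]],
    delivery_span_days: int = 31,
    tiling: tuple[int, int] | None = None,
    seed: int = 0,
) -> Scenario:
    """Assemble fires into a delivery sequence with global truth labels.

    ``specs`` is a list of ("spread"|"spotting"|"rekindle"|"merging",
    kwargs) pairs. Patches are assigned to consecutive
    ``delivery_span_days``-day windows by burn date. With ``tiling``
    (nx, ny), every patch is clipped into per-tile pieces WITHOUT changing
    the truth labels — the miner must undo the split.
    """
    patches: list[BurntPatch] = []
    labels: list[int] = []
    next_label = 0
    for kind, kwargs in specs:
        fire_patches, local = GENERATORS[kind](**kwargs)
        patches.extend(fire_patches)
        labels.extend(next_label + l for l in local)
        next_label += (max(local) + 1) if local else 0

    if not patches:
        return Scenario(deliveries=[], truth={}, seed=seed)

    if tiling is not None:
        patches, labels = _clip_to_tiles(patches, labels, tiling)

    # deterministic uid assignment in canonical patch order; exact
    # duplicates (same date, same geometry — e.g. a same-day rekindle)
    # collapse here exactly as the ingest normalizer would collapse them
    order = sorted(range(len(patches)), key=lambda k: patches[k].sort_key())
    truth: dict[int, int] = {}
    with_uids: list[BurntPatch] = []
    seen: set[tuple] = set()
    uid = 0
    for k in order:
        p = patches[k]
        key = p.sort_key()
        if key in seen:
            continue
        seen.add(key)
        with_uids.append(BurntPatch(p.geometry, p.burn_date, p.source_tag, uid=uid))
        truth[uid] = labels[k]
        uid += 1

    deliveries = _window_deliveries(with_uids, delivery_span_days)
    return Scenario(deliveries=deliveries, truth=truth, seed=seed)


def _window_deliveries(patches: list[BurntPatch], span_days: int) -> list[Delivery]:
    t0 = min(p.burn_date for p in patches)
    t_end = max(p.burn_date for p in patches)
    deliveries = []
    start = t0
    while start <= t_end:
        end = start + datetime.timedelta(days=span_days - 1)
        window = [p for p in patches if start <= p.burn_date <= end]
        deliveries.append(
            Delivery(
                patches=tuple(normalize_patches(window)),
                period_start=start,
                period_end=end,
            )
        )
        start = end + datetime.timedelta(days=1)
    return deliveries


def pool_deliveries(deliveries: Sequence[Delivery]) -> Delivery:
    """All patches of a delivery sequence as one batch delivery."""
    patches = [p for d in deliveries for p in d.patches]
    return Delivery(
        patches=tuple(normalize_patches(patches)),
        period_start=min(d.period_start for d in deliveries),
        period_end=max(d.period_end for d in deliveries),
    )


def random_scenario(
    n_fires: int,
    seed: int,
    delivery_span_days: int = 31,
    tiling: tuple[int, int] | None = None,
    base_date: Date = datetime.date(2017, 1, 5),
) -> Scenario:
    """Random mixture of generator kinds on a well-separated lattice.

    Fires sit on a 0.3° lattice with jitter, far enough apart that
    different fires can never join: the truth partition is exact by
    construction. Dates spread over ~4 months so several deliveries occur.
    """
    rng = np.random.default_rng(seed)
    kinds = ["spread", "spotting", "rekindle", "merging"]
    side = int(np.ceil(np.sqrt(n_fires)))
    specs: list[tuple[str, dict]] = []
    for k in range(n_fires):
        gx, gy = k % side, k // side
        ox = gx * 0.3 + rng.uniform(-0.05, 0.05)
        oy = gy * 0.3 + rng.uniform(-0.05, 0.05)
        start = base_date + datetime.timedelta(days=int(rng.integers(0, 120)))
        kind = kinds[int(rng.integers(0, len(kinds)))]
        if kind == "spread":
            specs.append(
                (kind, dict(origin=(ox, oy), start_date=start,
                            n_days=int(rng.integers(1, 7)),
                            cells_per_day=int(rng.integers(1, 5)))),
            )
        elif kind == "spotting":
            specs.append(
                (kind, dict(origin=(ox, oy), start_date=start,
                            gap_deg=float(rng.choice([0.004, 0.008, 0.02, 0.03])),
                            date_offset_days=int(rng.integers(0, 9)))),
            )
        elif kind == "rekindle":
            specs.append(
                (kind, dict(origin=(ox, oy), date1=start,
                            date2=start + datetime.timedelta(days=int(rng.integers(1, 10))))),
            )
        else:
            meet = int(rng.integers(1, 4))
            stop = None if rng.random() < 0.5 else int(rng.integers(1, meet + 2))
            specs.append(
                (kind, dict(origin=(ox, oy), start_date=start,
                            meet_day=meet, stop_a_after=stop)),
            )
    return make_scenario(specs, delivery_span_days=delivery_span_days,
                         tiling=tiling, seed=seed)


def random_patch_scenario(
    n_patches: int,
    seed: int,
    span_deg: float = 0.12,
    n_days: int = 45,
    delivery_span_days: int = 31,
    base_date: Date = datetime.date(2017, 3, 1),
    cell_size_deg: float = CELL_DEG,
) -> Scenario:
    """Dense random cells with no designed truth — oracle stress input.

    Random positions in a ``span_deg`` square and random dates over
    ``n_days`` produce rich, unplanned connectivity; the reference
    partition comes from an independent brute-force oracle, not from the
    generator.
    """
    rng = np.random.default_rng(seed)
    patches = []
    for _ in range(n_patches):
        x = float(rng.uniform(0, span_deg))
        y = float(rng.uniform(0, span_deg))
        date = base_date + datetime.timedelta(days=int(rng.integers(0, n_days)))
        patches.append(BurntPatch(_box(x, y, cell_size_deg, cell_size_deg), date, "synthetic"))
    order = sorted(range(len(patches)), key=lambda k: patches[k].sort_key())
    with_uids = [
        BurntPatch(patches[k].geometry, patches[k].burn_date, "synthetic", uid=uid)
        for uid, k in enumerate(order)
    ]
    return Scenario(
        deliveries=_window_deliveries(with_uids, delivery_span_days),
        truth=None,
        seed=seed,
    )
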