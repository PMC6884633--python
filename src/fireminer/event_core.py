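"""Incremental spatio-temporal clustering of burned patches into fire events.

The workflow per delivery: active fires and new patches enter a spatial
index (step 0); candidate pairs found by bounding-box search yield a sparse
pairwise distance matrix compressed by rows (step 1); the eps-thresholded
graph is clustered — with a minimum cluster size of one this is exactly
connected components (step 2); labels are applied back onto the fire array
(extend / create / merge) and fires inactive for longer than the archive
threshold are retired (step 3).

Two thresholds define an event: patches closer than ``eps_deg`` (default
0.01°) in space AND no more than ``t_join_days`` (default 5) apart in time
belong to the same fire; a fire with no additions for more than
``t_archive_days`` (default 16) is archived and can never absorb new
patches. Because the archive threshold exceeds the join threshold, the
incremental per-delivery run produces the same partition as pooling all
patches into a single batch.

A pair involving a fire is joinable only if some of the fire's daily parts
is simultaneously close in space and in time to the other element: the
stored pair distance is the minimum spatial distance over *temporally
admissible* daily pairs. This keeps event membership identical to
patch-level connectivity (a patch near an old flank of a long fire but
dated far from any burn there does not join).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, Union

import numpy as np
import shapely
from scipy.sparse import coo_array, csr_array
from scipy.sparse.csgraph import connected_components
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .ingest import BurntPatch, Delivery

Element = Union["FireEvent", BurntPatch]

#: (lon, lat) -> (eps_deg, t_join_days); per-location threshold hook.
ThresholdProvider = Callable[[float, float], tuple[float, int]]


@dataclass(frozen=True)
class ClusterConfig:
    """Thresholds that define a fire event.

    eps_deg
        Spatial join threshold in degrees (constant worldwide by default).
    t_join_days
        Patches further apart in time than this belong to different fires;
        a gap of exactly ``t_join_days`` still joins (separation requires
        *more than* this many days).
    t_archive_days
        A fire with no additions for more than this many days (strictly) is
        archived. Must be ≥ ``t_join_days`` for incremental processing to
        match batch processing.
    min_elements
        Minimum cluster size. Only 1 is supported: every patch founds or
        joins an event, and clustering reduces to connected components.
    threshold_provider
        Optional per-location override returning (eps_deg, t_join_days) for
        a representative point; a pair of elements uses the larger of its
        two elements' thresholds.
    """

    eps_deg: float = 0.01
    t_join_days: int = 5
    t_archive_days: int = 16
    min_elements: int = 1
    threshold_provider: ThresholdProvider | None = None

    def __post_init__(self):
        if self.eps_deg <= 0:
            raise ValueError("eps_deg must be positive")
        if self.t_archive_days < self.t_join_days:
            raise ValueError("t_archive_days must be >= t_join_days")
        if self.min_elements < 1:
            raise ValueError("min_elements must be >= 1")

    def thresholds_at(self, geom: BaseGeometry) -> tuple[float, int]:
        if self.threshold_provider is None:
            return self.eps_deg, self.t_join_days
        pt = geom.representative_point()
        return self.threshold_provider(pt.x, pt.y)


@dataclass
class FireEvent:
    """An identified fire: daily evolution plus derived dates and perimeter.

    ``daily`` maps each calendar date to that day's burned multipolygon
    (same-date patches are unioned). ``patch_uids`` accumulates the ``uid``
    of every input patch absorbed, for provenance/testing.
    """

    id: int
    daily: dict[datetime.date, BaseGeometry]
    active: bool = True
    patch_uids: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.daily:
            raise ValueError("FireEvent.daily must be non-empty")

    @property
    def initial_date(self) -> datetime.date:
        return min(self.daily)

    @property
    def final_date(self) -> datetime.date:
        return max(self.daily)

    @property
    def final_geometry(self) -> BaseGeometry:
        return shapely.unary_union(list(self.daily.values()))

    def dates(self) -> list[datetime.date]:
        return sorted(self.daily)


def _daily_parts(el: Element) -> list[tuple[datetime.date, BaseGeometry]]:
    if isinstance(el, BurntPatch):
        return [(el.burn_date, el.geometry)]
    return sorted(el.daily.items())


def element_geometry(el: Element) -> BaseGeometry:
    return el.geometry if isinstance(el, BurntPatch) else el.final_geometry


def temporal_gap(a: Element, b: Element) -> int:
    """Minimum day gap between the dated parts of two elements (always ≥ 0).

    Patch vs patch is |date₁ − date₂|; a fire contributes every one of its
    daily dates, so the gap to a fire is the distance to its *nearest*
    daily date, not only its last one.
    """
    da = [d.toordinal() for d, _ in _daily_parts(a)]
    db = [d.toordinal() for d, _ in _daily_parts(b)]
    return min(abs(x - y) for x in da for y in db)


def admissible_distance(a: Element, b: Element, t_join_days: int) -> float | None:
    """Minimum spatial distance over temporally admissible daily pairs.

    Returns ``None`` when no pair of dated parts is within ``t_join_days``
    (the elements are temporally unreachable). For two patches this is the
    plain geometry distance gated by the date gap.
    """
    parts_a = _daily_parts(a)
    parts_b = _daily_parts(b)
    best: float | None = None
    for da, ga in parts_a:
        for db, gb in parts_b:
            if abs((da - db).days) > t_join_days:
                continue
            d = shapely.distance(ga, gb)
            if best is None or d < best:
                best = d
                if best == 0.0:
                    return 0.0
    return best


@dataclass
class SparseDistance:
    """Row-compressed pairwise candidate distances (CSR layout).

    ``n`` elements in deterministic order (active fires first, then new
    patches). ``indptr``/``indices``/``data`` are standard CSR arrays; the
    matrix is symmetric and complete for every pair within eps and t_join
    (it may additionally hold candidate entries with distance > eps).
    ``pair_eps`` carries the per-entry spatial threshold (varies only when
    a threshold provider is configured).
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    data: np.ndarray
    pair_eps: np.ndarray

    @classmethod
    def from_entries(
        cls, n: int, entries: Iterable[tuple[int, int, float, float]]
    ) -> "SparseDistance":
        """Build from (i, j, distance, eps) tuples with i < j; symmetrized."""
        rows: list[int] = []
        cols: list[int] = []
        dist: list[float] = []
        eps: list[float] = []
        for i, j, d, e in entries:
            rows += [i, j]
            cols += [j, i]
            dist += [d, d]
            eps += [e, e]
        order = np.lexsort((np.asarray(cols, dtype=np.int64), np.asarray(rows, dtype=np.int64)))
        rows_a = np.asarray(rows, dtype=np.int64)[order]
        cols_a = np.asarray(cols, dtype=np.int64)[order]
        dist_a = np.asarray(dist, dtype=float)[order]
        eps_a = np.asarray(eps, dtype=float)[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, rows_a + 1, 1)
        indptr = np.cumsum(indptr)
        return cls(n=n, indptr=indptr, indices=cols_a, data=dist_a, pair_eps=eps_a)

    def row(self, i: int) -> list[tuple[int, float]]:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return list(zip(self.indices[lo:hi].tolist(), self.data[lo:hi].tolist()))

    def to_scipy(self) -> csr_array:
        return csr_array(
            (self.data.copy(), self.indices.copy(), self.indptr.copy()), shape=(self.n, self.n)
        )

    def adjacency(self) -> csr_array:
        """Adjacency of the pairs within their spatial threshold.

        Candidate entries beyond eps are removed from the sparsity
        structure entirely (graph routines treat any stored entry,
        including an explicit zero, as an edge).
        """
        rows = np.repeat(np.arange(self.n, dtype=np.int64), np.diff(self.indptr))
        keep = self.data <= self.pair_eps
        return coo_array(
            (np.ones(int(keep.sum()), dtype=np.int8), (rows[keep], self.indices[keep])),
            shape=(self.n, self.n),
        ).tocsr()


class SpatialIndex:
    """Bounding-box index over elements (STR-packed R-tree)."""

    def __init__(self, elements: Sequence[Element]):
        self.elements = list(elements)
        self._geoms = [element_geometry(e) for e in self.elements]
        self._tree = STRtree(self._geoms) if self._geoms else None

    def __len__(self) -> int:
        return len(self.elements)

    def geometry(self, i: int) -> BaseGeometry:
        return self._geoms[i]

    def query(self, minx: float, miny: float, maxx: float, maxy: float) -> list[int]:
        """Indices of elements whose bounding box intersects the rectangle."""
        if self._tree is None:
            return []
        box = shapely.box(minx, miny, maxx, maxy)
        return sorted(int(i) for i in self._tree.query(box))


def index_elements(
    active_fires: Sequence[FireEvent], patches: Sequence[BurntPatch]
) -> SpatialIndex:
    """Spatial index over active fires then new patches (deterministic order)."""
    return SpatialIndex(list(active_fires) + list(patches))


def build_distance_matrix(index: SpatialIndex, config: ClusterConfig) -> SparseDistance:
    """Sparse candidate distances among the indexed elements.

    Candidates for each element come from querying its bounding box
    expanded by eps on all sides (a plain bbox-intersection query would
    miss near-but-disjoint pairs within eps, e.g. spotting). Pairs whose
    dated parts are all further apart than t_join are temporally
    unreachable and omitted entirely.
    """
    elements = index.elements
    thresholds = [config.thresholds_at(index.geometry(i)) for i in range(len(elements))]
    entries: list[tuple[int, int, float, float]] = []
    for i, el in enumerate(elements):
        eps_i = thresholds[i][0]
        minx, miny, maxx, maxy = index.geometry(i).bounds
        for j in index.query(minx - eps_i, miny - eps_i, maxx + eps_i, maxy + eps_i):
            if j <= i:
                continue
            pair_eps = max(eps_i, thresholds[j][0])
            pair_t = max(thresholds[i][1], thresholds[j][1])
            d = admissible_distance(el, elements[j], pair_t)
            if d is None:
                continue
            entries.append((i, j, d, pair_eps))
    return SparseDistance.from_entries(len(elements), entries)


def cluster_labels(dist: SparseDistance, config: ClusterConfig) -> np.ndarray:
    """Cluster elements on the eps-thresholded distance graph.

    With a minimum cluster size of 1 no element is noise and the density
    clustering reduces exactly to connected components; the label of a
    component is its smallest member index, so labels are deterministic
    given element order.
    """
    if config.min_elements != 1:
        raise NotImplementedError("only min_elements=1 is supported")
    if dist.n == 0:
        return np.empty(0, dtype=np.int64)
    n_comp, comp = connected_components(dist.adjacency(), directed=False)
    # relabel: component label = smallest member index
    first = np.full(n_comp, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, comp, np.arange(dist.n, dtype=np.int64))
    return first[comp]


@dataclass
class MinerState:
    """Active fires, the append-only archive, and the id counter."""

    active_fires: list[FireEvent] = field(default_factory=list)
    archived: list[FireEvent] = field(default_factory=list)
    next_id: int = 1
    last_period_end: datetime.date | None = None

    def all_events(self) -> list[FireEvent]:
        return self.archived + self.active_fires


class ConsistencyError(RuntimeError):
    pass


class OrderingError(ValueError):
    """Deliveries (or archive reference dates) arrived out of order."""


def _merge_daily(
    into: dict[datetime.date, BaseGeometry], date: datetime.date, geom: BaseGeometry
) -> None:
    if date in into:
        into[date] = shapely.unary_union([into[date], geom])
    else:
        into[date] = geom


def apply_labels(
    labels: np.ndarray,
    active_fires: Sequence[FireEvent],
    patches: Sequence[BurntPatch],
    state: MinerState,
) -> MinerState:
    """Turn cluster labels into fire-array updates.

    Per label group: patches alone found a new event (fresh id from the
    monotone counter); one fire plus patches extends that fire; several
    fires merge into the one with the SMALLEST id (other ids are retired,
    never reused). Same-date geometries are unioned into one daily entry.
    """
    n_fires = len(active_fires)
    n = n_fires + len(patches)
    if len(labels) != n:
        raise ConsistencyError("labels do not cover all elements")
    for f in active_fires:
        if not f.active:
            raise ConsistencyError(f"archived fire #{f.id} present in active array")

    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels.tolist()):
        groups.setdefault(lab, []).append(idx)

    surviving: list[FireEvent] = []
    next_id = state.next_id
    for lab in sorted(groups):
        members = groups[lab]
        fires = [active_fires[i] for i in members if i < n_fires]
        group_patches = [patches[i - n_fires] for i in members if i >= n_fires]
        if fires:
            target = min(fires, key=lambda f: f.id)
            daily = dict(target.daily)
            uids = list(target.patch_uids)
            for other in fires:
                if other is not target:
                    for d, g in other.daily.items():
                        _merge_daily(daily, d, g)
                    uids.extend(other.patch_uids)
            event_id = target.id
        else:
            daily = {}
            uids = []
            event_id = next_id
            next_id += 1
        for p in group_patches:
            _merge_daily(daily, p.burn_date, p.geometry)
            if p.uid is not None:
                uids.append(p.uid)
        surviving.append(FireEvent(id=event_id, daily=daily, active=True, patch_uids=uids))

    surviving.sort(key=lambda f: f.id)
    return MinerState(
        active_fires=surviving,
        archived=state.archived,
        next_id=next_id,
        last_period_end=state.last_period_end,
    )


def archive_inactive(
    state: MinerState, reference_date: datetime.date, config: ClusterConfig
) -> MinerState:
    """Retire fires with no additions for more than t_archive_days.

    Strict inequality: a gap of exactly ``t_archive_days`` keeps the fire
    active. Keeping borderline fires active can never change clustering
    because joining already requires a gap ≤ t_join_days ≤ t_archive_days.
    """
    still_active: list[FireEvent] = []
    archived = list(state.archived)
    for f in state.active_fires:
        gap = (reference_date - f.final_date).days
        if gap < 0:
            raise OrderingError(
                f"reference date {reference_date} earlier than fire #{f.id} final date"
            )
        if gap > config.t_archive_days:
            f.active = False
            archived.append(f)
        else:
            still_active.append(f)
    return MinerState(
        active_fires=still_active,
        archived=archived,
        next_id=state.next_id,
        last_period_end=state.last_period_end,
    )


def process_delivery(
    state: MinerState, delivery: Delivery, config: ClusterConfig | None = None
) -> MinerState:
    """One execution step: index → distances → labels → update → archive."""
    config = config or ClusterConfig()
    if state.last_period_end is not None and delivery.period_start <= state.last_period_end:
        raise OrderingError(
            f"delivery starting {delivery.period_start} does not follow "
            f"previous period end {state.last_period_end}"
        )
    index = index_elements(state.active_fires, delivery.patches)
    dist = build_distance_matrix(index, config)
    labels = cluster_labels(dist, config)
    state = apply_labels(labels, state.active_fires, delivery.patches, state)
    state = archive_inactive(state, delivery.period_end, config)
    state.last_period_end = delivery.period_end
    return state


@dataclass
class EventSet:
    """Archive of finished events plus any events still active at the end."""

    events: list[FireEvent]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def archived(self) -> list[FireEvent]:
        return [e for e in self.events if not e.active]

    @property
    def still_active(self) -> list[FireEvent]:
        return [e for e in self.events if e.active]

    def partition(self) -> dict[int, int]:
        """Map patch uid → event id (patches that carried a uid)."""
        out: dict[int, int] = {}
        for e in self.events:
            for uid in e.patch_uids:
                out[uid] = e.id
        return out

    def by_id(self, event_id: int) -> FireEvent:
        for e in self.events:
            if e.id == event_id:
                return e
        raise KeyError(event_id)


def run(
    deliveries: Iterable[Delivery], config: ClusterConfig | None = None
) -> EventSet:
    """Fold the per-delivery step over an ordered delivery sequence.

    Remaining active fires are flushed into the result still flagged
    active, so the EventSet always covers every input patch.
    """
    config = config or ClusterConfig()
    state = MinerState()
    for delivery in deliveries:
        state = process_delivery(state, delivery, config)
    events = state.archived + state.active_fires
    events.sort(key=lambda e: e.id)
    return EventSet(events=events)
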