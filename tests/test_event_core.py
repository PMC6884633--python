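import datetime

import numpy as np
import pytest
import shapely

from fireminer import event_core as ec
from fireminer.event_core import (
    ClusterConfig,
    FireEvent,
    MinerState,
    SparseDistance,
    apply_labels,
    archive_inactive,
    build_distance_matrix,
    cluster_labels,
    index_elements,
    process_delivery,
    run,
    temporal_gap,
)
from fireminer.ingest import BurntPatch, make_delivery
from fireminer import synthfire

from _oracle import UnionFind, bruteforce_partition, partitions_equal

D = datetime.date


def day(n: int) -> D:
    return D(2017, 1, 1) + datetime.timedelta(days=n - 1)


def fire(fid: int, entries: dict) -> FireEvent:
    return FireEvent(id=fid, daily=dict(entries))


def sq(x0, y0=0.0, size=0.005):
    return shapely.box(x0, y0, x0 + size, y0 + size)


class TestTemporalGap:
    def test_patch_vs_patch_absolute_difference(self, square_patch):
        a = square_patch(date=D(2017, 1, 3))
        b = square_patch(x0=1.0, date=D(2017, 1, 9))
        assert temporal_gap(a, b) == 6

    def test_fire_vs_patch_uses_nearest_daily_date(self, square_patch):
        f = fire(1, {day(k): sq(0) for k in range(1, 7)})  # Jan 1..6
        p = square_patch(date=day(8))
        assert temporal_gap(f, p) == 2

    def test_identity_gap_is_zero(self, square_patch):
        p = square_patch()
        assert temporal_gap(p, p) == 0
        f = fire(1, {day(1): sq(0), day(9): sq(1)})
        assert temporal_gap(f, f) == 0


class TestSpatialIndex:
    def test_empty_index_returns_nothing(self):
        index = index_elements([], [])
        assert index.query(-180, -90, 180, 90) == []

    def test_query_own_bbox_finds_element(self, square_patch):
        index = index_elements([], [square_patch()])
        assert index.query(0, 0, 0.005, 0.005) == [0]

    def test_disjoint_query_is_empty(self, square_patch):
        index = index_elements([], [square_patch()])
        assert index.query(1.0, 1.0, 2.0, 2.0) == []

    def test_order_is_fires_then_patches(self, square_patch):
        f = fire(7, {day(1): sq(0.5)})
        p = square_patch()
        index = index_elements([f], [p])
        assert index.elements[0] is f and index.elements[1] is p


class TestDistanceMatrix:
    def test_touching_squares_two_days_apart_have_zero_entry(self, config, square_patch):
        a = square_patch(0.0, date=day(1))
        b = square_patch(0.005, date=day(3))  # shares an edge
        dist = build_distance_matrix(index_elements([], [a, b]), config)
        assert dist.row(0) == [(1, 0.0)]
        assert dist.row(1) == [(0, 0.0)]

    def test_eps_expanded_query_finds_disjoint_bboxes(self, config, square_patch):
        # 0.005 degrees apart: bounding boxes do not intersect, but the
        # eps-expanded candidate query must still produce the pair
        a = square_patch(0.0, date=day(1))
        b = square_patch(0.010, date=day(1))
        dist = build_distance_matrix(index_elements([], [a, b]), config)
        assert dist.row(0) == [(1, pytest.approx(0.005))]

    def test_pairs_beyond_join_window_are_omitted(self, config, square_patch):
        a = square_patch(0.0, date=day(1))
        b = square_patch(0.005, date=day(7))  # touching, 6 days apart
        dist = build_distance_matrix(index_elements([], [a, b]), config)
        assert dist.row(0) == [] and dist.row(1) == []

    def test_symmetric_and_complete_on_random_points(self, config):
        rng = np.random.default_rng(7)
        patches = [
            BurntPatch(sq(rng.uniform(0, 0.08), rng.uniform(0, 0.08)),
                       day(int(rng.integers(1, 12))))
            for _ in range(40)
        ]
        dist = build_distance_matrix(index_elements([], patches), config)
        entries = {
            (i, j): d for i in range(dist.n) for j, d in dist.row(i)
        }
        for (i, j), d in entries.items():
            assert entries[(j, i)] == d
        # completeness: every within-eps within-t_join pair present
        for i in range(len(patches)):
            for j in range(i + 1, len(patches)):
                gap = abs((patches[i].burn_date - patches[j].burn_date).days)
                d = shapely.distance(patches[i].geometry, patches[j].geometry)
                if gap <= config.t_join_days and d <= config.eps_deg:
                    assert (i, j) in entries

    def test_fire_patch_edge_requires_joint_space_time_admissibility(self, config):
        # a long fire: burned at x=0 on day 1 and (via a chain) at x=1 on day 20;
        # a patch at x=0 on day 22 is spatially near the day-1 flank only, and
        # temporally near the day-20 flank only -> no edge
        f = fire(1, {day(1): sq(0.0), day(20): sq(1.0)})
        p = BurntPatch(sq(0.0, 0.006), day(22))
        dist = build_distance_matrix(index_elements([f], [p]), config)
        # the candidate entry may exist but its admissible distance is the
        # ~1 degree to the day-20 flank, far beyond eps: no join
        assert all(d > config.eps_deg for _, d in dist.row(0))
        # but a patch near the day-20 flank does join
        p2 = BurntPatch(sq(1.0, 0.006), day(22))
        dist2 = build_distance_matrix(index_elements([f], [p2]), config)
        assert dist2.row(0) == [(1, pytest.approx(0.001))]


class TestClusterLabels:
    def _dist(self, n, entries, eps=0.01):
        return SparseDistance.from_entries(n, [(i, j, d, eps) for i, j, d in entries])

    def test_chain_transitivity_single_label(self, config):
        dist = self._dist(3, [(0, 1, 0.005), (1, 2, 0.005), (0, 2, 0.02)])
        labels = cluster_labels(dist, config)
        assert labels.tolist() == [0, 0, 0]

    def test_isolated_element_gets_singleton_label(self, config):
        dist = self._dist(2, [])
        assert cluster_labels(dist, config).tolist() == [0, 1]

    def test_labels_equal_unionfind_components_on_random_graph(self, config):
        rng = np.random.default_rng(11)
        n = 50
        entries = []
        uf = UnionFind(n)
        for _ in range(60):
            i, j = sorted(rng.integers(0, n, 2).tolist())
            if i == j:
                continue
            d = float(rng.uniform(0, 0.02))
            entries.append((i, j, d))
            if d <= config.eps_deg:
                uf.union(i, j)
        labels = cluster_labels(self._dist(n, entries), config)
        roots = [uf.find(i) for i in range(n)]
        assert labels.tolist() == roots  # smallest-member labelling matches

    def test_matches_density_clustering_with_precomputed_matrix(self, config):
        pytest.importorskip("sklearn")
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(3)
        n = 60
        entries = []
        for _ in range(80):
            i, j = sorted(rng.integers(0, n, 2).tolist())
            if i != j:
                # strictly positive distances: sparse precomputed input treats
                # stored zeros as absent
                entries.append((i, j, float(rng.uniform(1e-6, 0.02))))
        dist = self._dist(n, entries)
        ours = cluster_labels(dist, config)
        db = DBSCAN(eps=config.eps_deg, min_samples=1, metric="precomputed")
        theirs = db.fit_predict(dist.to_scipy().tocsr(copy=True))
        assert partitions_equal(
            dict(enumerate(ours.tolist())), dict(enumerate(theirs.tolist()))
        )

    def test_min_elements_above_one_unsupported(self):
        cfg = ClusterConfig(min_elements=2)
        with pytest.raises(NotImplementedError):
            cluster_labels(SparseDistance.from_entries(1, []), cfg)


class TestApplyLabels:
    def test_patches_only_create_event_with_daily_map(self, square_patch):
        patches = [square_patch(date=day(1), uid=0), square_patch(0.005, date=day(2), uid=1)]
        state = apply_labels(np.array([0, 0]), [], patches, MinerState())
        [event] = state.active_fires
        assert event.id == 1
        assert event.initial_date == day(1) and event.final_date == day(2)
        assert len(event.daily) == 2
        assert state.next_id == 2

    def test_merge_keeps_smallest_id(self, square_patch):
        f3 = fire(3, {day(1): sq(0)})
        f7 = fire(7, {day(2): sq(0.005)})
        p = square_patch(0.010, date=day(2))
        state = MinerState(active_fires=[f3, f7], next_id=8)
        out = apply_labels(np.array([0, 0, 0]), [f3, f7], [p], state)
        [event] = out.active_fires
        assert event.id == 3
        assert event.final_date == day(2)
        assert out.next_id == 8  # retired id 7 never reused, counter untouched

    def test_same_date_geometries_unioned(self, square_patch):
        f3 = fire(3, {day(1): sq(0)})
        p = square_patch(0.005, date=day(1))
        out = apply_labels(np.array([0, 0]), [f3], [p], MinerState(active_fires=[f3], next_id=4))
        [event] = out.active_fires
        assert len(event.daily) == 1
        assert event.daily[day(1)].area == pytest.approx(2 * 0.005 ** 2)

    def test_label_coverage_enforced(self, square_patch):
        with pytest.raises(ec.ConsistencyError):
            apply_labels(np.array([0]), [], [square_patch(), square_patch(0.1)], MinerState())


class TestArchiveInactive:
    def test_gap_over_threshold_archives(self, config):
        f = fire(1, {day(1): sq(0)})
        state = archive_inactive(MinerState(active_fires=[f], next_id=2), day(18), config)
        assert state.active_fires == [] and [e.id for e in state.archived] == [1]
        assert state.archived[0].active is False

    def test_gap_exactly_threshold_stays_active(self, config):
        f = fire(1, {day(1): sq(0)})
        state = archive_inactive(MinerState(active_fires=[f], next_id=2), day(17), config)
        assert [e.id for e in state.active_fires] == [1] and state.archived == []

    def test_empty_state_unchanged(self, config):
        state = archive_inactive(MinerState(), day(1), config)
        assert state.active_fires == [] and state.archived == []

    def test_reference_before_final_date_rejected(self, config):
        f = fire(1, {day(10): sq(0)})
        with pytest.raises(ec.OrderingError):
            archive_inactive(MinerState(active_fires=[f]), day(5), config)


class TestProcessDelivery:
    def test_single_patch_founds_event_one(self, config, square_patch):
        delivery = make_delivery([square_patch(uid=0)])
        state = process_delivery(MinerState(), delivery, config)
        assert [f.id for f in state.active_fires] == [1]

    def test_nearby_patch_extends_fire_without_new_id(self, config, square_patch):
        state = process_delivery(
            MinerState(), make_delivery([square_patch(date=day(10))]), config
        )
        delivery2 = make_delivery(
            [square_patch(x0=0.005, date=day(13))],
            period_start=day(11), period_end=day(40),
        )
        state = process_delivery(state, delivery2, config)
        assert state.next_id == 2
        [f] = state.all_events()
        assert len(f.daily) == 2

    def test_out_of_order_delivery_rejected(self, config, square_patch):
        state = process_delivery(MinerState(), make_delivery([square_patch()]), config)
        with pytest.raises(ec.OrderingError):
            process_delivery(state, make_delivery([square_patch(date=day(1))]), config)

    def test_empty_delivery_only_archives(self, config, square_patch):
        state = process_delivery(
            MinerState(), make_delivery([square_patch(date=day(1))]), config
        )
        empty = make_delivery([], period_start=day(2), period_end=day(40))
        state = process_delivery(state, empty, config)
        assert state.active_fires == [] and len(state.archived) == 1


class TestRun:
    def test_no_deliveries_empty_eventset(self, config):
        assert len(run([], config)) == 0

    def test_fire_spanning_two_deliveries_is_one_event(self, config, square_patch):
        d1 = make_delivery(
            [square_patch(date=day(30), uid=0)], period_start=day(1), period_end=day(31)
        )
        d2 = make_delivery(
            [square_patch(0.005, date=day(32), uid=1)],
            period_start=day(32), period_end=day(62),
        )
        events = run([d1, d2], config)
        assert len(events) == 1
        assert sorted(events.events[0].patch_uids) == [0, 1]

    def test_reburn_months_apart_is_two_events(self, config, square_patch):
        d1 = make_delivery(
            [square_patch(date=D(2017, 3, 10))],
            period_start=D(2017, 3, 1), period_end=D(2017, 3, 31),
        )
        d2 = make_delivery(
            [square_patch(date=D(2017, 6, 10))],
            period_start=D(2017, 6, 1), period_end=D(2017, 6, 30),
        )
        assert len(run([d1, d2], config)) == 2

    def test_multi_ignition_fires_meeting_while_active_merge(self, config):
        patches, labels = synthfire.make_merging_fires((0, 0), day(1), meet_day=2)
        assert set(labels) == {0}
        events = run([make_delivery(patches)], config)
        assert len(events) == 1


class TestInvariants:
    def test_partition_no_patch_lost_or_duplicated(self, config):
        scenario = synthfire.random_patch_scenario(80, seed=5)
        events = run(scenario.deliveries, config)
        uids = sorted(uid for e in events for uid in e.patch_uids)
        assert uids == list(range(80))

    def test_union_area_conserved(self, config):
        scenario = synthfire.random_patch_scenario(60, seed=9)
        events = run(scenario.deliveries, config)
        union_events = shapely.unary_union([e.final_geometry for e in events])
        union_inputs = shapely.unary_union([p.geometry for p in scenario.patches])
        assert union_events.area == pytest.approx(union_inputs.area, rel=1e-9)

    def test_matches_bruteforce_on_dense_scenario(self, config):
        scenario = synthfire.random_patch_scenario(120, seed=2)
        events = run(scenario.deliveries, config)
        oracle = bruteforce_partition(
            scenario.patches, eps=config.eps_deg, t_join=config.t_join_days
        )
        assert partitions_equal(events.partition(), oracle)

    @pytest.mark.parametrize("eps2, t2", [(0.02, 5), (0.01, 8), (0.03, 10)])
    def test_enlarging_thresholds_never_increases_event_count(self, config, eps2, t2):
        scenario = synthfire.random_patch_scenario(100, seed=4)
        base = len(run(scenario.deliveries, config))
        wider = len(
            run(scenario.deliveries, ClusterConfig(eps_deg=eps2, t_join_days=t2,
                                                   t_archive_days=16))
        )
        assert wider <= base

    def test_daily_component_graph_connected(self, config):
        # FireEvent invariant: the daily-dated parts of one event form a
        # connected graph under (<= eps, <= t_join) edges
        scenario = synthfire.random_patch_scenario(80, seed=13)
        events = run(scenario.deliveries, config)
        for event in events:
            parts = sorted(event.daily.items())
            n = len(parts)
            uf = UnionFind(n)
            for i in range(n):
                for j in range(i + 1, n):
                    gap = abs((parts[i][0] - parts[j][0]).days)
                    d = shapely.distance(parts[i][1], parts[j][1])
                    if gap <= config.t_join_days and d <= config.eps_deg:
                        uf.union(i, j)
            assert len({uf.find(i) for i in range(n)}) == 1


class TestThresholdProvider:
    def test_location_dependent_eps_changes_joins(self):
        # northern fires get a wider eps than southern ones
        def provider(lon, lat):
            return (0.03, 5) if lat > 1.0 else (0.01, 5)

        cfg = ClusterConfig(threshold_provider=provider)
        south = [BurntPatch(sq(0.0, 0.0), day(1)), BurntPatch(sq(0.02, 0.0), day(1))]
        north = [BurntPatch(sq(0.0, 2.0), day(1)), BurntPatch(sq(0.02, 2.0), day(1))]
        events = run([make_delivery(south + north)], cfg)
        assert len(events) == 3  # south pair split, north pair joined
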