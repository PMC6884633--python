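# Methods

## Event model

A fire event is a set of burned patches connected in space and time. The
atomic element is the patch: a maximal group of touching same-date burned
pixels, polygonized (8-connectivity — corner contact counts as touching,
which matches the polygon `touches` predicate the vector side uses). An
event carries a daily map (date → that day's burned multipolygon, same-date
patches unioned), from which the initial date, final date and final
perimeter (union of dailies) are derived.

Connectivity is pairwise: two elements join when their minimum spatial
distance is at most `eps_deg` AND their dates differ by at most
`t_join_days`. Transitivity does the rest — a fire can therefore have
several ignition points, and spatially disjoint spotting parts within eps
belong to the same event. The partition of patches into events is exactly
the connected components of the (≤ eps, ≤ t_join) graph; this equivalence
is the backbone of the test suite (a brute-force all-pairs union-find is
the reference).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `eps_deg` | 0.01 | degrees | spatial join threshold, constant worldwide |
| `t_join_days` | 5 | days | temporal join threshold; a gap of exactly 5 joins, separation requires more than 5 |
| `t_archive_days` | 16 | days | inactivity (strictly greater) after which a fire is archived |
| `min_elements` | 1 | — | minimum cluster size; only 1 is supported |

Distances are computed in degree space with no geodesic correction — the
eps threshold is defined in degrees, so a metric correction would change
its meaning. The per-location hook `threshold_provider`
(`(lon, lat) → (eps_deg, t_join_days)`) lets regional authorities supply
their own thresholds; a pair of elements uses the larger of its two
elements' thresholds so the relation stays symmetric. No calibration is
shipped.

Boundary semantics worth stating exactly:

- join: gap ≤ 5 days joins (separation only when *more than* 5 days apart);
- archive: gap > 16 days archives, a gap of exactly 16 keeps the fire
  active. Keeping borderline fires active can never change the partition,
  because joining already requires ≤ t_join ≤ t_archive; it only costs a
  slightly larger active array.

## Incremental workflow

Per delivery: (0) active fires and new patches enter a bounding-box index
(shapely's STR-packed tree; element order is deterministic — active fires
sorted by id, then patches in canonical order). (1) Each element queries
its bounding box **expanded by eps on all sides**; a plain bbox-intersection
query would miss near-but-disjoint pairs within eps (spotting), so the
expansion is the minimal correction that makes the candidate set complete.
Candidate pairs within the temporal window get their spatial distance
stored in a symmetric CSR matrix; temporally unreachable pairs are omitted.
(2) Labels are the connected components of the eps-thresholded graph
(scipy's sparse `connected_components`); with minimum cluster size 1 this
is provably identical to density-based clustering on the precomputed
matrix, and a cross-check test runs scikit-learn's DBSCAN
(`metric="precomputed"`, `min_samples=1`) against it. A component's label
is its smallest member index, so labelling is order-deterministic.
(3) Labels update the fire array: patch-only groups found a new event (ids
from a monotone counter), groups with one fire extend it, groups with
several fires merge them keeping the smallest id (retired ids are never
reused). (4) Fires quiet for more than `t_archive_days`, measured against
the delivery's period end (archival is tied to execution steps, not wall
clock), are archived.

**Pair distance for fires.** The distance stored for a pair involving a
fire is the minimum spatial distance over *temporally admissible* daily
pairs (daily dates within t_join of the other element's dates), not the
whole-geometry distance gated by the overall minimum date gap. The two
differ for long fires: a patch can be spatially near an old flank but
temporally near only the recent front — crossing space from one daily and
time from another would create a join no constituent patch pair justifies.
The admissible-pair form keeps fire-level connectivity exactly equal to
patch-level connectivity, which is what makes the incremental run
reproduce the batch partition. For patch–patch pairs the two definitions
coincide.

**Incremental = batch.** Ordered, non-overlapping deliveries plus
t_archive ≥ t_join guarantee that an archived fire is temporally
unreachable from every later patch (later patches are dated after the
period end, hence > t_archive > t_join days after the fire's last burn), so
archiving never removes a possible edge and the per-delivery fold equals
one pooled batch run. Both directions are tested.

## Persistence

Final perimeters and daily areas are written as two record streams
partitioned by the year of the event's initial date. Geometry
simplification removes vertices whose incident edges are collinear
(absolute cross-product tolerance 1e-12 in degree coordinates) and
continuing in the same direction — the direction test keeps zero-area
spikes, whose removal would change the perimeter. The pass repeats until
stable (removing a vertex can make its neighbour removable), never emits a
ring with fewer than 3 distinct vertices, and preserves area and perimeter
to 1e-12 relative.

The canonical output is a GeoPackage with layers `final_<year>` /
`daily_<year>` and attributes `Id, InitialDate, FinalDate, IsDaily, Day`
(ISO-8601 dates); a Shapefile export mirrors it (DBF truncates
`InitialDate` to `InitialDat`, dates use the DBF date type). Both
round-trip through the bundled readers. The GeoPackage and Shapefile
codecs are self-contained (stdlib sqlite3 + WKB, and struct-level
.shp/.shx/.dbf); they implement only what these layers need: polygon
geometries, WGS84, and N/C/D attribute types. Miner state between
executions checkpoints to JSON with WKB-hex geometries.

## Statistics

Hectares come from a Lambert cylindrical equal-area projection on the
authalic sphere (R = 6 371 007.181 m; x = Rλ, y = R sin φ), exact on the
sphere and within ~0.6 % of the WGS84 ellipsoidal area for cells between
60°S and 60°N (frozen geodesic reference values in the tests). "Fire
spread speed" is not uniquely defined by the product; it is implemented as
the **maximum daily burned area per day** (ha/day), with the mean daily
growth (area/duration) also exposed for max-of-mean aggregation. Regional
summaries count an event in every region its final perimeter intersects.
The agricultural filter keeps an event iff its non-agricultural burned
area is ≥ 10 % of the total AND > 100 ha; land cover arrives through a
pluggable per-event function (a grid-sampling adapter is provided) so no
specific land-cover raster is a dependency.

## Synthetic scenarios

The generator emits axis-aligned grid-cell patches (default cell 0.005° ≈
MODIS 500 m at the equator), so truth labels are provable by construction
and areas exact. Behaviours: daily strip spread; spotting (a disjoint part
at a controlled gap and date offset); rekindling (same footprint twice);
two ignitions whose fronts advance three columns per day toward each other
— the closing gap stays above eps until the fronts actually meet, and with
an early-stopping fire the join/split truth follows from a direct
geometric check over the two designed chains. Random scenarios place fires
on a 0.3° lattice with jitter, far enough apart that distinct fires can
never interact; dense "stress" scenarios drop random cells in a small
window with no designed truth and are judged against the brute-force
oracle instead. Scenario generation is seed-deterministic byte for byte; a
tiling option clips every patch along an n×m rectangular grid without
changing truth labels, reproducing the per-tile splitting artifact an
event miner must not exhibit.

What the synthetic data does *not* emulate: real burn-date noise and
multi-day detection lag, irregular patch shapes, pixel-level QA,
projection distortion of real MODIS tiles, and land-cover heterogeneity.
Passing tests therefore demonstrate the correctness of the event-mining
logic under the stated thresholds, not the remote-sensing accuracy of any
specific product.

## Problem sizes and numerical choices

Tests and the acceptance script run scenarios of 50–200 patches (dense
stress cases) and 20–100 fires (ground-truth cases), 1 000 random
rectilinear unions for simplification, and 100 seeded oracle-equivalence
scenarios — sizes chosen so the full suite completes in seconds while
still producing multi-delivery, multi-event state. Degenerate inputs:
invalid geometries are repaired with `make_valid` (area preserved),
zero-area or non-polygonal remnants are dropped with a warning, exact
duplicate patches (same date, same canonical WKB) collapse to one, and
empty deliveries advance only the archival clock. Antimeridian-crossing
geometries are not rejoined across ±180° — a known limitation.

## Limitations

- Degree-space distances make eps slightly anisotropic away from the
  equator; the per-location threshold hook is the intended remedy.
- Only `min_elements = 1` is implemented; other density parameters raise.
- Hierarchical labelling of fire complexes (nested clustering passes) is
  out of scope.
- The Shapefile writer supports polygon layers with N/C/D fields only.
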