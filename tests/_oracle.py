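"""Independent reference implementations used only to check the package.

These deliberately share no code with the library: partitions come from a
brute-force all-pairs union-find, raster components from a BFS flood fill,
areas from a plain shoelace sum.
"""

from __future__ import annotations

from collections import defaultdict, deque

import numpy as np
import shapely


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def bruteforce_partition(patches, eps: float = 0.01, t_join: int = 5) -> dict[int, int]:
    """Patch uid -> component label from all-pairs (space, time) edges."""
    n = len(patches)
    geoms = np.array([p.geometry for p in patches], dtype=object)
    days = np.array([p.burn_date.toordinal() for p in patches])
    uf = UnionFind(n)
    for i in range(n - 1):
        close_t = np.abs(days[i + 1:] - days[i]) <= t_join
        if not close_t.any():
            continue
        js = np.nonzero(close_t)[0] + i + 1
        dists = shapely.distance(geoms[i], geoms[js])
        for j in js[dists <= eps]:
            uf.union(i, int(j))
    return {patches[i].uid: uf.find(i) for i in range(n)}


def groups_of(partition: dict) -> set[frozenset]:
    by_label = defaultdict(set)
    for key, lab in partition.items():
        by_label[lab].add(key)
    return set(map(frozenset, by_label.values()))


def partitions_equal(p1: dict, p2: dict) -> bool:
    """Same grouping of the same keys, labels ignored."""
    return groups_of(p1) == groups_of(p2)


def flood_fill_components(grid: np.ndarray) -> int:
    """Number of same-date 8-connected components of positive cells (BFS)."""
    grid = np.asarray(grid)
    seen = np.zeros(grid.shape, dtype=bool)
    count = 0
    nrow, ncol = grid.shape
    for r0 in range(nrow):
        for c0 in range(ncol):
            if grid[r0, c0] <= 0 or seen[r0, c0]:
                continue
            count += 1
            code = grid[r0, c0]
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < nrow and 0 <= cc < ncol
                            and not seen[rr, cc] and grid[rr, cc] == code
                        ):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
    return count


def shoelace_area(geom) -> float:
    """Planar area of a (multi)polygon summed ring by ring."""
    polys = list(geom.geoms) if isinstance(geom, shapely.MultiPolygon) else [geom]
    total = 0.0
    for poly in polys:
        rings = [(list(poly.exterior.coords), 1.0)]
        rings += [(list(h.coords), -1.0) for h in poly.interiors]
        for coords, sign in rings:
            s = 0.0
            for (x1, y1), (x2, y2) in zip(coords[:-1], coords[1:]):
                s += x1 * y2 - x2 * y1
            total += sign * abs(s) / 2.0
    return total


def count_vertices(geom) -> int:
    return len(shapely.get_coordinates(geom))
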