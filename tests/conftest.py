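import datetime

import numpy as np
import pytest
import shapely

from fireminer.event_core import ClusterConfig
from fireminer.ingest import BurntPatch


@pytest.fixture
def config() -> ClusterConfig:
    return ClusterConfig()


@pytest.fixture
def square_patch():
    def factory(x0=0.0, y0=0.0, size=0.005, date=datetime.date(2017, 1, 1), uid=None):
        return BurntPatch(
            geometry=shapely.box(x0, y0, x0 + size, y0 + size),
            burn_date=date,
            uid=uid,
        )

    return factory


def random_rectilinear_union(rng: np.random.Generator, max_cells: int = 20):
    """Union of random grid cells: staircase outlines full of collinear points."""
    n = int(rng.integers(2, max_cells + 1))
    cells = set()
    r, c = 0, 0
    while len(cells) < n:
        cells.add((r, c))
        dr, dc = rng.choice([(0, 1), (1, 0), (0, -1), (-1, 0)])
        r, c = r + int(dr), c + int(dc)
    boxes = [shapely.box(c * 0.01, r * 0.01, (c + 1) * 0.01, (r + 1) * 0.01) for r, c in cells]
    return shapely.unary_union(boxes)
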