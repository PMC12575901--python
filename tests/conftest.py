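import numpy as np
import pytest
from shapely.geometry import Polygon, box

import mapseg as ms


@pytest.fixture(scope="session")
def unit_square() -> Polygon:
    return box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def region_map(unit_square) -> ms.RegionMap:
    return ms.build_region_map(unit_square, n_regions=10, seed=7)


def make_graph_map(edges, n_regions) -> ms.RegionMap:
    """RegionMap with a prescribed adjacency graph (geometry is a stand-in;
    only the adjacency matters for selection logic)."""
    polys = tuple(box(i, 0, i + 1, 1) for i in range(n_regions))
    return ms.RegionMap(outline=box(0, 0, n_regions, 1), regions=polys,
                        adjacency=frozenset(tuple(sorted(e)) for e in edges),
                        seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """Five experiment 2 stimuli, 20 participants, change-driven presses."""
    designs = ms.enumerate_design(2)[:5]
    series = {d.stimulus_id: ms.generate_series(d) for d in designs}
    params = ms.ResponseModelParams(change_gain=4.0, congruence_gain=0.0,
                                    participant_sd=0.2)
    logs = ms.simulate_cohort(designs, series, 20, params, seed=5)
    binned, audit = ms.bin_cohort(logs, {d.stimulus_id: 30 for d in designs})
    return designs, series, logs, binned, audit
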