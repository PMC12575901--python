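"""Stimulus generators: region geometry and per-region value dynamics.

The stimuli are animated choropleth maps. A map outline is partitioned into
regions with a Voronoi tessellation; each region carries a per-second value
in [0, 1] (a keyframe series; rendering at higher frame rates interpolates
between keyframes and is out of analysis scope). Three experimental designs
are supported:

* experiment 1 — a semi-random piecewise-linear global trend shared by all
  regions, plus per-region Gaussian noise, min-max rescaled to [0, 1];
* experiment 2 — a systematically varied linear whole-map trend drawn from
  an 8-point grid, noise added and truncated (clipped) to [0, 1] so the
  nominal trend is preserved;
* experiment 3 — the trend confined to a clustered or distributed subset of
  3-4 regions, the remainder holding a stable level plus noise.
"""

from __future__ import annotations

import itertools
import zlib
import struct
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

__all__ = [
    "RegionMap",
    "ValueSeries",
    "StimulusDesign",
    "EXP2_TREND_GRID",
    "EXP3_TREND_GRID",
    "build_region_map",
    "generate_exp1_series",
    "feasible_start_range",
    "generate_exp2_series",
    "select_changing_regions",
    "generate_exp3_series",
    "enumerate_design",
    "generate_series",
]

# Trend grids: 8 equally spaced points on [-1, 1] rounded to 2 decimals
# (experiment 2) and a coarse 4-point grid (experiment 3).
EXP2_TREND_GRID = tuple(round(x, 2) for x in np.linspace(-1.0, 1.0, 8))
EXP3_TREND_GRID = (-1.0, -0.5, 0.5, 1.0)

_BORDER_NOISE_FRAC = 0.01  # jitter amplitude as a fraction of outline diameter


def _substream(seed: int, *purpose: int) -> np.random.Generator:
    """Deterministic sub-stream of a root seed, one per purpose."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *purpose])


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMap:
    """A polygon partition of an outline into regions with adjacency.

    ``regions[i]`` is the (possibly border-jittered) polygon of region ``i``;
    ``adjacency`` is a symmetric, irreflexive shared-border relation computed
    on the pre-noise Voronoi cells.
    """

    outline: Polygon
    regions: tuple[Polygon, ...]
    adjacency: frozenset[tuple[int, int]]
    seed: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def neighbors(self, i: int) -> set[int]:
        return {b for a, b in self.adjacency if a == i} | {
            a for a, b in self.adjacency if b == i
        }

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(self.adjacency)
        return g

    def to_geojson(self) -> dict:
        feats = []
        for i, poly in enumerate(self.regions):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [list(map(list, poly.exterior.coords))],
                    },
                    "properties": {
                        "region_id": i,
                        "neighbors": sorted(self.neighbors(i)),
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def _vertex_jitter(x: float, y: float, seed: int, amplitude: float) -> tuple[float, float]:
    """Deterministic displacement keyed on the (rounded) vertex coordinates.

    Vertices shared by neighboring regions hash identically, so both copies
    move together and the partition is preserved.
    """
    key = struct.pack("<qqq", int(round(x * 1e9)), int(round(y * 1e9)), seed)
    h = zlib.crc32(key)
    angle = 2.0 * np.pi * ((h & 0xFFFF) / 0x10000)
    radius = amplitude * (((h >> 16) & 0xFFFF) / 0x10000)
    return x + radius * np.cos(angle), y + radius * np.sin(angle)


def _jitter_polygon(poly: Polygon, outline: Polygon, seed: int, amplitude: float,
                    segment_len: float) -> Polygon:
    ring = poly.exterior.segmentize(segment_len)
    coords = list(ring.coords)[:-1]
    out = []
    boundary = outline.exterior
    for x, y in coords:
        if boundary.distance(Point(x, y)) < 1e-9:
            out.append((x, y))  # outline vertices stay put
        else:
            out.append(_vertex_jitter(x, y, seed, amplitude))
    return Polygon(out)


def build_region_map(outline: Polygon, n_regions: int = 10, seed: int = 0) -> RegionMap:
    """Partition ``outline`` into ``n_regions`` Voronoi regions.

    Seed points are drawn uniformly inside the outline; regions are the
    Voronoi cells of those points clipped to the outline, with cosmetic
    seed-deterministic border jitter. Adjacency (shared borders of positive
    length) is computed on the pre-noise cells.
    """
    outline = Polygon(outline)
    if not outline.is_valid or outline.area <= 0:
        raise ValueError("outline must be a simple closed polygon with positive area")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")

    if n_regions == 1:
        return RegionMap(outline=outline, regions=(outline,), adjacency=frozenset(),
                         seed=seed)

    rng = _substream(seed, 1)
    minx, miny, maxx, maxy = outline.bounds
    pts: list[Point] = []
    while len(pts) < n_regions:
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if outline.contains(p):
            pts.append(p)

    cells_raw = voronoi_diagram(MultiPoint(pts), envelope=outline)
    # voronoi_diagram returns cells in arbitrary order; match each cell to
    # its generating point so region ids follow the sampling order.
    cells: list[Polygon | None] = [None] * n_regions
    for cell in cells_raw.geoms:
        for i, p in enumerate(pts):
            if cells[i] is None and cell.contains(p):
                cells[i] = cell.intersection(outline)
                break
    if any(c is None for c in cells):  # pragma: no cover - degenerate tie
        raise RuntimeError("could not assign a Voronoi cell to every seed point")

    edges = set()
    for i, j in itertools.combinations(range(n_regions), 2):
        inter = cells[i].intersection(cells[j])
        if inter.length > 1e-12:
            edges.add((i, j))

    diameter = float(np.hypot(maxx - minx, maxy - miny))
    amplitude = _BORDER_NOISE_FRAC * diameter
    segment_len = diameter / 25.0
    jittered = tuple(
        _jitter_polygon(c, outline, seed, amplitude, segment_len) for c in cells
    )
    # Border noise is cosmetic; fall back to the clean cells if the jitter
    # produced a self-intersection or broke the area partition.
    area_ok = abs(sum(p.area for p in jittered) - outline.area) < 1e-6 * outline.area
    if not (all(p.is_valid for p in jittered) and area_ok):
        jittered = tuple(cells)

    return RegionMap(outline=outline, regions=jittered,
                     adjacency=frozenset(edges), seed=seed)


# ---------------------------------------------------------------------------
# Value dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValueSeries:
    """Per-region keyframe values in [0, 1] (one keyframe per second).

    ``values`` has shape (n_regions, duration_s + 1): a 60-s stimulus has 61
    keyframes. Descriptors summarize the global (region-mean) series: trend
    is last minus first global value, summed_values the sum over keyframes,
    max_slope the largest absolute one-second change.
    """

    values: np.ndarray
    duration_s: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.duration_s + 1:
            raise ValueError("values must be (n_regions, duration_s + 1)")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def global_series(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def trend(self) -> float:
        g = self.global_series
        return float(g[-1] - g[0])

    @property
    def summed_values(self) -> float:
        return float(self.global_series.sum())

    @property
    def max_slope(self) -> float:
        return float(np.max(np.abs(np.diff(self.global_series))))


@dataclass(frozen=True)
class StimulusDesign:
    """Design cell of one stimulus (factors are metadata for the generators)."""

    experiment: int
    stimulus_id: str
    duration_s: int
    trend_level: float = 0.0
    framing: str = "none"  # endangered | invasive | none
    salience_factor: str | None = None  # saturation/hue (exp 2), clustered/distributed (exp 3)
    timeline_unit: str | None = None  # days | years | calendar (metadata only)
    n_changing: int = 0  # exp 3: size of the changing-region subset (3 or 4)
    changing_regions: tuple[int, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2, or 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.experiment == 2 and round(self.trend_level, 2) not in EXP2_TREND_GRID:
            raise ValueError(f"experiment 2 trend {self.trend_level} not on the 8-point grid")
        if self.experiment == 3:
            if self.trend_level not in EXP3_TREND_GRID:
                raise ValueError(f"experiment 3 trend {self.trend_level} not in {EXP3_TREND_GRID}")
            if self.changing_regions and len(self.changing_regions) != self.n_changing:
                raise ValueError("changing_regions must match n_changing")
            if self.n_changing not in (3, 4):
                raise ValueError("experiment 3 uses 3 or 4 changing regions")
        elif self.changing_regions:
            raise ValueError("changing_regions only apply to experiment 3")

    def with_regions(self, regions: tuple[int, ...]) -> "StimulusDesign":
        return replace(self, changing_regions=tuple(sorted(regions)))


def _rescale01(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi - lo < 1e-15:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def generate_exp1_series(duration_s: int = 60, n_regions: int = 10,
                         noise_sd: float = 0.1, seed: int = 0,
                         noise_smoothing_s: float = 0.0) -> ValueSeries:
    """Semi-random piecewise-linear global dynamic (experiment 1).

    The global value starts at 0 and advances by a per-second slope drawn
    uniformly from [-1, 1]; the slope changes 5-10 times at random distinct
    interior seconds. The global series is min-max rescaled to [0, 1], each
    region receives i.i.d. per-second Gaussian noise (sd ``noise_sd``), and
    the full matrix is rescaled to [0, 1] again.

    ``noise_smoothing_s`` > 0 applies a moving-average kernel of that width
    to the region noise before it is added (temporally smoothed divergence
    between regions; off by default).
    """
    if duration_s < 2:
        raise ValueError("duration_s must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _substream(seed, 2)
    n_changes = int(rng.integers(5, 11))
    change_at = np.sort(rng.choice(np.arange(1, duration_s), size=n_changes,
                                   replace=False))
    slopes = rng.uniform(-1.0, 1.0, size=n_changes + 1)
    g = np.zeros(duration_s + 1)
    seg = 0
    for t in range(duration_s):
        while seg < n_changes and change_at[seg] <= t:
            seg += 1
        g[t + 1] = g[t] + slopes[seg]
    g = _rescale01(g)

    noise = rng.normal(0.0, noise_sd, size=(n_regions, duration_s + 1))
    if noise_smoothing_s > 0:
        w = max(1, int(round(noise_smoothing_s)))
        kernel = np.ones(w) / w
        noise = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"),
                                    1, noise)
    values = _rescale01(g[None, :] + noise)
    return ValueSeries(values=values, duration_s=duration_s)


def feasible_start_range(trend_level: float) -> tuple[float, float]:
    """Start values s with s and s + trend both in [0, 1].

    A trend of -1 forces a start of 1; a trend of -0.43 allows any start in
    [0.43, 1]; a flat trend allows [0, 1].
    """
    if abs(trend_level) > 1:
        raise ValueError("feasible start set is empty for |trend| > 1")
    return (float(max(0.0, -trend_level)), float(min(1.0, 1.0 - trend_level)))


def generate_exp2_series(design: StimulusDesign) -> ValueSeries:
    """Linear whole-map trend plus truncated noise (experiment 2).

    The noise-free global series runs linearly from a feasible uniform start
    to start + trend; per-region noise is added and values are truncated
    (clipped) to [0, 1] — no rescaling, so with noise_sd = 0 the realized
    trend equals the nominal trend exactly.
    """
    if design.experiment != 2:
        raise ValueError("design.experiment must be 2")
    rng = _substream(design.seed, 3)
    lo, hi = feasible_start_range(design.trend_level)
    start = float(rng.uniform(lo, hi))
    t = np.linspace(0.0, 1.0, design.duration_s + 1)
    g = start + design.trend_level * t
    noise = rng.normal(0.0, design.noise_sd, size=(10, design.duration_s + 1))
    values = np.clip(g[None, :] + noise, 0.0, 1.0)
    return ValueSeries(values=values, duration_s=design.duration_s)


def select_changing_regions(region_map: RegionMap, pattern: str, count: int,
                            seed: int = 0) -> tuple[int, ...]:
    """Select the subset of regions that carries the trend (experiment 3).

    Starting from one uniformly random region: ``clustered`` grows the set
    through regions adjacent to an already-selected one; ``distributed``
    picks regions non-adjacent to every selected one, falling back to a
    uniformly random unselected region when none qualifies.
    """
    if pattern not in ("clustered", "distributed"):
        raise ValueError("pattern must be 'clustered' or 'distributed'")
    if count > region_map.n_regions:
        raise ValueError("count exceeds the number of regions")
    rng = _substream(seed, 4)
    selected = [int(rng.integers(region_map.n_regions))]
    all_ids = set(range(region_map.n_regions))
    for step in range(1, count):
        remaining = sorted(all_ids - set(selected))
        if pattern == "clustered":
            candidates = [r for r in remaining
                          if region_map.neighbors(r) & set(selected)]
            if not candidates:
                raise RuntimeError(
                    f"clustered selection stranded at step {step}: no region "
                    f"adjacent to {sorted(selected)}"
                )
        else:
            candidates = [r for r in remaining
                          if not (region_map.neighbors(r) & set(selected))]
            if not candidates:
                candidates = remaining  # stated random fallback
        selected.append(int(candidates[rng.integers(len(candidates))]))
    return tuple(sorted(selected))


def generate_exp3_series(design: StimulusDesign, region_map: RegionMap) -> ValueSeries:
    """Trend confined to a region subset, remainder stable (experiment 3).

    Changing regions follow a linear trajectory with slope ``trend_level``
    from a feasible start; the other regions hold one stable seed-drawn
    level (uniform on [0.2, 0.8], shared within the stimulus). All regions
    receive i.i.d. per-second Gaussian noise, truncated to [0, 1].
    """
    if design.experiment != 3:
        raise ValueError("design.experiment must be 3")
    if not design.changing_regions:
        raise ValueError("design.changing_regions must be nonempty")
    ids = set(range(region_map.n_regions))
    if not set(design.changing_regions) <= ids:
        raise ValueError("changing_regions must be a subset of map region ids")
    rng = _substream(design.seed, 5)
    lo, hi = feasible_start_range(design.trend_level)
    start = float(rng.uniform(lo, hi))
    stable_level = float(rng.uniform(0.2, 0.8))
    t = np.linspace(0.0, 1.0, design.duration_s + 1)
    values = np.full((region_map.n_regions, design.duration_s + 1), stable_level)
    for r in design.changing_regions:
        values[r] = start + design.trend_level * t
    noise = rng.normal(0.0, design.noise_sd,
                       size=(region_map.n_regions, design.duration_s + 1))
    return ValueSeries(values=np.clip(values + noise, 0.0, 1.0),
                       duration_s=design.duration_s)


def enumerate_design(experiment: int) -> list[StimulusDesign]:
    """Orthogonal factorial enumeration of the 32 experiment 2 or 3 designs."""
    if experiment == 2:
        designs = []
        for trend, framing, scale in itertools.product(
                EXP2_TREND_GRID, ("endangered", "invasive"), ("hue", "saturation")):
            sid = f"e2_t{trend:+.2f}_{framing[:3]}_{scale[:3]}"
            designs.append(StimulusDesign(
                experiment=2, stimulus_id=sid, duration_s=30,
                trend_level=trend, framing=framing, salience_factor=scale))
        return designs
    if experiment == 3:
        designs = []
        for trend, framing, pattern, n_changing in itertools.product(
                EXP3_TREND_GRID, ("endangered", "invasive"),
                ("distributed", "clustered"), (3, 4)):
            sid = f"e3_t{trend:+.1f}_{framing[:3]}_{pattern[:4]}_k{n_changing}"
            designs.append(StimulusDesign(
                experiment=3, stimulus_id=sid, duration_s=30,
                trend_level=trend, framing=framing, salience_factor=pattern,
                n_changing=n_changing))
        return designs
    raise ValueError("experiment must be 2 or 3")


def generate_series(design: StimulusDesign,
                    region_map: RegionMap | None = None) -> ValueSeries:
    """Dispatch to the experiment-appropriate generator."""
    if design.experiment == 1:
        return generate_exp1_series(duration_s=design.duration_s,
                                    noise_sd=design.noise_sd, seed=design.seed)
    if design.experiment == 2:
        return generate_exp2_series(design)
    if region_map is None:
        raise ValueError("experiment 3 requires a region map")
    return generate_exp3_series(design, region_map)
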