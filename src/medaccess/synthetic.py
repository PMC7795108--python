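"""Reproducible synthetic study regions for the accessibility analysis.

A region is a square demand grid (5 km cells by default) with a handful
of urban cores, one of which is the provincial capital.  Population
concentrates around the cores with a dispersed rural remainder; the
agricultural share is higher in rural cells and the aging share higher
in core cells.  Facilities follow a three-tier structure: primary
facilities everywhere in proportion to population, secondary facilities
biased toward the cores, tertiary hospitals only inside cores.  The
road network is a lattice: a national-class backbone along core-to-core
routes, county-class infill, and a township/village spanning tree
pruned so that roughly nine cells in ten keep a road; a rail line
threads the cores through the capital.

Everything is drawn from a single seeded generator, so a (config, seed)
pair maps to one region, bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .access import DemandCell, Facility
from .network import RoadSegment, TransportNetwork, build_network

SUBDIVISION_BANDS = ("south", "central", "north")


@dataclass(frozen=True)
class RegionConfig:
    extent_km: float = 100.0
    cell_km: float = 5.0
    n_cities: int = 4
    capital_index: int = 0
    facility_counts: dict = field(
        default_factory=lambda: {"primary": 60, "secondary": 12, "tertiary": 5}
    )
    population_total: int = 1_000_000
    rural_fraction: float = 0.4
    aging_core_ratio: float = 0.15
    aging_rural_ratio: float = 0.09
    agricultural_core_ratio: float = 0.15
    agricultural_rural_ratio: float = 0.75
    road_density: float = 0.15
    core_radius_cells: int = 1
    staff_medians: dict = field(
        default_factory=lambda: {"primary": 20.0, "secondary": 150.0, "tertiary": 800.0}
    )
    staff_sigma: float = 0.5
    network_coverage: float = 0.92
    seed: int = 0

    def __post_init__(self):
        n = self.extent_km / self.cell_km
        if abs(n - round(n)) > 1e-9:
            raise ValueError("cell_km must divide extent_km")
        if self.n_cities < 1 or self.population_total < 1:
            raise ValueError("counts must be at least 1")
        if not 0 <= self.capital_index < self.n_cities:
            raise ValueError("capital_index out of range")
        for r in (
            self.rural_fraction,
            self.aging_core_ratio,
            self.aging_rural_ratio,
            self.agricultural_core_ratio,
            self.agricultural_rural_ratio,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("ratios must lie in [0, 1]")
        if any(v < 0 for v in self.facility_counts.values()):
            raise ValueError("facility counts must be non-negative")
        if self.facility_counts.get("tertiary", 0) < 1:
            raise ValueError("need at least one tertiary hospital")
        if self.n_cities > self.n_side**2:
            raise ValueError("more urban cores than grid cells")

    @property
    def n_side(self) -> int:
        return round(self.extent_km / self.cell_km)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegionConfig":
        return cls(**d)


@dataclass
class StudyRegion:
    """A generated or loaded study region.

    ``segments`` include rail; the ``network`` property is the road-only
    graph, ``network_with_rail`` adds rail edges (used for tertiary-care
    time costs).
    """

    segments: list[RoadSegment]
    cells: list[DemandCell]
    facilities: list[Facility]
    subdivisions: dict[int, str]
    capital_city_id: int
    config: RegionConfig | None = None
    _road_net: TransportNetwork | None = field(default=None, repr=False)
    _rail_net: TransportNetwork | None = field(default=None, repr=False)

    def __post_init__(self):
        cities = {c.city_id for c in self.cells}
        for f in self.facilities:
            if f.city_id not in cities:
                raise ValueError(f"facility {f.id} has unknown city {f.city_id}")
        if self.capital_city_id not in cities:
            raise ValueError("capital city has no cells")

    @property
    def network(self) -> TransportNetwork:
        if self._road_net is None:
            self._road_net = build_network(self.segments, include_rail=False)
        return self._road_net

    @property
    def network_with_rail(self) -> TransportNetwork:
        if self._rail_net is None:
            self._rail_net = build_network(self.segments, include_rail=True)
        return self._rail_net

    def facilities_by_level(self, *levels: str) -> list[Facility]:
        return [f for f in self.facilities if f.level in levels]

    def save(self, directory) -> None:
        from .io import save_region

        save_region(self, directory)

    @classmethod
    def load(cls, directory) -> "StudyRegion":
        from .io import load_region

        return load_region(directory)


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation proportional to weights (largest remainder)."""
    if total <= 0 or weights.sum() <= 0:
        return np.zeros(len(weights), dtype=int)
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _place_cores(n_side: int, n_cities: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    cells = [(ix, iy) for ix in range(n_side) for iy in range(n_side)]
    if n_cities > len(cells):
        raise ValueError("more urban cores than grid cells")
    for _ in range(2000):
        picks = rng.choice(len(cells), size=n_cities, replace=False)
        pts = [cells[i] for i in picks]
        ok = all(
            max(abs(a[0] - b[0]), abs(a[1] - b[1])) >= 2
            for i, a in enumerate(pts)
            for b in pts[i + 1:]
        )
        if ok:
            return pts
    raise ValueError("could not place cores at least 2 cells apart; grid too small")


def generate_region(config: RegionConfig) -> StudyRegion:
    """Draw a synthetic study region from a seeded configuration."""
    rng = np.random.default_rng(config.seed)
    n = config.n_side
    cell_m = config.cell_km * 1000.0
    cores = _place_cores(n, config.n_cities, rng)

    ix = np.tile(np.arange(n), n)           # row-major from the southwest corner
    iy = np.repeat(np.arange(n), n)
    cx = (ix + 0.5) * cell_m
    cy = (iy + 0.5) * cell_m

    core_arr = np.array(cores, dtype=float)
    dx = ix[:, None] - core_arr[None, :, 0]
    dy = iy[:, None] - core_arr[None, :, 1]
    euclid = np.hypot(dx, dy)
    cheb = np.maximum(np.abs(dx), np.abs(dy))
    city_id = np.argmin(euclid, axis=1)
    is_core = cheb.min(axis=1) <= config.core_radius_cells

    # population: decaying kernel around cores, uniform rural field
    core_total = round(config.population_total * (1.0 - config.rural_fraction))
    rural_total = config.population_total - core_total
    if not is_core.all() and not is_core.any():  # pragma: no cover - degenerate
        raise ValueError("no core cells")
    if is_core.all():
        core_total, rural_total = config.population_total, 0
    pop = np.zeros(n * n, dtype=int)
    core_w = np.exp(-euclid.min(axis=1)) * rng.uniform(0.7, 1.3, n * n)
    pop[is_core] = _apportion(core_total, core_w[is_core])
    rural_w = rng.uniform(0.2, 1.0, n * n)
    if (~is_core).any():
        pop[~is_core] = _apportion(rural_total, rural_w[~is_core])
    else:
        pop[is_core] = _apportion(config.population_total, core_w[is_core])

    aging_ratio = np.where(is_core, config.aging_core_ratio, config.aging_rural_ratio)
    agri_ratio = np.where(is_core, config.agricultural_core_ratio, config.agricultural_rural_ratio)
    aging = rng.binomial(pop, aging_ratio)
    agri = rng.binomial(pop, agri_ratio)

    # counties: coarse blocks of the grid; subdivisions: three latitude bands
    block = max(2, round(n / 6))
    county = [f"c{int(a) // block}_{int(b) // block}" for a, b in zip(ix, iy)]

    def band(iy_core: int) -> str:
        return SUBDIVISION_BANDS[min(2, int(3 * iy_core / n))]

    subdivisions = {c: band(cores[c][1]) for c in range(config.n_cities)}

    cells = [
        DemandCell(
            id=i,
            x=float(cx[i]),
            y=float(cy[i]),
            population=int(pop[i]),
            aging_count=int(aging[i]),
            agricultural_count=int(agri[i]),
            county_id=county[i],
            city_id=int(city_id[i]),
            subdivision=subdivisions[int(city_id[i])],
        )
        for i in range(n * n)
    ]

    facilities = _place_facilities(config, rng, cores, cells, is_core, cell_m)
    segments = _build_segments(config, rng, cores, cell_m)

    region = StudyRegion(
        segments=segments,
        cells=cells,
        facilities=facilities,
        subdivisions=subdivisions,
        capital_city_id=config.capital_index,
        config=config,
    )
    _check_coverage(region, cores, cell_m)
    return region


def _place_facilities(config, rng, cores, cells, is_core, cell_m) -> list[Facility]:
    pop = np.array([c.population for c in cells], dtype=float)
    n_cells = len(cells)
    facilities: list[Facility] = []
    fid = 0

    def jitter():
        return rng.uniform(-0.3, 0.3) * cell_m

    def staff(level: str) -> float:
        med = config.staff_medians[level]
        return float(np.exp(np.log(med) + config.staff_sigma * rng.standard_normal()))

    # tertiary: only in core cells, concentrated in the capital (about half),
    # the remainder assigned to other cities by population rank — so small
    # cities may have none, as in real provinces
    n_ter = config.facility_counts.get("tertiary", 0)
    n_capital = max(1, round(0.5 * n_ter))
    city_pop = np.array(
        [pop[np.array([c.city_id for c in cells]) == cc].sum()
         for cc in range(config.n_cities)]
    )
    others = [c for c in np.argsort(-city_pop, kind="stable").tolist()
              if c != config.capital_index]
    ter_cities = [config.capital_index] * n_capital + [
        others[t % len(others)] for t in range(n_ter - n_capital)
    ] if others else [config.capital_index] * n_ter
    for city in ter_cities:
        ccx, ccy = cores[city]
        x = (ccx + 0.5) * cell_m + jitter()
        y = (ccy + 0.5) * cell_m + jitter()
        facilities.append(Facility(fid, x, y, "tertiary", staff("tertiary"), city_id=city))
        fid += 1

    cell_city = np.array([c.city_id for c in cells])

    def sample_cells(count: int, weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            w = np.ones(n_cells)
        return rng.choice(n_cells, size=count, replace=True, p=w / w.sum())

    # secondary: clustered where population is dense (urban cores)
    for i in sample_cells(config.facility_counts.get("secondary", 0), pop**2):
        c = cells[i]
        facilities.append(
            Facility(fid, c.x + jitter(), c.y + jitter(), "secondary",
                     staff("secondary"), city_id=int(cell_city[i]))
        )
        fid += 1

    # primary: everywhere, density proportional to population
    for i in sample_cells(config.facility_counts.get("primary", 0), pop):
        c = cells[i]
        facilities.append(
            Facility(fid, c.x + jitter(), c.y + jitter(), "primary",
                     staff("primary"), city_id=int(cell_city[i]))
        )
        fid += 1
    return facilities


def _build_segments(config, rng, cores, cell_m) -> list[RoadSegment]:
    n = config.n_side

    # Road nodes sit near, not on, cell centroids: demand points generally
    # do not fall on the network, which is what the access-leg model of the
    # travel-cost engine assumes.  One jittered position per lattice node
    # keeps shared endpoints (and rail stations) consistent.
    node_pos = {
        (a, b): (
            (a + 0.5) * cell_m + rng.uniform(-0.2, 0.2) * cell_m,
            (b + 0.5) * cell_m + rng.uniform(-0.2, 0.2) * cell_m,
        )
        for a in range(n)
        for b in range(n)
    }

    def centroid(node):
        return node_pos[node]

    lattice = nx.grid_2d_graph(n, n)
    for u, v in lattice.edges:
        lattice.edges[u, v]["w"] = 1.0 + rng.uniform(0.0, 0.5)

    # national backbone: lattice routes along the core-to-core spanning tree
    classed: dict[tuple, str] = {}
    core_mst = nx.minimum_spanning_tree(
        nx.Graph(
            (a, b, {"weight": math.dist(a, b)})
            for i, a in enumerate(cores)
            for b in cores[i + 1:]
        )
    ) if len(cores) > 1 else nx.Graph()
    for a, b in core_mst.edges:
        path = nx.shortest_path(lattice, a, b, weight="w")
        for u, v in zip(path[:-1], path[1:]):
            classed[frozenset((u, v))] = "national"

    # county infill: random extra lattice edges
    for u, v in lattice.edges:
        key = frozenset((u, v))
        if key not in classed and rng.random() < config.road_density:
            classed[key] = "county"

    # township / village spanning tree over all cells
    mst = nx.minimum_spanning_tree(lattice, weight="w")
    for u, v in mst.edges:
        key = frozenset((u, v))
        if key not in classed:
            classed[key] = "township" if rng.random() < 0.6 else "village"

    # prune leaf edges until the target coverage (cores always kept)
    sel = nx.Graph()
    sel.add_nodes_from(lattice.nodes)
    for key, rc in classed.items():
        u, v = tuple(key)
        sel.add_edge(u, v, road_class=rc)
    target = max(0.90, config.network_coverage)
    core_set = set(cores)
    total = n * n

    def coverage() -> float:
        return sum(1 for node in sel.nodes if sel.degree(node) > 0) / total

    leaves = [v for v in sel.nodes if sel.degree(v) == 1 and v not in core_set]
    leaves = [leaves[i] for i in rng.permutation(len(leaves))]
    for leaf in leaves:
        if coverage() <= target:
            break
        if sel.degree(leaf) != 1:
            continue
        nbr = next(iter(sel.neighbors(leaf)))
        sel.remove_edge(leaf, nbr)

    segments = [
        RoadSegment((centroid(u), centroid(v)), sel.edges[u, v]["road_class"])
        for u, v in sorted(sel.edges)
    ]

    # rail: one ordinary line threading the cores through the capital
    if len(cores) > 1:
        capital = cores[config.capital_index]
        rest = sorted(
            (c for c in cores if c != capital),
            key=lambda c: math.atan2(c[1] - capital[1], c[0] - capital[0]),
        )
        line = [capital]
        pool = list(rest)
        while pool:  # nearest-neighbour chain keeps the line short
            last = line[-1]
            pool.sort(key=lambda c: math.dist(c, last))
            line.append(pool.pop(0))
        for a, b in zip(line[:-1], line[1:]):
            segments.append(RoadSegment((centroid(a), centroid(b)), "rail_ordinary"))
    return segments


def _check_coverage(region: StudyRegion, cores, cell_m: float) -> None:
    # a cell counts as road-served when its centroid snaps within one
    # cell size of the network
    net = region.network
    touched = sum(1 for c in region.cells if net.snap((c.x, c.y)).dist_m <= cell_m)
    if touched / len(region.cells) < 0.90:
        raise ValueError(
            f"network reaches only {touched}/{len(region.cells)} cells; "
            "raise road_density or network_coverage"
        )
    g = net.graph
    core_nodes = [net.snap(((a + 0.5) * cell_m, (b + 0.5) * cell_m)).edge[0]
                  for a, b in cores]
    first = core_nodes[0]
    if not all(nx.has_path(g, first, node) for node in core_nodes[1:]):
        raise ValueError("road network does not connect all urban cores")


def fixture_minimal() -> StudyRegion:
    """Tiny 3x3 region whose travel costs can be traced by hand.

    One county road runs west-east through the middle row at 50 km/h,
    one township road south-north through the middle column at 25 km/h
    (crossing at the centre), and one ordinary-rail diagonal links the
    west road end to the north road end.  Four facilities sit exactly on
    road endpoints, so their access legs are zero.
    """
    cell = 5000.0
    seg_road_we = RoadSegment(((2500.0, 7500.0), (12500.0, 7500.0)), "county")
    seg_road_sn = RoadSegment(((7500.0, 2500.0), (7500.0, 12500.0)), "township")
    seg_rail = RoadSegment(((2500.0, 7500.0), (7500.0, 12500.0)), "rail_ordinary")

    pops = [60, 120, 60, 120, 480, 120, 60, 120, 60]
    aging = [6, 12, 6, 12, 48, 12, 6, 12, 6]
    agri = [48, 48, 48, 48, 48, 48, 48, 48, 48]
    county_of_col = ["west", "mid", "east"]
    cells = []
    for i in range(9):
        col, row = i % 3, i // 3
        cells.append(
            DemandCell(
                id=i,
                x=(col + 0.5) * cell,
                y=(row + 0.5) * cell,
                population=pops[i],
                aging_count=aging[i],
                agricultural_count=agri[i],
                county_id=county_of_col[col],
                city_id=0,
                subdivision="central",
            )
        )

    facilities = [
        Facility(0, 2500.0, 7500.0, "primary", 20.0, city_id=0),
        Facility(1, 7500.0, 2500.0, "primary", 30.0, city_id=0),
        Facility(2, 12500.0, 7500.0, "secondary", 150.0, city_id=0),
        Facility(3, 7500.0, 12500.0, "tertiary", 500.0, city_id=0),
    ]
    return StudyRegion(
        segments=[seg_road_we, seg_road_sn, seg_rail],
        cells=cells,
        facilities=facilities,
        subdivisions={0: "central"},
        capital_city_id=0,
        config=None,
    )
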