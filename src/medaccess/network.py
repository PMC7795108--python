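"""Transport graph construction and origin-destination travel costs.

Demand points and facilities rarely sit exactly on a digitised road, so
every origin-destination cost is assembled from three pieces: an access
leg from the origin to its nearest road, a shortest path along the
network, and an access leg from the road to the destination.  Access
legs are costed with a two-speed rule: short gaps are walked, longer
gaps (where the low-level road was presumably dropped during
digitisation) are traversed at a feeder speed.  Because missing minor
roads can make two nearby points look far apart on the network, the
final cost is the minimum of the network route and a direct
straight-line route costed by the same two-speed rule, which removes
those outliers.

Two cost metrics are supported throughout: ``time_min`` (minutes, uses
road-class speeds) and ``space_m`` (metres, pure distance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Average travel speed per road class, km/h.
ROAD_SPEEDS_KMH: dict[str, float] = {
    "national": 80.0,
    "provincial": 70.0,
    "county": 50.0,
    "township": 25.0,
    "special": 20.0,
    "village": 15.0,
    "rail_highspeed": 200.0,
    "rail_ordinary": 120.0,
}

RAIL_CLASSES = frozenset({"rail_highspeed", "rail_ordinary"})

TIME_METRIC = "time_min"
SPACE_METRIC = "space_m"

_COORD_DECIMALS = 6  # node-merge tolerance, ~1 micrometre in planar metres


def _minutes_per_metre(speed_kmh: float) -> float:
    return 60.0 / (speed_kmh * 1000.0)


@dataclass(frozen=True)
class RoadSegment:
    """A polyline of one road class with planar coordinates in metres."""

    coords: tuple[tuple[float, float], ...]
    road_class: str
    speed_kmh: float | None = None

    def __post_init__(self):
        if self.road_class not in ROAD_SPEEDS_KMH:
            raise ValueError(f"unknown road class {self.road_class!r}")
        if self.speed_kmh is None:
            object.__setattr__(self, "speed_kmh", ROAD_SPEEDS_KMH[self.road_class])
        if self.speed_kmh <= 0:
            raise ValueError("speed must be positive")
        object.__setattr__(self, "coords", tuple(tuple(map(float, c)) for c in self.coords))
        if len(self.coords) < 2:
            raise ValueError("segment needs at least two coordinates")

    @property
    def is_rail(self) -> bool:
        return self.road_class in RAIL_CLASSES

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)


@dataclass(frozen=True)
class AccessParams:
    """Parameters of the off-network access legs.

    ``d_threshold_m`` is the walkable gap: the distance a resident
    covers on foot in 15 minutes at ``walk_speed_kmh`` (1250 m at
    5 km/h).  Beyond it the gap is costed at ``feeder_speed_kmh``
    (25 km/h), standing in for informal transport on undigitised minor
    roads.  ``direct_rule`` selects how the straight-line candidate is
    combined with the network route:

    - ``"min"`` (default): cost = min(network route, direct route).
    - ``"literal"``: use the direct route only when it is cheaper than
      the two access legs combined, otherwise the network route.
    - ``"network"``: plain node-cost result, no direct fallback.
    """

    d_threshold_m: float = 1250.0
    walk_speed_kmh: float = 5.0
    feeder_speed_kmh: float = 25.0
    direct_rule: str = "min"

    def __post_init__(self):
        if min(self.d_threshold_m, self.walk_speed_kmh, self.feeder_speed_kmh) <= 0:
            raise ValueError("access parameters must be positive")
        if self.direct_rule not in ("min", "literal", "network"):
            raise ValueError(f"unknown direct_rule {self.direct_rule!r}")

    def leg_time_min(self, dist_m: float) -> float:
        speed = self.walk_speed_kmh if dist_m <= self.d_threshold_m else self.feeder_speed_kmh
        return dist_m * _minutes_per_metre(speed)

    def leg_cost(self, dist_m: float, metric: str) -> float:
        if metric == TIME_METRIC:
            return self.leg_time_min(dist_m)
        if metric == SPACE_METRIC:
            return dist_m
        raise ValueError(f"unknown metric {metric!r}")


class TransportNetwork:
    """Noded undirected transport graph with a snapping index.

    Nodes are coordinates; each edge carries ``length_m``, ``time_min``,
    ``road_class`` and ``is_rail``.  Off-network points snap to the
    nearest point of any *road* (non-rail) edge; rail is reachable only
    through shared road/rail nodes (stations).
    """

    def __init__(self, graph: nx.MultiGraph, include_rail: bool):
        self.graph = graph
        self.include_rail = include_rail
        road_geoms = []
        road_keys = []
        for u, v, k, data in graph.edges(keys=True, data=True):
            if not data["is_rail"]:
                geom = data["geometry"]
                # orient the key tuple along the geometry so snap offsets
                # are always measured from the first coordinate
                u0 = _node_key(geom.coords[0])
                v0 = _node_key(geom.coords[-1])
                road_geoms.append(geom)
                road_keys.append((u0, v0, k))
        if not road_geoms:
            raise ValueError("network has no road edges to snap to")
        self._road_geoms = road_geoms
        self._road_keys = road_keys
        self._tree = STRtree(road_geoms)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def snap(self, xy: tuple[float, float]) -> "SnapResult":
        """Nearest point on any road edge (never rail).

        Equidistant edges are tie-broken by edge index so snapping is
        deterministic.
        """
        pt = Point(xy)
        idx = int(self._tree.nearest(pt))
        dmin = pt.distance(self._road_geoms[idx])
        near = sorted(
            int(j) for j in self._tree.query(pt.buffer(dmin + 1e-6))
            if pt.distance(self._road_geoms[int(j)]) <= dmin + 1e-9
        )
        if near:
            idx = near[0]
        geom = self._road_geoms[idx]
        offset = geom.project(pt)
        snap_pt = geom.interpolate(offset)
        return SnapResult(
            edge=self._road_keys[idx],
            offset_m=float(offset),
            point=(snap_pt.x, snap_pt.y),
            dist_m=float(pt.distance(snap_pt)),
        )


@dataclass(frozen=True)
class SnapResult:
    edge: tuple          # (u, v, key) in the network graph
    offset_m: float      # arc-length position along the edge geometry from u
    point: tuple[float, float]
    dist_m: float


def _node_key(xy) -> tuple[float, float]:
    return (round(float(xy[0]), _COORD_DECIMALS), round(float(xy[1]), _COORD_DECIMALS))


def _split_line(line: LineString, offsets: list[float]) -> list[LineString]:
    """Cut a line at interior arc-length offsets, preserving vertices."""
    from shapely.ops import substring

    cuts = sorted({o for o in offsets if 1e-9 < o < line.length - 1e-9})
    bounds = [0.0, *cuts, line.length]
    return [substring(line, a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def build_network(segments: list[RoadSegment], include_rail: bool = False) -> TransportNetwork:
    """Node a set of polyline segments into an undirected graph.

    Nodes are created at segment endpoints and at geometric crossings
    between segments; edge traversal time follows the class speed.
    Rail segments are dropped unless ``include_rail`` is set.
    """
    if not segments:
        raise ValueError("no segments supplied")
    kept = [s for s in segments if include_rail or not s.is_rail]
    if not kept:
        raise ValueError("no usable segments after rail filtering")

    geoms = []
    for s in kept:
        g = s.geometry
        if g.length <= 0:
            raise ValueError(f"zero-length segment rejected: {s.coords}")
        geoms.append(g)

    # Split each segment where another segment crosses it.  Rail/road
    # crossings are not split: rail is boarded only at shared endpoints
    # (stations), never at grade crossings.
    tree = STRtree(geoms)
    pieces: list[tuple[LineString, RoadSegment]] = []
    for i, (g, seg) in enumerate(zip(geoms, kept)):
        offsets: list[float] = []
        for j in tree.query(g):
            if j == i or kept[int(j)].is_rail != seg.is_rail:
                continue
            inter = g.intersection(geoms[int(j)])
            if inter.is_empty:
                continue
            points = []
            if inter.geom_type == "Point":
                points = [inter]
            elif inter.geom_type == "MultiPoint":
                points = list(inter.geoms)
            # overlapping collinear segments share endpoints already
            for p in points:
                offsets.append(g.project(p))
        for piece in _split_line(g, offsets):
            pieces.append((piece, seg))

    graph = nx.MultiGraph()
    for piece, seg in pieces:
        u = _node_key(piece.coords[0])
        v = _node_key(piece.coords[-1])
        length = float(piece.length)
        if length <= 0:
            continue
        graph.add_node(u, x=u[0], y=u[1])
        graph.add_node(v, x=v[0], y=v[1])
        graph.add_edge(
            u,
            v,
            length_m=length,
            time_min=length * _minutes_per_metre(seg.speed_kmh),
            road_class=seg.road_class,
            is_rail=seg.is_rail,
            speed_kmh=seg.speed_kmh,
            geometry=piece,
        )
    return TransportNetwork(graph, include_rail)


def access_leg(
    point: tuple[float, float],
    network: TransportNetwork,
    params: AccessParams,
    metric: str = TIME_METRIC,
) -> tuple[SnapResult, float]:
    """Snap a point to the road network and cost the gap.

    Time metric: walked at ``walk_speed`` when the gap is within
    ``d_threshold_m``, else covered at ``feeder_speed``.  Space metric:
    the straight-line gap in metres.
    """
    snap = network.snap(point)
    return snap, params.leg_cost(snap.dist_m, metric)


@dataclass
class TravelCostMatrix:
    """Origin x destination costs in a single metric."""

    origin_ids: list
    dest_ids: list
    values: np.ndarray  # shape (n_origins, n_dests)
    metric: str
    rail_used: bool
    params: AccessParams = field(default_factory=AccessParams)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.origin_ids), len(self.dest_ids)):
            raise ValueError("cost matrix shape does not match id lists")
        if np.any(self.values < 0):
            raise ValueError("negative travel cost")

    def column(self, dest_id) -> np.ndarray:
        return self.values[:, self.dest_ids.index(dest_id)]

    def subset(self, dest_ids) -> "TravelCostMatrix":
        idx = [self.dest_ids.index(d) for d in dest_ids]
        return TravelCostMatrix(
            self.origin_ids, list(dest_ids), self.values[:, idx], self.metric,
            self.rail_used, self.params,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.origin_ids, columns=self.dest_ids)
        df.index.name = "origin_id"
        df.to_csv(path)
        sidecar = str(path) + ".meta.json"
        import json

        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "metric": self.metric,
                    "rail_used": self.rail_used,
                    "d_threshold_m": self.params.d_threshold_m,
                    "walk_speed_kmh": self.params.walk_speed_kmh,
                    "feeder_speed_kmh": self.params.feeder_speed_kmh,
                    "direct_rule": self.params.direct_rule,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_csv(cls, path) -> "TravelCostMatrix":
        import json

        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        with open(str(path) + ".meta.json") as fh:
            meta = json.load(fh)
        params = AccessParams(
            d_threshold_m=meta["d_threshold_m"],
            walk_speed_kmh=meta["walk_speed_kmh"],
            feeder_speed_kmh=meta["feeder_speed_kmh"],
            direct_rule=meta["direct_rule"],
        )
        def _coerce(ids):
            out = []
            for i in ids:
                try:
                    out.append(int(i))
                except (TypeError, ValueError):
                    out.append(i)
            return out

        return cls(
            _coerce(df.index.tolist()),
            _coerce(df.columns.tolist()),
            df.to_numpy(),
            meta["metric"],
            meta["rail_used"],
            params,
        )


def _weight_attr(metric: str) -> str:
    if metric == TIME_METRIC:
        return "time_min"
    if metric == SPACE_METRIC:
        return "length_m"
    raise ValueError(f"unknown metric {metric!r}")


def _edge_rate(data: dict, metric: str) -> float:
    """Cost per metre along an edge in the requested metric."""
    if metric == SPACE_METRIC:
        return 1.0
    return data["time_min"] / data["length_m"]


def _direct_cost(a, b, params: AccessParams, metric: str) -> float:
    d = math.dist(a, b)
    return params.leg_cost(d, metric)


def _insert_virtual_nodes(network: TransportNetwork, snaps: list[SnapResult]):
    """Copy the graph with a named node at every snap location.

    Snap points that share an edge split it consistently; each virtual
    node inherits proportional length/time of its host edge.  Returns
    (graph, node_names) with ``node_names[i]`` the node for ``snaps[i]``.
    """
    g = network.graph.copy()
    by_edge: dict[tuple, list[tuple[float, int]]] = {}
    for i, s in enumerate(snaps):
        by_edge.setdefault(s.edge, []).append((s.offset_m, i))

    names: dict[int, tuple] = {}
    for edge, offs in by_edge.items():
        u, v, k = edge
        data = network.graph.edges[u, v, k]
        length = data["length_m"]
        rate_t = data["time_min"] / length
        # endpoint-coincident snaps reuse the endpoint node
        chain: list[tuple[float, tuple]] = [(0.0, u)]
        for off, i in sorted(offs):
            if off <= 1e-9:
                names[i] = u
            elif off >= length - 1e-9:
                names[i] = v
            else:
                node = ("virt", edge, round(off, 6))
                names[i] = node
                if node not in [n for _, n in chain]:
                    chain.append((off, node))
        chain.append((length, v))
        if len(chain) > 2:
            g.remove_edge(u, v, key=k)
            chain.sort(key=lambda t: t[0])
            for (o1, n1), (o2, n2) in zip(chain[:-1], chain[1:]):
                seg_len = o2 - o1
                g.add_edge(
                    n1,
                    n2,
                    length_m=seg_len,
                    time_min=seg_len * rate_t,
                    road_class=data["road_class"],
                    is_rail=data["is_rail"],
                    speed_kmh=data["speed_kmh"],
                )
    return g, [names[i] for i in range(len(snaps))]


def _pairwise_costs(
    origins: list[tuple[float, float]],
    dests: list[tuple[float, float]],
    network: TransportNetwork,
    params: AccessParams,
    metric: str,
) -> np.ndarray:
    """Improved node-cost OD matrix: min(access+path+access, direct)."""
    o_snaps = [network.snap(p) for p in origins]
    d_snaps = [network.snap(p) for p in dests]
    o_legs = np.array([params.leg_cost(s.dist_m, metric) for s in o_snaps])
    d_legs = np.array([params.leg_cost(s.dist_m, metric) for s in d_snaps])

    g, d_nodes = _insert_virtual_nodes(network, d_snaps)

    # Bracketing nodes of each origin snap in the destination-split graph:
    # walk the split chain of the host edge to find neighbours around the
    # origin offset, with exact partial costs.
    edge_chains: dict[tuple, list[tuple[float, tuple]]] = {}
    for snap, node in zip(d_snaps, d_nodes):
        edge_chains.setdefault(snap.edge, []).append((snap.offset_m, node))

    wattr = _weight_attr(metric)
    dist_maps = []
    for node in d_nodes:
        dist_maps.append(nx.single_source_dijkstra_path_length(g, node, weight=wattr))

    n_o, n_d = len(origins), len(dests)
    out = np.full((n_o, n_d), np.inf)
    for i, (o_pt, o_snap) in enumerate(zip(origins, o_snaps)):
        u, v, k = o_snap.edge
        data = network.graph.edges[u, v, k]
        length = data["length_m"]
        rate = _edge_rate(data, metric)
        # candidate entry nodes from the origin snap with partial edge costs
        entries: list[tuple[tuple, float]] = [
            (u, o_snap.offset_m * rate),
            (v, (length - o_snap.offset_m) * rate),
        ]
        for off, node in edge_chains.get(o_snap.edge, []):
            entries.append((node, abs(off - o_snap.offset_m) * rate))
        for j, (d_pt, d_snap) in enumerate(zip(dests, d_snaps)):
            best = np.inf
            dmap = dist_maps[j]
            for node, partial in entries:
                path = dmap.get(node)
                if path is not None:
                    best = min(best, partial + path)
            # same-host-edge shortcut (both mid-edge, no node between)
            if d_snap.edge == o_snap.edge:
                best = min(best, abs(d_snap.offset_m - o_snap.offset_m) * rate)
            network_cand = o_legs[i] + best + d_legs[j]
            direct_cand = _direct_cost(o_pt, d_pt, params, metric)
            if params.direct_rule == "min":
                cost = min(network_cand, direct_cand)
            elif params.direct_rule == "literal":
                cost = direct_cand if direct_cand < o_legs[i] + d_legs[j] else network_cand
            else:  # plain node-cost
                cost = network_cand
            if not math.isfinite(cost):
                logger.warning("disconnected OD pair (%d, %d); using direct cost", i, j)
                cost = direct_cand
            out[i, j] = cost
    return out


def od_cost(
    origin: tuple[float, float],
    dest: tuple[float, float],
    network: TransportNetwork,
    params: AccessParams | None = None,
    metric: str = TIME_METRIC,
) -> float:
    """Travel cost between two points under the improved node-cost rule."""
    params = params or AccessParams()
    if origin == dest:
        return 0.0
    return float(_pairwise_costs([origin], [dest], network, params, metric)[0, 0])


def cost_matrix(
    cells,
    facilities,
    network: TransportNetwork,
    params: AccessParams | None = None,
    metric: str = TIME_METRIC,
) -> TravelCostMatrix:
    """OD cost matrix from demand-cell centroids to facility locations."""
    params = params or AccessParams()
    if not cells or not facilities:
        raise ValueError("cells and facilities must be non-empty")
    origins = [(c.x, c.y) for c in cells]
    dests = [(f.x, f.y) for f in facilities]
    values = _pairwise_costs(origins, dests, network, params, metric)
    return TravelCostMatrix(
        [c.id for c in cells],
        [f.id for f in facilities],
        values,
        metric,
        network.include_rail,
        params,
    )
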