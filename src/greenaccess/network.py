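"""Multi-modal road network construction and travel-time computation.

The road network is a planar graph whose edges carry a road classification.
Each travel mode (walking, cycling, public transport) is allowed on a subset
of road classes at a class-specific speed; classes a mode cannot use are
simply absent from that mode's subgraph, so travel between locations joined
only by such roads takes infinite time.  All coordinates are planar meters
(a projected CRS is assumed upstream); travel times are minutes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MODES = ("walking", "cycling", "public_transport")

ROAD_CLASSES = (
    "highway",
    "city_circle",
    "auxiliary_road",
    "main_street",
    "minor_street",
    "ramp",
    "feeder",
    "internal_road",
    "subway",
)

#: sentinel for (mode, class) pairs the mode cannot use
INACCESSIBLE = None

# Default mode x road-class speeds in km/h.  Walking and cycling are allowed
# only on main/minor streets, feeders and internal roads (5 and 15 km/h);
# public transport can use every class, with subway and highway fastest.
DEFAULT_SPEEDS: dict[tuple[str, str], float | None] = {}
_PT = dict(
    highway=50.0, city_circle=40.0, auxiliary_road=30.0, main_street=30.0,
    minor_street=30.0, ramp=20.0, feeder=20.0, internal_road=20.0, subway=50.0,
)
for _cls in ROAD_CLASSES:
    DEFAULT_SPEEDS[("public_transport", _cls)] = _PT[_cls]
    _open = _cls in ("main_street", "minor_street", "feeder", "internal_road")
    DEFAULT_SPEEDS[("cycling", _cls)] = 15.0 if _open else INACCESSIBLE
    DEFAULT_SPEEDS[("walking", _cls)] = 5.0 if _open else INACCESSIBLE


class NetworkFormatError(ValueError):
    """Raised when node/edge inputs violate the network schema."""


@dataclass(frozen=True)
class ModeSpeedTable:
    """Speeds in km/h per (mode, road class); ``None`` marks an inaccessible class."""

    entries: dict[tuple[str, str], float | None] = field(
        default_factory=lambda: dict(DEFAULT_SPEEDS)
    )

    def __post_init__(self) -> None:
        for (mode, cls), v in self.entries.items():
            if mode not in MODES:
                raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
            if cls not in ROAD_CLASSES:
                raise ValueError(
                    f"unknown road class {cls!r}; expected one of {ROAD_CLASSES}"
                )
            if v is not None and v <= 0:
                raise ValueError(f"speed for {(mode, cls)} must be > 0, got {v}")

    def speed(self, mode: str, road_class: str) -> float | None:
        return self.entries.get((mode, road_class), INACCESSIBLE)

    @classmethod
    def with_overrides(cls, overrides: dict) -> "ModeSpeedTable":
        """Default table with ``{(mode, class): speed-or-None}`` overrides applied."""
        entries = dict(DEFAULT_SPEEDS)
        entries.update(overrides)
        return cls(entries=entries)


@dataclass
class RoadNetwork:
    """Planar road graph: node coordinates plus typed directed arcs."""

    nodes: dict[int, tuple[float, float]]
    #: arcs as (u, v, length_m, road_class); undirected edges appear twice
    arcs: list[tuple[int, int, float, str]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def node_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted node ids and their coordinates as arrays."""
        ids = np.array(sorted(self.nodes), dtype=np.int64)
        xy = np.array([self.nodes[i] for i in ids], dtype=float)
        return ids, xy


def load_network(node_records: pd.DataFrame, edge_records: pd.DataFrame) -> RoadNetwork:
    """Validate node/edge tables and build a :class:`RoadNetwork`.

    ``node_records`` needs columns id, x, y; ``edge_records`` needs
    u, v, length_m, road_class and optionally oneway (0/1).  Undirected
    edges are expanded to two arcs.
    """
    ids = node_records["id"].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        dup = node_records["id"][node_records["id"].duplicated()].iloc[0]
        raise NetworkFormatError(f"duplicate node id {dup}")
    nodes = {
        int(r.id): (float(r.x), float(r.y)) for r in node_records.itertuples()
    }

    arcs: list[tuple[int, int, float, str]] = []
    has_oneway = "oneway" in edge_records.columns
    for idx, r in enumerate(edge_records.itertuples()):
        u, v = int(r.u), int(r.v)
        if u not in nodes or v not in nodes:
            missing = u if u not in nodes else v
            raise NetworkFormatError(
                f"edge row {idx}: endpoint {missing} not in node table"
            )
        cls = str(r.road_class)
        if cls not in ROAD_CLASSES:
            raise NetworkFormatError(
                f"edge row {idx}: unknown road class {cls!r}; "
                f"valid classes are {', '.join(ROAD_CLASSES)}"
            )
        length = float(r.length_m)
        if not length > 0:
            raise NetworkFormatError(f"edge row {idx}: length_m must be > 0, got {length}")
        arcs.append((u, v, length, cls))
        oneway = bool(getattr(r, "oneway", 0)) if has_oneway else False
        if not oneway:
            arcs.append((v, u, length, cls))
    return RoadNetwork(nodes=nodes, arcs=arcs)


def mode_subgraph(net: RoadNetwork, mode: str, speeds: ModeSpeedTable | None = None) -> nx.DiGraph:
    """Directed graph weighted in minutes for one mode; inaccessible classes dropped.

    Edge weight is ``length_m / 1000 / speed_kmh * 60``.  Parallel arcs
    between the same node pair keep the cheapest weight.
    """
    speeds = speeds or ModeSpeedTable()
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for u, v, length, cls in net.arcs:
        s = speeds.speed(mode, cls)
        if s is INACCESSIBLE:
            continue
        w = length / 1000.0 / s * 60.0
        if g.has_edge(u, v):
            if w < g[u][v]["minutes"]:
                g[u][v]["minutes"] = w
        else:
            g.add_edge(u, v, minutes=w)
    return g


@dataclass
class SnapResult:
    """Point-to-node assignments; unreachable points carry node id -1."""

    node_ids: np.ndarray  # int, -1 where unreachable
    distances_m: np.ndarray
    unreachable: np.ndarray  # bool


def snap_points(
    points: np.ndarray, net: RoadNetwork, tolerance_m: float = 500.0
) -> SnapResult:
    """Snap each (x, y) point to its nearest network node.

    Ties are broken by the smallest node id; points farther than
    ``tolerance_m`` from every node are flagged unreachable (with a warning)
    rather than raising.  The snap leg itself contributes zero travel time.
    """
    if tolerance_m <= 0:
        raise ValueError("tolerance_m must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ids, xy = net.node_array()
    if len(ids) == 0:
        raise NetworkFormatError("cannot snap to an empty network")
    out_ids = np.empty(len(pts), dtype=np.int64)
    out_d = np.empty(len(pts), dtype=float)
    unreach = np.zeros(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        d2 = (xy[:, 0] - p[0]) ** 2 + (xy[:, 1] - p[1]) ** 2
        # ids are sorted, so argmin's first minimum is the smallest id
        k = int(np.argmin(d2))
        dist = math.sqrt(d2[k])
        out_d[i] = dist
        if dist > tolerance_m:
            unreach[i] = True
            out_ids[i] = -1
        else:
            out_ids[i] = ids[k]
    if unreach.any():
        warnings.warn(
            f"{int(unreach.sum())} point(s) farther than {tolerance_m} m from any "
            "network node; flagged unreachable",
            stacklevel=2,
        )
    return SnapResult(node_ids=out_ids, distances_m=out_d, unreachable=unreach)


@dataclass
class TravelTimeMatrix:
    """Shortest travel times in minutes from origins to destinations for one mode."""

    mode: str
    origins: list[int]
    destinations: list[int]
    minutes: np.ndarray  # shape (len(origins), len(destinations)), inf = unreachable

    def time(self, origin: int, destination: int) -> float:
        return float(
            self.minutes[self.origins.index(origin), self.destinations.index(destination)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.minutes, index=self.origins, columns=self.destinations)


def travel_time_matrix(
    net: RoadNetwork,
    origins: list[int],
    destinations: list[int],
    mode: str,
    speeds: ModeSpeedTable | None = None,
    boarding_penalty_min: float = 0.0,
) -> TravelTimeMatrix:
    """Dijkstra travel times (minutes) over the mode subgraph.

    ``boarding_penalty_min`` adds a constant to every nonzero finite time
    (a crude public-transport access cost; default 0 keeps the pure
    road-speed model).  Unreachable pairs are infinity; an origin that is
    its own destination is 0.
    """
    g = mode_subgraph(net, mode, speeds)
    origins = [int(o) for o in origins]
    destinations = [int(d) for d in destinations]
    dest_index = {d: j for j, d in enumerate(destinations)}
    mat = np.full((len(origins), len(destinations)), np.inf)
    # one Dijkstra per distinct origin
    dist_cache: dict[int, dict[int, float]] = {}
    for i, o in enumerate(origins):
        if o < 0:  # unreachable snap
            continue
        if o not in dist_cache:
            dist_cache[o] = nx.single_source_dijkstra_path_length(g, o, weight="minutes")
        dists = dist_cache[o]
        for d, j in dest_index.items():
            if d in dists:
                t = dists[d]
                if boarding_penalty_min and t > 0:
                    t = t + boarding_penalty_min
                mat[i, j] = t
    return TravelTimeMatrix(mode=mode, origins=origins, destinations=destinations, minutes=mat)
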