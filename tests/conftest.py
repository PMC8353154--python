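"""Shared fixtures: small hand-built networks and communities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from greenaccess.accessibility import Community, GreenSpace
from greenaccess.network import RoadNetwork, load_network

# Edge lengths (meters) for which every Table-2 minute weight
# length/1000/speed*60 is an exactly representable binary fraction for all
# speeds {5,15,20,30,40,50}; with exact weights, shortest-path sums are
# associative and Dijkstra-vs-Floyd-Warshall comparisons are well defined at
# zero tolerance.
EXACT_LENGTHS = (18750.0, 37500.0, 75000.0, 150000.0)


def make_network(nodes: dict[int, tuple[float, float]], edges: list[tuple]) -> RoadNetwork:
    """Build a RoadNetwork from (u, v, length_m, road_class[, oneway]) tuples."""
    node_df = pd.DataFrame([{"id": i, "x": xy[0], "y": xy[1]} for i, xy in nodes.items()])
    rows = []
    for e in edges:
        u, v, length, cls = e[:4]
        oneway = e[4] if len(e) > 4 else 0
        rows.append({"u": u, "v": v, "length_m": length, "road_class": cls, "oneway": oneway})
    edge_df = pd.DataFrame(
        rows, columns=["u", "v", "length_m", "road_class", "oneway"]
    )
    return load_network(node_df, edge_df)


@pytest.fixture
def line_city():
    """Five nodes in a row, 500 m main-street links (walking: 6 min per link).

    Communities at nodes 0 and 4; green spaces at nodes 1 (two entrances:
    nodes 1 and 2) and 3.
    """
    nodes = {i: (500.0 * i, 0.0) for i in range(5)}
    edges = [(i, i + 1, 500.0, "main_street") for i in range(4)]
    net = make_network(nodes, edges)
    communities = [
        Community(id=0, node=0, pop_by_mode={"walking": 500.0, "cycling": 0.0, "public_transport": 0.0}),
        Community(id=1, node=4, pop_by_mode={"walking": 200.0, "cycling": 100.0, "public_transport": 0.0}),
    ]
    ugs = [
        GreenSpace(id=0, entrance_nodes=[1, 2], area_m2=10000.0, level=3),
        GreenSpace(id=1, entrance_nodes=[3], area_m2=9000.0, level=2),
    ]
    return net, communities, ugs


def random_routing_instance(rng: np.random.Generator, max_nodes: int = 60):
    """Random planar-ish network with Table-2 classes and exact-minute lengths."""
    from greenaccess.network import ROAD_CLASSES

    n = int(rng.integers(5, max_nodes + 1))
    nodes = {i: (float(rng.uniform(0, 1e5)), float(rng.uniform(0, 1e5))) for i in range(n)}
    m = int(rng.integers(n, 3 * n))
    edges = []
    for _ in range(m):
        u, v = rng.integers(0, n, size=2)
        if u == v:
            continue
        length = float(rng.choice(EXACT_LENGTHS))
        cls = str(rng.choice(ROAD_CLASSES))
        oneway = int(rng.random() < 0.3)
        edges.append((int(u), int(v), length, cls, oneway))
    return make_network(nodes, edges)


def floyd_warshall_minutes(net: RoadNetwork, mode: str) -> np.ndarray:
    """Independent all-pairs oracle: min-plus Floyd-Warshall over the
    mode-accessible arcs, with its own copy of the speed table."""
    speeds = {
        "public_transport": {
            "highway": 50.0, "city_circle": 40.0, "auxiliary_road": 30.0,
            "main_street": 30.0, "minor_street": 30.0, "ramp": 20.0,
            "feeder": 20.0, "internal_road": 20.0, "subway": 50.0,
        },
        "cycling": {"main_street": 15.0, "minor_street": 15.0, "feeder": 15.0, "internal_road": 15.0},
        "walking": {"main_street": 5.0, "minor_street": 5.0, "feeder": 5.0, "internal_road": 5.0},
    }[mode]
    ids = sorted(net.nodes)
    idx = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, length, cls in net.arcs:
        if cls in speeds:
            w = length / 1000.0 / speeds[cls] * 60.0
            i, j = idx[u], idx[v]
            if w < d[i, j]:
                d[i, j] = w
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def brute_force_2sfca_single_mode(
    communities, ugs_list, minutes: np.ndarray, threshold: float
) -> dict[int, float]:
    """Classic single-mode 2SFCA by direct enumeration.

    ``minutes[i, j]`` is community-i-to-green-space-j travel time (already
    minimized over entrances).  Written as plain loops straight from the
    definition: V_j = S_j / sum of reachable population, A_i = sum of
    reachable V_j.
    """
    comms = sorted(communities, key=lambda c: c.id)
    ugs_sorted = sorted(ugs_list, key=lambda g: g.id)
    V = []
    for j, g in enumerate(ugs_sorted):
        demand = 0.0
        for i, c in enumerate(comms):
            if minutes[i, j] <= threshold:
                demand += c.total_pop
        V.append(g.area_m2 / demand if demand > 0 else 0.0)
    A = {}
    for i, c in enumerate(comms):
        total = 0.0
        for j in range(len(ugs_sorted)):
            if minutes[i, j] <= threshold:
                total += V[j]
        A[c.id] = total
    return A
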