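"""Seeded synthetic-city generator.

Real community, road and green-space datasets of the kind this pipeline
targets are typically restricted, so every stage is exercised on synthetic
cities instead: a grid-with-diagonals road network whose edges carry road
classes sampled from a configurable mix, communities placed at network nodes
with Dirichlet mode splits and Beta-distributed SES proportions, and leveled
green spaces whose placement can be coupled to the local SES surface to plant
a known deprivation signal (supply-side mechanism: green spaces avoid or
favour disadvantaged neighbourhoods, and accessibility inherits the pattern).

Everything is driven by a single integer seed; the same seed reproduces the
same city byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accessibility import Community, GreenSpace
from .network import MODES, ROAD_CLASSES, RoadNetwork

#: SES proportion targets (mean, sd) used by default; proportions of people
#: aged over 65, unemployed, illiterate, educated below junior middle school,
#: and floating (migrant) population.
DEFAULT_SES_PARAMS: dict[str, tuple[float, float]] = {
    "older": (0.24, 0.07),
    "unemployed": (0.19, 0.15),
    "illiterate": (0.15, 0.06),
    "less_educated": (0.46, 0.15),
    "migrants": (0.24, 0.20),
}

#: Road-class sampling mix: dominated by the four classes open to walking and
#: cycling so the slow-mode network stays mostly connected, with a realistic
#: sprinkling of restricted classes.
DEFAULT_ROAD_MIX: dict[str, float] = {
    "main_street": 0.30,
    "minor_street": 0.28,
    "feeder": 0.15,
    "internal_road": 0.12,
    "auxiliary_road": 0.05,
    "city_circle": 0.03,
    "highway": 0.02,
    "ramp": 0.03,
    "subway": 0.02,
}

# Supply composition is community-park dominant: small level-3 (community)
# green spaces carry most of the per-capita supply, with a handful of
# district (level-2) and city (level-1) parks, mirroring how accessible area
# is typically distributed across park tiers in dense Chinese cities.
DEFAULT_UGS_COUNTS = {1: 2, 2: 20, 3: 150}
DEFAULT_UGS_AREAS = {1: (4e5, 8e5), 2: (4e4, 1.2e5), 3: (8e3, 3e4)}


@dataclass(frozen=True)
class GrowthConfig:
    """Between-timepoint growth: network densification, population growth,
    and new green spaces."""

    edge_density_multiplier: float = 1.5
    population_multiplier: float = 1.0
    n_new_ugs: int = 0


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    grid_nx: int = 20
    grid_ny: int = 20
    spacing_m: float = 700.0
    diagonal_prob: float = 0.25
    road_class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROAD_MIX))
    n_communities: int = 200
    population_range: tuple[float, float] = (500.0, 5000.0)
    #: Dirichlet concentration over (walking, cycling, public_transport);
    #: green-space trips are predominantly on foot, so the split is
    #: walking-heavy (mean shares about 0.64/0.18/0.18)
    mode_share_alpha: tuple[float, float, float] = (7.0, 2.0, 2.0)
    ses_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SES_PARAMS)
    )
    #: Gaussian-copula spatial range (meters) of the SES fields: communities
    #: form deprived/privileged districts rather than varying independently.
    #: 0 disables spatial correlation (iid draws).
    ses_spatial_range_m: float = 1400.0
    #: covariate -> placement log-weight per SD of the local SES surface;
    #: negative values starve high-covariate neighbourhoods of green space
    ses_access_coupling: dict[str, float] = field(default_factory=dict)
    ugs_counts: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_UGS_COUNTS))
    ugs_area_ranges: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_UGS_AREAS)
    )
    belt_fraction: float = 0.15
    multi_entrance_prob: float = 0.4

    def validate(self) -> None:
        total = sum(self.road_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"road_class_mix must sum to 1, got {total}")
        for cls in self.road_class_mix:
            if cls not in ROAD_CLASSES:
                raise ValueError(f"unknown road class {cls!r} in mix")
        if self.n_communities <= 0 or self.grid_nx < 2 or self.grid_ny < 2:
            raise ValueError("counts and grid dimensions must be positive")
        if self.n_communities > self.grid_nx * self.grid_ny:
            raise ValueError("more communities than grid nodes")
        for name, (m, s) in self.ses_params.items():
            if not 0 < m < 1:
                raise ValueError(f"SES mean for {name} must be in (0,1)")
            if s**2 >= m * (1 - m):
                raise ValueError(
                    f"SES sd for {name} infeasible for a Beta distribution "
                    f"(need sd^2 < mean*(1-mean))"
                )


@dataclass
class SyntheticCity:
    net: RoadNetwork
    communities: list[Community]
    ugs: list[GreenSpace]


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments Beta(a, b) for a proportion with given mean/sd."""
    v = sd**2
    k = mean * (1 - mean) / v - 1.0
    return mean * k, (1 - mean) * k


def _grid_network(cfg: ScenarioConfig, rng: np.random.Generator) -> RoadNetwork:
    nx_, ny = cfg.grid_nx, cfg.grid_ny
    nodes = {}
    for j in range(ny):
        for i in range(nx_):
            nodes[j * nx_ + i] = (i * cfg.spacing_m, j * cfg.spacing_m)
    classes = list(cfg.road_class_mix.keys())
    probs = np.array([cfg.road_class_mix[c] for c in classes])

    pairs: list[tuple[int, int]] = []
    for j in range(ny):
        for i in range(nx_):
            u = j * nx_ + i
            if i + 1 < nx_:
                pairs.append((u, u + 1))
            if j + 1 < ny:
                pairs.append((u, u + nx_))
            # one random diagonal per cell, sometimes
            if i + 1 < nx_ and j + 1 < ny and rng.random() < cfg.diagonal_prob:
                if rng.random() < 0.5:
                    pairs.append((u, u + nx_ + 1))
                else:
                    pairs.append((u + 1, u + nx_))
    arcs = []
    cls_idx = rng.choice(len(classes), size=len(pairs), p=probs)
    for (u, v), ci in zip(pairs, cls_idx):
        (x1, y1), (x2, y2) = nodes[u], nodes[v]
        length = math.hypot(x2 - x1, y2 - y1)
        cls = classes[int(ci)]
        arcs.append((u, v, length, cls))
        arcs.append((v, u, length, cls))
    return RoadNetwork(nodes=nodes, arcs=arcs)


def _ses_surface(
    cfg: ScenarioConfig,
    net: RoadNetwork,
    communities: list[Community],
) -> dict[str, np.ndarray]:
    """Inverse-distance-weighted SES proportion per covariate at every node."""
    ids, xy = net.node_array()
    cxy = np.array([net.nodes[c.node] for c in communities], dtype=float)
    out = {}
    d2 = (
        (xy[:, 0:1] - cxy[None, :, 0]) ** 2 + (xy[:, 1:2] - cxy[None, :, 1]) ** 2
    )
    w = 1.0 / (d2 + (0.5 * cfg.spacing_m) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    for name in cfg.ses_params:
        vals = np.array([c.ses[name] for c in communities])
        out[name] = w @ vals
    return out


def _place_ugs(
    cfg: ScenarioConfig,
    net: RoadNetwork,
    communities: list[Community],
    rng: np.random.Generator,
    start_id: int = 0,
    counts: dict[int, int] | None = None,
) -> list[GreenSpace]:
    ids, xy = net.node_array()
    surface = _ses_surface(cfg, net, communities)
    logw = np.zeros(len(ids))
    for name, coupling in cfg.ses_access_coupling.items():
        if coupling == 0:
            continue
        s = surface[name]
        z = (s - s.mean()) / (s.std() if s.std() > 0 else 1.0)
        logw += coupling * z
    w = np.exp(logw - logw.max())
    w /= w.sum()

    # neighbour lookup for extra entrances / belt parts
    neighbours: dict[int, list[int]] = {int(i): [] for i in ids}
    seen = set()
    for u, v, _, _ in net.arcs:
        if (u, v) not in seen and (v, u) not in seen:
            seen.add((u, v))
            neighbours[u].append(v)
            neighbours[v].append(u)
    for k in neighbours:
        neighbours[k].sort()

    ugs: list[GreenSpace] = []
    next_id = start_id
    counts = counts if counts is not None else cfg.ugs_counts
    for level in sorted(counts):
        n_level = counts[level]
        lo, hi = cfg.ugs_area_ranges[level]
        for _ in range(n_level):
            node = int(rng.choice(ids, p=w))
            area = float(rng.uniform(lo, hi))
            if rng.random() < cfg.belt_fraction and len(neighbours[node]) >= 2:
                # belt park: partition the area among parts anchored on a
                # chain of adjacent nodes, each part with its own entrance
                n_parts = int(rng.integers(2, 4))
                chain = [node]
                cur = node
                for _ in range(n_parts - 1):
                    cands = [n for n in neighbours[cur] if n not in chain]
                    if not cands:
                        break
                    cur = int(rng.choice(cands))
                    chain.append(cur)
                fracs = rng.dirichlet(np.ones(len(chain)))
                parts = [area * f for f in fracs[:-1]]
                parts.append(area - sum(parts))  # exact partition
                for pnode, parea in zip(chain, parts):
                    ugs.append(
                        GreenSpace(
                            id=next_id, entrance_nodes=[pnode], area_m2=parea, level=level
                        )
                    )
                    next_id += 1
            else:
                entrances = [node]
                if rng.random() < cfg.multi_entrance_prob and neighbours[node]:
                    extra = int(rng.choice(neighbours[node]))
                    entrances.append(extra)
                ugs.append(
                    GreenSpace(id=next_id, entrance_nodes=entrances, area_m2=area, level=level)
                )
                next_id += 1
    return ugs


def _ses_fields(
    cfg: ScenarioConfig, coords: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Spatially correlated SES proportions via a Gaussian copula.

    Each covariate is an independent Gaussian random field over the community
    coordinates (squared-exponential covariance, range ``ses_spatial_range_m``)
    pushed through the normal CDF and the Beta quantile function, so the
    marginal distribution hits the configured mean/sd exactly while nearby
    communities share similar values (deprivation clusters in districts).
    """
    from scipy import stats as _stats

    n = len(coords)
    ell = cfg.ses_spatial_range_m
    if ell > 0:
        d2 = (coords[:, 0:1] - coords[None, :, 0]) ** 2 + (
            coords[:, 1:2] - coords[None, :, 1]
        ) ** 2
        C = np.exp(-d2 / (2.0 * ell**2)) + 1e-8 * np.eye(n)
        L = np.linalg.cholesky(C)
    else:
        L = None
    out = {}
    for name, (m, s) in cfg.ses_params.items():
        a, b = _beta_params(m, s)
        z = rng.standard_normal(n)
        if L is not None:
            z = L @ z
        # re-standardize the realized field so the sample moments hit the
        # Beta targets regardless of how much variance the spatial draw
        # happened to absorb
        z = (z - z.mean()) / z.std(ddof=1)
        out[name] = _stats.beta.ppf(_stats.norm.cdf(z), a, b)
    return out


def generate_city(cfg: ScenarioConfig) -> SyntheticCity:
    """Generate a full synthetic city from a scenario config (seed-determined)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    net = _grid_network(cfg, rng)
    ids, _ = net.node_array()

    comm_nodes = rng.choice(ids, size=cfg.n_communities, replace=False)
    lo, hi = cfg.population_range
    totals = rng.uniform(lo, hi, size=cfg.n_communities)
    shares = rng.dirichlet(np.array(cfg.mode_share_alpha), size=cfg.n_communities)
    cxy = np.array([net.nodes[int(nd)] for nd in comm_nodes], dtype=float)
    ses_draws = _ses_fields(cfg, cxy, rng)

    communities = []
    for i in range(cfg.n_communities):
        pops = {m: float(totals[i] * shares[i, v]) for v, m in enumerate(MODES)}
        ses = {name: float(ses_draws[name][i]) for name in cfg.ses_params}
        communities.append(
            Community(id=i, node=int(comm_nodes[i]), pop_by_mode=pops, ses=ses)
        )

    ugs = _place_ugs(cfg, net, communities, rng)
    return SyntheticCity(net=net, communities=communities, ugs=ugs)


def deprived_scenario(seed: int, coupling: float = -4.0) -> ScenarioConfig:
    """Default city with green-space placement steered away from communities
    with many less-educated residents (a strongly deprived city); coupling 0
    gives the matching no-deprivation control."""
    return ScenarioConfig(seed=seed, ses_access_coupling={"less_educated": coupling})


def generate_trip_survey(
    breakpoints: dict[str, float] | None = None,
    n_per_mode: int = 1000,
    seed: int = 0,
    slope_ratio: float = 4.0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Trip durations whose cumulative frequency curve has two linear
    segments meeting exactly at the mode's breakpoint.

    Durations are drawn from a piecewise-uniform density: constant rate up to
    the breakpoint b, then a rate ``slope_ratio`` times lower out to
    2.2*b.  ``noiseless=True`` places trips on the exact quantile grid so the
    empirical curve is the model curve.
    """
    if breakpoints is None:
        breakpoints = {"walking": 18.0, "cycling": 23.0, "public_transport": 33.0}
    if n_per_mode < 100:
        raise ValueError(f"need at least 100 trips per mode, got {n_per_mode}")
    rng = np.random.default_rng(seed)
    rows = []
    for mode, b in breakpoints.items():
        t_max = 2.2 * b
        # share of trips before the breakpoint given the slope ratio
        p = slope_ratio * b / (slope_ratio * b + (t_max - b))
        if noiseless:
            u = (np.arange(n_per_mode) + 0.5) / n_per_mode
        else:
            u = rng.uniform(size=n_per_mode)
        minutes = np.where(
            u <= p,
            u / p * b,
            b + (u - p) / (1 - p) * (t_max - b),
        )
        for t in minutes:
            rows.append({"mode": mode, "minutes": float(t)})
    return pd.DataFrame(rows)


def evolve_scenario(
    city: SyntheticCity,
    growth: GrowthConfig,
    cfg: ScenarioConfig,
    seed: int = 1,
) -> SyntheticCity:
    """Advance a city one timepoint: densify the network, scale populations,
    and add green spaces.  Community ids are preserved so change analyses can
    pair timepoints."""
    rng = np.random.default_rng(seed)
    net = city.net
    ids, xy = net.node_array()

    n_undirected = len(net.arcs) // 2
    target = int(round(growth.edge_density_multiplier * n_undirected))
    existing = set()
    for u, v, _, _ in net.arcs:
        existing.add((min(u, v), max(u, v)))
    new_arcs = list(net.arcs)
    if target > n_undirected:
        # candidate chords: node pairs within 2.2 grid spacings not yet linked
        max_d = 2.2 * cfg.spacing_m
        cands = []
        for a in range(len(ids)):
            for b_ in range(a + 1, len(ids)):
                u, v = int(ids[a]), int(ids[b_])
                if (u, v) in existing:
                    continue
                d = math.hypot(xy[a, 0] - xy[b_, 0], xy[a, 1] - xy[b_, 1])
                if d <= max_d:
                    cands.append((u, v, d))
        need = target - n_undirected
        if need > len(cands):
            raise ValueError(
                f"cannot densify: need {need} new edges, only {len(cands)} candidates"
            )
        classes = list(cfg.road_class_mix.keys())
        probs = np.array([cfg.road_class_mix[c] for c in classes])
        pick = rng.choice(len(cands), size=need, replace=False)
        cls_idx = rng.choice(len(classes), size=need, p=probs)
        for kk, ci in zip(pick, cls_idx):
            u, v, d = cands[int(kk)]
            cls = classes[int(ci)]
            new_arcs.append((u, v, d, cls))
            new_arcs.append((v, u, d, cls))
    new_net = RoadNetwork(nodes=dict(net.nodes), arcs=new_arcs)

    new_comms = []
    for c in city.communities:
        pops = {m: p * growth.population_multiplier for m, p in c.pop_by_mode.items()}
        new_comms.append(Community(id=c.id, node=c.node, pop_by_mode=pops, ses=dict(c.ses)))

    new_ugs = [
        GreenSpace(id=g.id, entrance_nodes=list(g.entrance_nodes), area_m2=g.area_m2, level=g.level)
        for g in city.ugs
    ]
    if growth.n_new_ugs > 0:
        next_id = max(g.id for g in city.ugs) + 1 if city.ugs else 0
        # keep level proportions of the base config
        total = sum(cfg.ugs_counts.values())
        counts = {}
        left = growth.n_new_ugs
        for lvl in sorted(cfg.ugs_counts):
            k = int(round(growth.n_new_ugs * cfg.ugs_counts[lvl] / total))
            k = min(k, left)
            counts[lvl] = k
            left -= k
        if left > 0:
            counts[3] = counts.get(3, 0) + left
        added = _place_ugs(cfg, new_net, new_comms, rng, start_id=next_id, counts=counts)
        new_ugs.extend(added)
    return SyntheticCity(net=new_net, communities=new_comms, ugs=new_ugs)
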