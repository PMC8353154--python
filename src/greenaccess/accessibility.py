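"""Multi-mode two-step floating catchment area (2SFCA) accessibility.

Step 1 computes, for every green space j, a supply-demand ratio

    V_j = S_j / [ sum_{k: d_jk(M1) <= d0(M1)} P_k,M1
                + sum_{k: d_jk(M2) <= d0(M2)} P_k,M2
                + sum_{k: d_jk(M3) <= d0(M3)} P_k,M3 ]

where S_j is the green-space area (m2), P_k,Mv the population of community k
travelling by mode v, d_jk(Mv) the network travel time by mode v and d0(Mv)
the mode threshold (defaults 18/23/33 min for walking/cycling/public
transport).  Step 2 sums the reachable ratios per community, weighting by the
community's mode split:

    A_i = sum_v (P_i,Mv / P_i) * sum_{j: d_ij(Mv) <= d0(Mv)} V_j

A_i is in m2 of green space per person.  Catchment membership is inclusive
(time <= threshold).  Evaluating step 2 in this mode-share form is
algebraically identical to the population-weighted quotient and makes the
single-mode case reduce bit-exactly to the classic 2SFCA.

Travel time to a green space with several entrances is the minimum over its
entrances.  Travel times are assumed symmetric (undirected network), so the
same community -> entrance matrix serves both steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    MODES,
    ModeSpeedTable,
    RoadNetwork,
    TravelTimeMatrix,
    travel_time_matrix,
)

LEVELS = (1, 2, 3)

#: National Ecological Garden City per-capita green-space standard, m2/person
GARDEN_CITY_STANDARD_M2 = 12.0


@dataclass
class Community:
    """Demand point: a residential community anchored to a network node."""

    id: int
    node: int
    pop_by_mode: dict[str, float]
    ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, p in self.pop_by_mode.items():
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}")
            if p < 0:
                raise ValueError(f"negative population for mode {m}")
        for k, v in self.ses.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SES proportion {k}={v} outside [0, 1]")

    @property
    def total_pop(self) -> float:
        return float(sum(self.pop_by_mode.get(m, 0.0) for m in MODES))


@dataclass
class GreenSpace:
    """Supply point set: one green space with one or more entrance nodes.

    Belt-shaped parks are represented as several GreenSpace records whose
    areas partition the original area.
    """

    id: int
    entrance_nodes: list[int]
    area_m2: float
    level: int = 3

    def __post_init__(self) -> None:
        if not self.entrance_nodes:
            raise ValueError(f"green space {self.id} has no entrances")
        if not self.area_m2 > 0:
            raise ValueError(f"green space {self.id} area must be > 0")
        if self.level not in LEVELS:
            raise ValueError(f"green space {self.id} level must be in {LEVELS}")


@dataclass(frozen=True)
class AccessConfig:
    """Mode-specific catchment thresholds d0 in minutes."""

    thresholds_min: dict[str, float] = field(
        default_factory=lambda: {"walking": 18.0, "cycling": 23.0, "public_transport": 33.0}
    )

    def __post_init__(self) -> None:
        for m in MODES:
            if m not in self.thresholds_min:
                raise ValueError(f"missing threshold for mode {m}")
            if not self.thresholds_min[m] > 0:
                raise ValueError(f"threshold for {m} must be > 0")


@dataclass
class SupplyDemandRatios:
    """Step-1 output: V_j in m2/person, plus zero-demand flags."""

    V: dict[int, float]
    zero_demand: set[int]


@dataclass
class AccessResult:
    """Per-community accessibility in m2/person.

    ``table`` is indexed by community id with columns walking, cycling,
    public_transport, integrated; level-stratified runs add
    ``integrated_level1..3`` columns.
    """

    table: pd.DataFrame


def compute_mode_travel_times(
    net: RoadNetwork,
    communities: list[Community],
    ugs_list: list[GreenSpace],
    speeds: ModeSpeedTable | None = None,
) -> dict[str, TravelTimeMatrix]:
    """Per-mode travel-time matrices from community anchors (sorted by
    community id) to every distinct green-space entrance node."""
    origins = [c.node for c in sorted(communities, key=lambda c: c.id)]
    dests = sorted({e for g in ugs_list for e in g.entrance_nodes})
    return {
        mode: travel_time_matrix(net, origins, dests, mode, speeds) for mode in MODES
    }


def ugs_travel_time(ttm: TravelTimeMatrix, ugs: GreenSpace) -> np.ndarray:
    """Minutes from every TTM origin to green space ``ugs``: min over entrances."""
    cols = [ttm.destinations.index(e) for e in ugs.entrance_nodes]
    return ttm.minutes[:, cols].min(axis=1)


def _ugs_time_table(
    ttms: dict[str, TravelTimeMatrix], ugs_list: list[GreenSpace]
) -> dict[str, np.ndarray]:
    """Per mode: (n_communities, n_ugs) minutes, min over entrances, ugs sorted by id."""
    ugs_sorted = sorted(ugs_list, key=lambda g: g.id)
    out = {}
    for mode in MODES:
        ttm = ttms[mode]
        out[mode] = np.column_stack([ugs_travel_time(ttm, g) for g in ugs_sorted])
    return out


def supply_demand_ratios(
    ugs_list: list[GreenSpace],
    communities: list[Community],
    ttms: dict[str, TravelTimeMatrix],
    cfg: AccessConfig | None = None,
) -> SupplyDemandRatios:
    """Step 1: supply-demand ratio V_j per green space.

    Each mode's catchment sums that mode's population; a green space no
    population can reach gets V_j = 0 and is flagged zero-demand.
    TTM origins must be ordered like ``sorted(communities, key=id)``.
    """
    cfg = cfg or AccessConfig()
    comms = sorted(communities, key=lambda c: c.id)
    ugs_sorted = sorted(ugs_list, key=lambda g: g.id)
    times = _ugs_time_table(ttms, ugs_list)

    V: dict[int, float] = {}
    zero_demand: set[int] = set()
    for j, g in enumerate(ugs_sorted):
        demand = 0.0
        for mode in MODES:
            d0 = cfg.thresholds_min[mode]
            col = times[mode][:, j]
            for i, c in enumerate(comms):
                if col[i] <= d0:
                    demand += c.pop_by_mode.get(mode, 0.0)
        if demand > 0:
            V[g.id] = g.area_m2 / demand
        else:
            V[g.id] = 0.0
            zero_demand.add(g.id)
    return SupplyDemandRatios(V=V, zero_demand=zero_demand)


def accessibility_scores(
    communities: list[Community],
    ugs_list: list[GreenSpace],
    ratios: SupplyDemandRatios,
    ttms: dict[str, TravelTimeMatrix],
    cfg: AccessConfig | None = None,
) -> AccessResult:
    """Step 2: per-community accessibility, integrated and per mode.

    The integrated score weights each mode's reachable-ratio sum by the
    community's mode share.  Per-mode columns place the whole population on
    that mode (so they equal the plain reachable-ratio sum).  Communities
    with zero total population are excluded with a warning (NaN rows).
    """
    cfg = cfg or AccessConfig()
    comms = sorted(communities, key=lambda c: c.id)
    ugs_sorted = sorted(ugs_list, key=lambda g: g.id)
    times = _ugs_time_table(ttms, ugs_list)

    rows = {}
    excluded = []
    for i, c in enumerate(comms):
        sums = {}
        for mode in MODES:
            d0 = cfg.thresholds_min[mode]
            col = times[mode][i, :]
            sv = 0.0
            for j, g in enumerate(ugs_sorted):
                if col[j] <= d0:
                    sv += ratios.V[g.id]
            sums[mode] = sv
        P = c.total_pop
        if P <= 0:
            excluded.append(c.id)
            rows[c.id] = {**sums, "integrated": np.nan}
            continue
        integrated = 0.0
        for mode in MODES:
            w = c.pop_by_mode.get(mode, 0.0) / P
            integrated += w * sums[mode]
        rows[c.id] = {**sums, "integrated": integrated}
    if excluded:
        warnings.warn(
            f"{len(excluded)} community(ies) with zero population excluded: {excluded}",
            stacklevel=2,
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "community_id"
    return AccessResult(table=table)


def stratified_accessibility(
    communities: list[Community],
    ugs_list: list[GreenSpace],
    ttms: dict[str, TravelTimeMatrix],
    cfg: AccessConfig | None = None,
) -> AccessResult:
    """Accessibility recomputed per green-space level plus the total.

    V_j depends only on green space j's own catchment, so the total over all
    green spaces equals the sum of the three level-restricted runs.
    Output adds ``<col>_level1..3`` columns for every score column.
    """
    cfg = cfg or AccessConfig()
    full = accessibility_scores(
        communities, ugs_list, supply_demand_ratios(ugs_list, communities, ttms, cfg), ttms, cfg
    )
    table = full.table.copy()
    for lvl in LEVELS:
        subset = [g for g in ugs_list if g.level == lvl]
        if subset:
            res = accessibility_scores(
                communities, subset, supply_demand_ratios(subset, communities, ttms, cfg), ttms, cfg
            )
            sub = res.table
        else:
            sub = pd.DataFrame(0.0, index=table.index, columns=table.columns)
        for col in ("walking", "cycling", "public_transport", "integrated"):
            table[f"{col}_level{lvl}"] = sub[col]
    return AccessResult(table=table)


def estimate_threshold(
    trips: pd.DataFrame, min_trips: int = 30
) -> dict[str, float]:
    """Catchment threshold per mode from a trip survey.

    Builds the cumulative trip-frequency curve (share of trips taking at
    most t minutes, on an integer-minute grid) and fits a continuous
    two-segment piecewise-linear function by least squares for every interior
    integer breakpoint; the breakpoint minimizing the SSE is the threshold.
    A breakpoint landing on the search boundary (no interior slope change)
    triggers a warning.
    """
    out = {}
    for mode, grp in trips.groupby("mode"):
        minutes = np.asarray(grp["minutes"], dtype=float)
        if len(minutes) < min_trips:
            raise ValueError(
                f"mode {mode!r}: {len(minutes)} trips < required minimum {min_trips}"
            )
        t_lo = int(np.floor(minutes.min()))
        t_hi = int(np.ceil(minutes.max()))
        grid = np.arange(t_lo, t_hi + 1, dtype=float)
        cum = np.array([(minutes <= t).mean() for t in grid])
        if len(grid) < 5:
            raise ValueError(f"mode {mode!r}: travel-time range too narrow to fit")
        candidates = grid[1:-1]
        best_b, best_sse = None, np.inf
        for b in candidates:
            X = np.column_stack([np.ones_like(grid), grid, np.maximum(grid - b, 0.0)])
            coef, *_ = np.linalg.lstsq(X, cum, rcond=None)
            resid = cum - X @ coef
            sse = float(resid @ resid)
            if sse < best_sse - 1e-15:
                best_b, best_sse = float(b), sse
        if best_b in (float(candidates[0]), float(candidates[-1])):
            warnings.warn(
                f"mode {mode!r}: breakpoint {best_b} lies on the search boundary; "
                "the cumulative curve may have no interior slope change",
                stacklevel=2,
            )
        out[str(mode)] = best_b
    return out


def coverage_fraction(
    ugs_list: list[GreenSpace],
    ttm: TravelTimeMatrix,
    threshold_min: float,
    level: int | None = None,
) -> float:
    """Fraction of (optionally level-filtered) green spaces reachable within
    ``threshold_min`` from at least one community."""
    subset = [g for g in ugs_list if level is None or g.level == level]
    if not subset:
        raise ValueError(f"no green spaces at level {level}")
    reached = 0
    for g in subset:
        if ugs_travel_time(ttm, g).min() <= threshold_min:
            reached += 1
    return reached / len(subset)


def flag_below_standard(
    result: AccessResult, standard_m2: float = GARDEN_CITY_STANDARD_M2
) -> pd.Series:
    """Communities whose integrated accessibility is strictly below the
    per-capita green-space standard (default 12 m2/person)."""
    return result.table["integrated"] < standard_m2
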