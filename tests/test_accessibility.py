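"""Multi-mode 2SFCA: ratios, scores, stratification, thresholds, coverage."""

import numpy as np
import pandas as pd
import pytest

from greenaccess.accessibility import (
    AccessConfig,
    Community,
    GreenSpace,
    accessibility_scores,
    compute_mode_travel_times,
    coverage_fraction,
    estimate_threshold,
    flag_below_standard,
    stratified_accessibility,
    supply_demand_ratios,
    ugs_travel_time,
)
from greenaccess.synthetic_city import ScenarioConfig, generate_city, generate_trip_survey

from conftest import make_network


@pytest.fixture
def line_setup(line_city):
    net, comms, ugs = line_city
    ttms = compute_mode_travel_times(net, comms, ugs)
    return net, comms, ugs, ttms


class TestUgsTravelTime:
    def test_minimum_over_entrances(self, line_setup):
        _, comms, ugs, ttms = line_setup
        # community 0 at node 0: entrances of ugs 0 at nodes 1 (6 min) and 2 (12 min)
        t = ugs_travel_time(ttms["walking"], ugs[0])
        assert t[0] == pytest.approx(6.0)

    def test_single_entrance(self, line_setup):
        _, comms, ugs, ttms = line_setup
        t = ugs_travel_time(ttms["walking"], ugs[1])
        assert t[0] == pytest.approx(18.0)  # 3 links x 6 min

    def test_all_entrances_unreachable_is_infinite(self):
        net = make_network(
            {0: (0, 0), 1: (500, 0), 2: (1000, 0)},
            [(0, 1, 500.0, "highway"), (1, 2, 500.0, "highway")],
        )
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 10.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1, 2], area_m2=100.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        assert np.isinf(ugs_travel_time(ttms["walking"], g[0])[0])


class TestSupplyDemandRatios:
    def test_single_catchment_arithmetic(self):
        net = make_network({0: (0, 0), 1: (500, 0)}, [(0, 1, 500.0, "main_street")])
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 500.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=10000.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        ratios = supply_demand_ratios(g, comm, ttms)
        assert ratios.V[0] == 20.0

    def test_mixed_mode_denominator(self):
        # 100 walkers reach within 18 min and 200 cyclists within 23 min
        net = make_network({0: (0, 0), 1: (1000, 0)}, [(0, 1, 1000.0, "main_street")])
        comms = [
            Community(id=0, node=0, pop_by_mode={"walking": 100.0, "cycling": 0.0, "public_transport": 0.0}),
            Community(id=1, node=0, pop_by_mode={"walking": 0.0, "cycling": 200.0, "public_transport": 0.0}),
        ]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=9000.0)]
        ttms = compute_mode_travel_times(net, comms, g)
        ratios = supply_demand_ratios(g, comms, ttms)
        assert ratios.V[0] == 30.0

    def test_zero_demand_flagged(self):
        net = make_network({0: (0, 0), 1: (50000, 0)}, [(0, 1, 50000.0, "main_street")])
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 10.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=100.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        ratios = supply_demand_ratios(g, comm, ttms)
        assert ratios.V[0] == 0.0 and 0 in ratios.zero_demand

    def test_inclusive_catchment_boundary(self):
        # exactly 18.0 walking minutes: 1500 m at 5 km/h
        net = make_network({0: (0, 0), 1: (1500, 0)}, [(0, 1, 1500.0, "main_street")])
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 100.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=1800.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        assert ttms["walking"].time(0, 1) == 18.0
        ratios = supply_demand_ratios(g, comm, ttms)
        assert ratios.V[0] == 18.0


class TestAccessibilityScores:
    def test_single_community_single_ugs(self):
        net = make_network({0: (0, 0), 1: (500, 0)}, [(0, 1, 500.0, "main_street")])
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 500.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=10000.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        res = accessibility_scores(comm, g, supply_demand_ratios(g, comm, ttms), ttms)
        assert res.table.loc[0, "integrated"] == 20.0
        assert res.table.loc[0, "walking"] == 20.0

    def test_unreachable_community_scores_zero(self):
        net = make_network({0: (0, 0), 1: (80000, 0)}, [(0, 1, 80000.0, "main_street")])
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 100.0, "cycling": 0.0, "public_transport": 0.0})]
        g = [GreenSpace(id=0, entrance_nodes=[1], area_m2=100.0)]
        ttms = compute_mode_travel_times(net, comm, g)
        res = accessibility_scores(comm, g, supply_demand_ratios(g, comm, ttms), ttms)
        assert res.table.loc[0, "integrated"] == 0.0

    def test_zero_population_community_excluded_with_warning(self, line_city):
        net, comms, ugs = line_city
        comms = comms + [
            Community(id=9, node=2, pop_by_mode={"walking": 0.0, "cycling": 0.0, "public_transport": 0.0})
        ]
        ttms = compute_mode_travel_times(net, comms, ugs)
        ratios = supply_demand_ratios(ugs, comms, ttms)
        with pytest.warns(UserWarning, match="zero population"):
            res = accessibility_scores(comms, ugs, ratios, ttms)
        assert np.isnan(res.table.loc[9, "integrated"])

    def test_toy_instance_matches_hand_enumerated_brute_force(self):
        """3 communities x 2 green spaces: engine equals direct enumeration of
        the two-step formula over every (community, ugs, mode) triple."""
        nodes = {i: (700.0 * i, 0.0) for i in range(7)}
        edges = [(i, i + 1, 700.0, "main_street") for i in range(6)]
        net = make_network(nodes, edges)
        comms = [
            Community(id=0, node=0, pop_by_mode={"walking": 300.0, "cycling": 100.0, "public_transport": 50.0}),
            Community(id=1, node=3, pop_by_mode={"walking": 80.0, "cycling": 20.0, "public_transport": 400.0}),
            Community(id=2, node=6, pop_by_mode={"walking": 0.0, "cycling": 500.0, "public_transport": 100.0}),
        ]
        ugs = [
            GreenSpace(id=0, entrance_nodes=[1], area_m2=5000.0),
            GreenSpace(id=1, entrance_nodes=[5, 6], area_m2=20000.0),
        ]
        ttms = compute_mode_travel_times(net, comms, ugs)
        cfg = AccessConfig()
        res = accessibility_scores(comms, ugs, supply_demand_ratios(ugs, comms, ttms, cfg), ttms, cfg)

        # independent enumeration from the formula
        thr = cfg.thresholds_min
        times = {
            m: {
                (c.id, g.id): min(ttms[m].time(c.node, e) for e in g.entrance_nodes)
                for c in comms
                for g in ugs
            }
            for m in thr
        }
        V = {}
        for g in ugs:
            demand = sum(
                c.pop_by_mode[m]
                for m in thr
                for c in comms
                if times[m][(c.id, g.id)] <= thr[m]
            )
            V[g.id] = g.area_m2 / demand if demand > 0 else 0.0
        for c in comms:
            P = sum(c.pop_by_mode.values())
            expected = (
                sum(
                    c.pop_by_mode[m]
                    * sum(V[g.id] for g in ugs if times[m][(c.id, g.id)] <= thr[m])
                    for m in thr
                )
                / P
            )
            assert res.table.loc[c.id, "integrated"] == pytest.approx(expected, rel=1e-12)


@pytest.fixture(scope="module")
def random_city():
    city = generate_city(ScenarioConfig(seed=77, n_communities=60, grid_nx=10, grid_ny=10))
    ttms = compute_mode_travel_times(city.net, city.communities, city.ugs)
    return city, ttms


class TestInvariants:
    def test_conservation_of_supply(self, random_city):
        """Total population-weighted accessibility equals total green area
        (zero-demand spaces excluded)."""
        city, ttms = random_city
        ratios = supply_demand_ratios(city.ugs, city.communities, ttms)
        res = accessibility_scores(city.communities, city.ugs, ratios, ttms)
        lhs = sum(c.total_pop * res.table.loc[c.id, "integrated"] for c in city.communities)
        rhs = sum(g.area_m2 for g in city.ugs if g.id not in ratios.zero_demand)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_supply_linearity(self, random_city):
        city, ttms = random_city
        ratios = supply_demand_ratios(city.ugs, city.communities, ttms)
        res = accessibility_scores(city.communities, city.ugs, ratios, ttms)
        scaled_ugs = [
            GreenSpace(id=g.id, entrance_nodes=g.entrance_nodes, area_m2=3.0 * g.area_m2, level=g.level)
            for g in city.ugs
        ]
        ratios3 = supply_demand_ratios(scaled_ugs, city.communities, ttms)
        res3 = accessibility_scores(city.communities, scaled_ugs, ratios3, ttms)
        assert np.allclose(res3.table["integrated"], 3.0 * res.table["integrated"], rtol=1e-12)

    def test_adding_population_never_increases_ratios(self, random_city):
        city, ttms = random_city
        ratios = supply_demand_ratios(city.ugs, city.communities, ttms)
        boosted = [
            Community(
                id=c.id,
                node=c.node,
                pop_by_mode={m: p + 50.0 for m, p in c.pop_by_mode.items()},
                ses=c.ses,
            )
            for c in city.communities
        ]
        ratios_b = supply_demand_ratios(city.ugs, boosted, ttms)
        for gid in ratios.V:
            assert ratios_b.V[gid] <= ratios.V[gid] + 1e-15

    def test_raising_thresholds_never_shrinks_catchments(self, random_city):
        city, ttms = random_city
        lo = AccessConfig(thresholds_min={"walking": 10.0, "cycling": 15.0, "public_transport": 20.0})
        hi = AccessConfig(thresholds_min={"walking": 18.0, "cycling": 23.0, "public_transport": 33.0})
        r_lo = supply_demand_ratios(city.ugs, city.communities, ttms, lo)
        r_hi = supply_demand_ratios(city.ugs, city.communities, ttms, hi)
        # a green space with demand at low thresholds cannot lose it at high
        assert r_lo.zero_demand >= r_hi.zero_demand


class TestStratified:
    def test_all_level3_means_level3_equals_total(self, line_setup):
        net, comms, _, _ = line_setup
        ugs = [
            GreenSpace(id=0, entrance_nodes=[1], area_m2=10000.0, level=3),
            GreenSpace(id=1, entrance_nodes=[3], area_m2=9000.0, level=3),
        ]
        ttms = compute_mode_travel_times(net, comms, ugs)
        res = stratified_accessibility(comms, ugs, ttms)
        assert np.allclose(res.table["integrated_level3"], res.table["integrated"])
        assert (res.table["integrated_level1"] == 0).all()
        assert (res.table["integrated_level2"] == 0).all()

    def test_levels_sum_to_total_on_random_city(self):
        city = generate_city(ScenarioConfig(seed=5, n_communities=50, grid_nx=9, grid_ny=9))
        ttms = compute_mode_travel_times(city.net, city.communities, city.ugs)
        res = stratified_accessibility(city.communities, city.ugs, ttms)
        for col in ("walking", "cycling", "public_transport", "integrated"):
            total = res.table[[f"{col}_level{k}" for k in (1, 2, 3)]].sum(axis=1)
            assert np.allclose(total, res.table[col], rtol=1e-9, atol=1e-12)


class TestEstimateThreshold:
    def test_recovers_noiseless_planted_breakpoints_exactly(self):
        trips = generate_trip_survey(noiseless=True)
        est = estimate_threshold(trips)
        assert est == {"walking": 18.0, "cycling": 23.0, "public_transport": 33.0}

    def test_recovers_noisy_breakpoints_within_one_minute(self):
        trips = generate_trip_survey(seed=4)
        est = estimate_threshold(trips)
        for mode, b in {"walking": 18.0, "cycling": 23.0, "public_transport": 33.0}.items():
            assert abs(est[mode] - b) <= 1.0

    def test_too_few_trips_rejected(self):
        trips = pd.DataFrame({"mode": ["walking"] * 10, "minutes": np.linspace(1, 30, 10)})
        with pytest.raises(ValueError, match="minimum"):
            estimate_threshold(trips)

    def test_linear_curve_hits_boundary_with_warning(self):
        # half-integer minutes, equally weighted: the cumulative curve is
        # exactly linear at integer grid points, so no interior slope change
        minutes = np.repeat(np.arange(40) + 0.5, 10)
        trips = pd.DataFrame({"mode": "walking", "minutes": minutes})
        with pytest.warns(UserWarning, match="boundary"):
            estimate_threshold(trips)


class TestCoverageAndStandard:
    def test_coverage_fraction_counts_reachable_spaces(self):
        # single community at node 0 on the line: entrances at 6/12/18 min
        nodes = {i: (500.0 * i, 0.0) for i in range(4)}
        edges = [(i, i + 1, 500.0, "main_street") for i in range(3)]
        net = make_network(nodes, edges)
        comm = [Community(id=0, node=0, pop_by_mode={"walking": 10.0, "cycling": 0.0, "public_transport": 0.0})]
        ugs3 = [
            GreenSpace(id=0, entrance_nodes=[1], area_m2=100.0),
            GreenSpace(id=1, entrance_nodes=[2], area_m2=100.0),
            GreenSpace(id=2, entrance_nodes=[3], area_m2=100.0),
        ]
        ttm = compute_mode_travel_times(net, comm, ugs3)["walking"]
        assert coverage_fraction(ugs3, ttm, threshold_min=60.0) == 1.0
        assert coverage_fraction(ugs3, ttm, threshold_min=1.0) == 0.0
        assert coverage_fraction(ugs3, ttm, threshold_min=13.0) == pytest.approx(2 / 3)

    def test_coverage_empty_level_rejected(self, line_setup):
        _, _, ugs, ttms = line_setup
        with pytest.raises(ValueError, match="level 1"):
            coverage_fraction(ugs, ttms["walking"], 10.0, level=1)

    def test_below_standard_flag_is_strict(self):
        from greenaccess.accessibility import AccessResult

        table = pd.DataFrame({"integrated": [11.9, 12.0, 0.0]}, index=[0, 1, 2])
        flags = flag_below_standard(AccessResult(table=table))
        assert flags.tolist() == [True, False, True]
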