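"""Transport graph construction and improved node-cost travel costs."""

import math

import numpy as np
import pytest

import medaccess as m
from medaccess.network import AccessParams, RoadSegment, build_network, od_cost


def straight_road(length_m, road_class="county", y=0.0):
    return RoadSegment(((0.0, y), (length_m, y)), road_class)


class TestBuildNetwork:
    def test_single_national_segment_time(self):
        """An 80 km national road is one edge traversed in 60 minutes."""
        net = build_network([straight_road(80_000.0, "national")])
        (_, _, data), = net.graph.edges(data=True)
        assert data["time_min"] == pytest.approx(60.0)
        assert data["length_m"] == pytest.approx(80_000.0)

    def test_rail_filtered_without_flag(self):
        segs = [straight_road(10_000.0), RoadSegment(((0, 0), (0, 5000)), "rail_ordinary")]
        net = build_network(segs, include_rail=False)
        assert all(not d["is_rail"] for _, _, d in net.graph.edges(data=True))
        net2 = build_network(segs, include_rail=True)
        assert any(d["is_rail"] for _, _, d in net2.graph.edges(data=True))

    def test_crossing_creates_shared_node(self):
        """Two crossing roads share a node at the intersection with 4 incident edges."""
        segs = [
            RoadSegment(((-1000.0, 0.0), (1000.0, 0.0)), "county"),
            RoadSegment(((0.0, -1000.0), (0.0, 1000.0)), "township"),
        ]
        net = build_network(segs)
        assert net.graph.degree[(0.0, 0.0)] == 4
        assert net.n_edges == 4

    def test_rail_road_crossing_not_noded(self):
        """Rail is boarded at stations (shared endpoints), not at grade crossings."""
        segs = [
            RoadSegment(((-1000.0, 0.0), (1000.0, 0.0)), "county"),
            RoadSegment(((0.0, -1000.0), (0.0, 1000.0)), "rail_ordinary"),
        ]
        net = build_network(segs, include_rail=True)
        assert net.n_edges == 2  # neither line is split

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            build_network([RoadSegment(((5.0, 5.0), (5.0, 5.0)), "county")])

    def test_speed_defaults_from_class(self):
        assert RoadSegment(((0, 0), (1, 0)), "township").speed_kmh == 25.0
        assert RoadSegment(((0, 0), (1, 0)), "rail_highspeed").speed_kmh == 200.0


class TestAccessLeg:
    @pytest.mark.parametrize(
        "offset_m, expected_min",
        [(1000.0, 12.0),   # within walking threshold: 1 km at 5 km/h
         (2500.0, 6.0),    # beyond it: 2.5 km at 25 km/h
         (1250.0, 15.0),   # boundary is walked
         (0.0, 0.0)],
    )
    def test_two_speed_rule(self, offset_m, expected_min):
        net = build_network([straight_road(10_000.0)])
        snap, cost = m.access_leg((5000.0, offset_m), net, AccessParams())
        assert cost == pytest.approx(expected_min)
        assert snap.dist_m == pytest.approx(offset_m)

    def test_space_metric_is_raw_distance(self):
        net = build_network([straight_road(10_000.0)])
        _, cost = m.access_leg((5000.0, 3000.0), net, AccessParams(), m.SPACE_METRIC)
        assert cost == pytest.approx(3000.0)

    def test_never_snaps_to_rail(self):
        segs = [straight_road(10_000.0, y=5000.0),
                RoadSegment(((0.0, 0.0), (10_000.0, 0.0)), "rail_ordinary")]
        net = build_network(segs, include_rail=True)
        snap, _ = m.access_leg((5000.0, 100.0), net, AccessParams())
        assert snap.point[1] == pytest.approx(5000.0)


class TestOdCost:
    def test_same_edge_county_road(self):
        """4 km along a 50 km/h county road takes 4.8 minutes."""
        net = build_network([straight_road(20_000.0)])
        cost = od_cost((3000.0, 0.0), (7000.0, 0.0), net)
        assert cost == pytest.approx(4.8)

    def test_identity_zero_both_metrics(self):
        net = build_network([straight_road(10_000.0)])
        for metric in (m.TIME_METRIC, m.SPACE_METRIC):
            assert od_cost((1234.0, 56.0), (1234.0, 56.0), net, metric=metric) == 0.0

    def test_direct_candidate_removes_detour_outlier(self):
        """Two nearby points with a long network detour use the walked direct route."""
        segs = [
            RoadSegment(((0.0, 0.0), (0.0, 5000.0)), "village"),
            RoadSegment(((0.0, 5000.0), (150.0, 5000.0)), "village"),
            RoadSegment(((150.0, 5000.0), (150.0, 0.0)), "village"),
        ]
        net = build_network(segs)
        origin, dest = (0.0, -100.0), (150.0, -100.0)
        got = od_cost(origin, dest, net)
        assert got == pytest.approx(150.0 / 5000.0 * 60.0)  # 1.8 min walking
        plain = od_cost(origin, dest, net, AccessParams(direct_rule="network"))
        assert plain > 10.0

    def test_literal_conditional_rule(self):
        """The literal rule uses the direct route only when cheaper than both legs."""
        segs = [
            RoadSegment(((0.0, 0.0), (0.0, 5000.0)), "village"),
            RoadSegment(((0.0, 5000.0), (150.0, 5000.0)), "village"),
            RoadSegment(((150.0, 5000.0), (150.0, 0.0)), "village"),
        ]
        net = build_network(segs)
        lit = AccessParams(direct_rule="literal")
        # direct (1.8 min) < legs (1.2 + 1.2 = 2.4 min) -> direct chosen
        assert od_cost((0.0, -100.0), (150.0, -100.0), net, lit) == pytest.approx(1.8)
        # distant pair near the road: direct (12.5 min) > legs (2.4 min)
        # -> literal keeps the slower network route, min rule would not
        o, d = (0.0, -100.0), (150.0, 5100.0)
        network_route = 1.2 + (5000.0 + 150.0) / 15_000.0 * 60.0 + 1.2
        assert od_cost(o, d, net, lit) == pytest.approx(network_route)
        assert od_cost(o, d, net) < network_route

    def test_improved_never_exceeds_plain(self, fixture_region):
        cells, facs = fixture_region.cells, fixture_region.facilities
        net = fixture_region.network
        improved = m.cost_matrix(cells, facs, net, AccessParams())
        plain = m.cost_matrix(cells, facs, net, AccessParams(direct_rule="network"))
        assert np.all(improved.values <= plain.values + 1e-9)

    def test_time_cost_lower_bound(self, fixture_region, fixture_time_costs):
        """No trip is faster than the crow-flies distance at the top network speed."""
        cells, facs = fixture_region.cells, fixture_region.facilities
        vmax = 50.0 * 1000.0 / 60.0  # fastest road class in the fixture, m/min
        for i, c in enumerate(cells):
            for j, f in enumerate(facs):
                d = math.dist((c.x, c.y), (f.x, f.y))
                assert fixture_time_costs.values[i, j] >= d / vmax - 1e-9


class TestCostMatrix:
    def test_rail_never_increases_time(self, fixture_region):
        cells = fixture_region.cells
        ter = fixture_region.facilities_by_level("tertiary")
        no_rail = m.cost_matrix(cells, ter, fixture_region.network)
        with_rail = m.cost_matrix(cells, ter, fixture_region.network_with_rail)
        assert np.all(with_rail.values <= no_rail.values + 1e-9)
        assert with_rail.values.sum() < no_rail.values.sum()

    def test_adding_facility_appends_column(self, fixture_region):
        cells, facs = fixture_region.cells, fixture_region.facilities
        net = fixture_region.network
        base = m.cost_matrix(cells, facs[:3], net)
        full = m.cost_matrix(cells, facs, net)
        np.testing.assert_allclose(base.values, full.values[:, :3])

    def test_space_metric_ignores_speeds(self, fixture_region):
        cells, facs = fixture_region.cells, fixture_region.facilities
        fast = [m.RoadSegment(s.coords, s.road_class, s.speed_kmh * 2)
                for s in fixture_region.segments]
        net_fast = build_network(fast)
        a = m.cost_matrix(cells, facs, fixture_region.network, metric=m.SPACE_METRIC)
        b = m.cost_matrix(cells, facs, net_fast, metric=m.SPACE_METRIC)
        np.testing.assert_allclose(a.values, b.values)
        t1 = m.cost_matrix(cells, facs, fixture_region.network)
        t2 = m.cost_matrix(cells, facs, net_fast)
        assert t2.values.sum() < t1.values.sum()

    def test_swapped_identical_coordinates_symmetric(self, fixture_region):
        net = fixture_region.network
        p, q = (3000.0, 4000.0), (11_000.0, 9000.0)
        assert od_cost(p, q, net) == pytest.approx(od_cost(q, p, net))

    def test_triangle_sanity_with_access_slack(self, fixture_region, fixture_time_costs):
        """Costs through an intermediate facility obey the relaxed triangle bound."""
        facs = fixture_region.facilities
        net = fixture_region.network
        fac_mat = m.cost_matrix(
            [m.DemandCell(id=f.id, x=f.x, y=f.y, population=0) for f in facs],
            facs, net,
        )
        legs = [m.access_leg((f.x, f.y), net, AccessParams())[1] for f in facs]
        v = fixture_time_costs.values
        for i in range(v.shape[0]):
            for a in range(len(facs)):
                for b in range(len(facs)):
                    bound = v[i, b] + fac_mat.values[b, a] + 2 * legs[b]
                    assert v[i, a] <= bound + 1e-9

    def test_csv_round_trip(self, tmp_path, fixture_time_costs):
        path = tmp_path / "costs.csv"
        fixture_time_costs.to_csv(path)
        back = m.TravelCostMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, fixture_time_costs.values)
        assert back.metric == fixture_time_costs.metric
        assert back.origin_ids == fixture_time_costs.origin_ids
        assert back.dest_ids == fixture_time_costs.dest_ids
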