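"""Geodesics, raster graphs, and least-cost paths against independent oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecobarriers import cost_paths as cp
from ecobarriers.grids import Raster


def flat_raster(n_lat=7, n_lon=7, value=0.0, lat0=30.0, lon0=10.0, step=0.5):
    """A small constant raster for hand-built path fixtures."""
    lats = lat0 + step * np.arange(n_lat)
    lons = lon0 + step * np.arange(n_lon)
    return Raster(np.full((n_lat, n_lon), value), lats, lons)


class TestGeodesic:
    def test_zero_distance(self):
        assert cp.geodesic_km(0, 0, 0, 0) == 0.0

    def test_antipodal_on_equator(self):
        assert cp.geodesic_km(0, 0, 0, 180) == pytest.approx(
            np.pi * cp.EARTH_RADIUS_KM, rel=1e-9
        )

    def test_one_degree_on_equator(self):
        # closed form: R * 1 degree in radians
        expected = cp.EARTH_RADIUS_KM * np.deg2rad(1.0)
        assert cp.geodesic_km(0, 0, 0, 1) == pytest.approx(expected, rel=1e-9)
        assert cp.geodesic_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.01)

    def test_symmetry(self):
        assert cp.geodesic_km(12.3, 45.6, -7.8, 90.1) == pytest.approx(
            cp.geodesic_km(-7.8, 90.1, 12.3, 45.6), rel=1e-12
        )


class TestBuildGraph:
    def test_interior_degree_eight(self):
        graph = cp.build_graph(flat_raster(3, 3))
        center = graph.node_of_cell[1, 1]
        degree = np.sum(graph.edges == center)
        assert degree == 8

    def test_strip_is_path_graph(self):
        graph = cp.build_graph(flat_raster(1, 5))
        assert len(graph.edges) == 4

    def test_east_west_step_shrinks_with_latitude(self):
        high = flat_raster(2, 2, lat0=60.0, step=1.0)
        low = flat_raster(2, 2, lat0=0.0, step=1.0)
        g_high = cp.build_graph(high)
        g_low = cp.build_graph(low)

        def ew_step(graph, raster):
            i = graph.node_of_cell[0, 0]
            j = graph.node_of_cell[0, 1]
            for (u, v), s in zip(graph.edges, graph.step_km):
                if {u, v} == {i, j}:
                    return s
            raise AssertionError("edge not found")

        ratio = ew_step(g_high, high) / ew_step(g_low, low)
        assert ratio == pytest.approx(np.cos(np.deg2rad(60.0)), abs=0.01)

    def test_no_land_rejected(self):
        r = flat_raster(3, 3)
        r.land_mask[:] = False
        with pytest.raises(ValueError):
            cp.build_graph(r)

    def test_sixteen_connectivity_adds_knight_moves(self):
        g8 = cp.build_graph(flat_raster(5, 5), connectivity=8)
        g16 = cp.build_graph(flat_raster(5, 5), connectivity=16)
        assert len(g16.edges) > len(g8.edges)


def _nx_oracle(graph, weights_fn, start, end):
    """Brute-force shortest path via networkx on the same weighted graph."""
    g = nx.Graph()
    for (u, v), s in zip(graph.edges, graph.step_km):
        g.add_edge(int(u), int(v), weight=weights_fn(int(u), int(v), float(s)))
    return nx.dijkstra_path_length(g, start, end)


class TestEnvCostPath:
    def test_constant_surface_zero_cost_min_length(self):
        raster = flat_raster(6, 6)
        graph = cp.build_graph(raster)
        env = np.zeros(graph.n_nodes)
        start = graph.node_of_cell[0, 0]
        end = graph.node_of_cell[5, 5]
        res = cp.env_cost_path(graph, env, start, end)
        assert res.accumulated_cost == 0.0
        # minimum-length lattice path: pure shortest path on step lengths
        expected = _nx_oracle(graph, lambda u, v, s: s, int(start), int(end))
        assert res.length_km == pytest.approx(expected, rel=1e-9)

    def test_matches_bruteforce_dijkstra_on_random_grids(self):
        rng = np.random.default_rng(42)
        for rep in range(8):
            n = 12
            raster = flat_raster(n, n)
            graph = cp.build_graph(raster)
            env = rng.normal(size=graph.n_nodes)
            start, end = rng.choice(graph.n_nodes, 2, replace=False)
            res = cp.env_cost_path(graph, env, int(start), int(end))
            c = np.abs(env - env[start])
            expected = _nx_oracle(
                graph,
                lambda u, v, s: s * (c[u] + c[v]) / 2 + cp.TIE_EPS * s,
                int(start),
                int(end),
            )
            # compare total edge weight of the chosen path to the oracle optimum
            total = sum(
                graph.step_km[graph.edge_index[(u, v)]]
                * ((c[u] + c[v]) / 2 + cp.TIE_EPS)
                for u, v in zip(res.nodes[:-1], res.nodes[1:])
            )
            assert total == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_wall_with_gap_routes_through_gap(self):
        """A high-|dEnv| wall with one zero-difference gap attracts the path."""
        raster = flat_raster(7, 7)
        graph = cp.build_graph(raster)
        env = np.zeros(graph.n_nodes)
        # vertical wall at column 3 with huge env contrast, except row 5
        for i in range(7):
            if i != 5:
                env[graph.node_of_cell[i, 3]] = 50.0
        start = graph.node_of_cell[3, 0]
        end = graph.node_of_cell[3, 6]
        res = cp.env_cost_path(graph, env, int(start), int(end))
        crossing = [n for n in res.nodes if graph.cells[n][1] == 3]
        assert len(crossing) >= 1
        assert all(graph.cells[n][0] == 5 for n in crossing)
        assert res.accumulated_cost == pytest.approx(0.0, abs=1e-9)

    def test_scaling_env_scales_cost_linearly(self):
        rng = np.random.default_rng(3)
        raster = flat_raster(8, 8)
        graph = cp.build_graph(raster)
        env = rng.normal(size=graph.n_nodes)
        start, end = 2, graph.n_nodes - 3
        base = cp.env_cost_path(graph, env, start, end)
        scaled = cp.env_cost_path(graph, env * 7.0, start, end)
        assert scaled.accumulated_cost == pytest.approx(
            7.0 * base.accumulated_cost, rel=1e-9
        )

    def test_length_at_least_geodesic(self, small_world, small_graph):
        rng = np.random.default_rng(0)
        graph = small_graph
        env = cp.node_env_values(graph, small_world.th)
        for _ in range(20):
            s, e = rng.choice(graph.n_nodes, 2, replace=False)
            res = cp.env_cost_path(graph, env, int(s), int(e))
            lat_s = graph.grid.lats[graph.cells[s][0]]
            lon_s = graph.grid.lons[graph.cells[s][1]]
            lat_e = graph.grid.lats[graph.cells[e][0]]
            lon_e = graph.grid.lons[graph.cells[e][1]]
            assert res.length_km >= cp.geodesic_km(lat_s, lon_s, lat_e, lon_e) - 1e-9


class TestTopoCostPath:
    def test_flat_terrain_cost_equals_length(self):
        raster = flat_raster(6, 6)
        graph = cp.build_graph(raster)
        res = cp.topo_cost_path(graph, np.zeros(graph.n_nodes), 0, graph.n_nodes - 1)
        assert res.accumulated_cost == pytest.approx(res.length_km, rel=1e-12)

    def test_matches_bruteforce_dijkstra(self):
        rng = np.random.default_rng(11)
        raster = flat_raster(10, 10)
        graph = cp.build_graph(raster)
        elev = rng.normal(size=graph.n_nodes) * 2000
        for _ in range(5):
            start, end = rng.choice(graph.n_nodes, 2, replace=False)
            res = cp.topo_cost_path(graph, elev, int(start), int(end))
            expected = _nx_oracle(
                graph,
                lambda u, v, s: s * (1 + abs(elev[u] - elev[v]) / (s * 1000)),
                int(start),
                int(end),
            )
            assert res.accumulated_cost == pytest.approx(expected, rel=1e-9)

    def test_flat_detour_beats_ridge_crossing(self):
        """A ridge whose crossing penalty exceeds the flat detour is avoided."""
        raster = flat_raster(5, 5, step=0.1)
        graph = cp.build_graph(raster)
        elev = np.zeros(graph.n_nodes)
        # steep ridge on column 2, rows 0..3; row 4 stays flat
        for i in range(4):
            elev[graph.node_of_cell[i, 2]] = 100000.0
        start = graph.node_of_cell[0, 0]
        end = graph.node_of_cell[0, 4]
        res = cp.topo_cost_path(graph, elev, int(start), int(end))
        ridge_nodes = {graph.node_of_cell[i, 2] for i in range(4)}
        assert not (set(res.nodes) & ridge_nodes)


class TestPairBarriers:
    def test_same_location_all_zero(self):
        raster = flat_raster(5, 5)
        graph = cp.build_graph(raster)
        rng = np.random.default_rng(1)
        th = rng.normal(size=graph.n_nodes)
        ai = rng.normal(size=graph.n_nodes)
        elev = rng.normal(size=graph.n_nodes)
        lat, lon = raster.lats[2], raster.lons[2]
        row = cp.pair_barriers(graph, (lat, lon), (lat, lon), th, ai, elev)
        assert row["geodesic_km"] == 0.0
        for f in ["th_dissim", "ai_dissim", "th_cost", "ai_cost", "topo_cost"]:
            assert row[f] == 0.0

    def test_constant_th_zero_th_cost_despite_ai_structure(self):
        raster = flat_raster(5, 5)
        graph = cp.build_graph(raster)
        rng = np.random.default_rng(2)
        th = np.zeros(graph.n_nodes)
        ai = rng.normal(size=graph.n_nodes) * 3
        elev = rng.normal(size=graph.n_nodes)
        a = (raster.lats[0], raster.lons[0])
        b = (raster.lats[4], raster.lons[4])
        row = cp.pair_barriers(graph, a, b, th, ai, elev)
        assert row["th_cost"] == pytest.approx(0.0, abs=1e-9)
        assert row["th_dissim"] == 0.0
        assert row["ai_cost"] > 0

    def test_symmetric_in_arguments(self, small_world, small_graph):
        th = cp.node_env_values(small_graph, small_world.th)
        ai = cp.node_env_values(small_graph, small_world.ai)
        elev = cp.node_env_values(small_graph, small_world.elevation)
        soc = small_world.societies
        a = (soc.at[0, "lat"], soc.at[0, "lon"])
        b = (soc.at[7, "lat"], soc.at[7, "lon"])
        r1 = cp.pair_barriers(small_graph, a, b, th, ai, elev)
        r2 = cp.pair_barriers(small_graph, b, a, th, ai, elev)
        pd.testing.assert_series_equal(r1, r2)

    def test_directional_asymmetry_before_averaging(self, small_world, small_graph):
        """Start-relative surfaces make A->B and B->A costs differ."""
        th = cp.node_env_values(small_graph, small_world.th)
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(10):
            s, e = rng.choice(small_graph.n_nodes, 2, replace=False)
            fwd = cp.env_cost_path(small_graph, th, int(s), int(e))
            rev = cp.env_cost_path(small_graph, th, int(e), int(s))
            diffs.append(abs(fwd.accumulated_cost - rev.accumulated_cost))
        assert max(diffs) > 1e-6

    def test_batch_matches_single_pair(self, small_world, small_graph):
        th = cp.node_env_values(small_graph, small_world.th)
        ai = cp.node_env_values(small_graph, small_world.ai)
        elev = cp.node_env_values(small_graph, small_world.elevation)
        soc = small_world.societies.iloc[:6]
        pairs = pd.DataFrame({"id_a": ["S0000", "S0002"], "id_b": ["S0003", "S0005"]})
        batch = cp.compute_pair_barriers(soc, pairs, small_graph, th, ai, elev)
        srow = soc.set_index("id")
        for _, row in batch.iterrows():
            a = (srow.at[row["id_a"], "lat"], srow.at[row["id_a"], "lon"])
            b = (srow.at[row["id_b"], "lat"], srow.at[row["id_b"], "lon"])
            single = cp.pair_barriers(small_graph, a, b, th, ai, elev)
            for f in cp.BARRIER_COLUMNS:
                assert row[f] == pytest.approx(single[f], rel=1e-12)
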