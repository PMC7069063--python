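"""Simulator tests: sampling, geometry, junction extraction, ensembles."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point

import nwtopo as nw
from nwtopo.exceptions import ParameterError


def params(n=10, length=8.0, disp=0.0, w=30.0, h=30.0, seed=0):
    return nw.WireEnsembleParams(n, length, disp, w, h, seed)


def wire_from_endpoints(wid, p1, p2):
    cx, cy = (p1[0] + p2[0]) / 2, (p1[1] + p2[1]) / 2
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    return nw.Wire(wid, cx, cy, math.atan2(dy, dx), math.hypot(dx, dy))


class TestSampling:
    def test_zero_dispersion_gives_exact_lengths(self):
        wires = nw.sample_wires(params(n=3, length=8.0, disp=0.0, seed=42))
        assert len(wires) == 3
        assert all(w.length == 8.0 for w in wires)

    def test_midpoints_inside_plane_and_angles_in_range(self):
        wires = nw.sample_wires(params(n=500, length=7.0, disp=0.5, seed=1))
        assert all(0 <= w.cx <= 30 and 0 <= w.cy <= 30 for w in wires)
        assert all(0 <= w.angle < 2 * math.pi for w in wires)
        assert all(w.length > 0 for w in wires)

    def test_dispersion_matches_requested_spread(self):
        wires = nw.sample_wires(params(n=20000, length=8.0, disp=0.2, seed=5))
        lengths = np.array([w.length for w in wires])
        assert lengths.mean() == pytest.approx(8.0, rel=0.01)
        assert lengths.std() == pytest.approx(1.6, rel=0.05)

    def test_same_seed_reproduces_wires(self):
        a = nw.sample_wires(params(n=50, disp=0.3, seed=9))
        b = nw.sample_wires(params(n=50, disp=0.3, seed=9))
        assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"length": 0.0},
            {"length": -2.0},
            {"disp": 1.5},
            {"disp": -0.1},
            {"w": 0.0},
            {"h": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            params(**kwargs)


class TestSegmentIntersection:
    def test_perpendicular_crossing(self):
        a = wire_from_endpoints(0, (0, 0), (2, 0))
        b = wire_from_endpoints(1, (1, -1), (1, 1))
        assert nw.segment_intersection(a, b) == pytest.approx((1.0, 0.0))

    def test_parallel_disjoint_is_none(self):
        a = wire_from_endpoints(0, (0, 0), (1, 0))
        b = wire_from_endpoints(1, (0, 1), (1, 1))
        assert nw.segment_intersection(a, b) is None

    def test_disjoint_nonparallel_is_none(self):
        a = wire_from_endpoints(0, (0, 0), (1, 0))
        b = wire_from_endpoints(1, (3, -1), (4, 1))
        assert nw.segment_intersection(a, b) is None

    def test_touching_endpoint_counts(self):
        a = wire_from_endpoints(0, (0, 0), (1, 0))
        b = wire_from_endpoints(1, (1, 0), (2, 1))
        pt = nw.segment_intersection(a, b)
        assert pt == pytest.approx((1.0, 0.0), abs=1e-9)

    def test_collinear_overlap_is_none(self):
        a = wire_from_endpoints(0, (0, 0), (2, 0))
        b = wire_from_endpoints(1, (1, 0), (3, 0))
        assert nw.segment_intersection(a, b) is None

    def test_agrees_with_shapely_on_random_pairs(self):
        rng = np.random.default_rng(0)
        wires = nw.sample_wires(params(n=2000, length=8.0, disp=0.5, seed=11))
        idx = rng.integers(0, len(wires), size=(1000, 2))
        for i, j in idx:
            if i == j:
                continue
            a, b = wires[i], wires[j]
            got = nw.segment_intersection(a, b)
            inter = LineString(a.endpoints).intersection(LineString(b.endpoints))
            if inter.is_empty:
                assert got is None
            else:
                assert got is not None
                assert got == pytest.approx((inter.x, inter.y), abs=1e-7)

    def test_agrees_with_point_sampling_oracle(self):
        # existence check: 1e4 sample points along a, min distance to b
        wires = nw.sample_wires(params(n=200, length=8.0, disp=0.3, seed=13))
        rng = np.random.default_rng(1)
        pairs = rng.integers(0, len(wires), size=(150, 2))
        for i, j in pairs:
            if i == j:
                continue
            a, b = wires[i], wires[j]
            (ax1, ay1), (ax2, ay2) = a.endpoints
            t = np.linspace(0.0, 1.0, 10_000)
            px = ax1 + t * (ax2 - ax1)
            py = ay1 + t * (ay2 - ay1)
            (bx1, by1), (bx2, by2) = b.endpoints
            sx, sy = bx2 - bx1, by2 - by1
            u = np.clip(((px - bx1) * sx + (py - by1) * sy) / (sx**2 + sy**2), 0, 1)
            d = np.hypot(px - (bx1 + u * sx), py - (by1 + u * sy))
            oracle_hit = d.min() < a.length / 2e4
            assert (nw.segment_intersection(a, b) is not None) == oracle_hit


class TestBuildNetwork:
    def test_two_crossing_wires(self):
        a = wire_from_endpoints(0, (0, 0), (2, 2))
        b = wire_from_endpoints(1, (0, 2), (2, 0))
        net = nw.build_network([a, b])
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1
        assert net.junctions[0].wire_a == 0 and net.junctions[0].wire_b == 1

    def test_empty_wire_list_rejected(self):
        with pytest.raises(ParameterError):
            nw.build_network([])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_edges_match_pairwise_bruteforce(self, seed):
        wires = nw.sample_wires(params(n=120, length=8.0, disp=0.3, seed=seed))
        net = nw.build_network(wires)
        expected = set()
        for i in range(len(wires)):
            for j in range(i + 1, len(wires)):
                if nw.segment_intersection(wires[i], wires[j]) is not None:
                    expected.add((i, j))
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected

    def test_edges_match_shapely_oracle(self):
        wires = nw.sample_wires(params(n=150, length=8.0, disp=0.2, seed=4))
        net = nw.build_network(wires)
        lines = [LineString(w.endpoints) for w in wires]
        expected = {
            (i, j)
            for i in range(len(wires))
            for j in range(i + 1, len(wires))
            if lines[i].intersects(lines[j])
        }
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected

    def test_graph_is_simple_and_mirrors_junctions(self, small_deposition):
        g = small_deposition.graph
        assert not any(u == v for u, v in g.edges)
        assert g.number_of_edges() == len(small_deposition.junctions)
        assert {(j.wire_a, j.wire_b) for j in small_deposition.junctions} == {
            tuple(sorted(e)) for e in g.edges
        }
        assert all(j.wire_a < j.wire_b for j in small_deposition.junctions)

    def test_junctions_lie_on_both_segments(self, small_deposition):
        wires = small_deposition.wires
        for j in small_deposition.junctions:
            for w in (wires[j.wire_a], wires[j.wire_b]):
                line = LineString(w.endpoints)
                assert line.distance(Point(j.x, j.y)) < 1e-9 * w.length + 1e-12

    @pytest.mark.parametrize("n", [100, 500])
    def test_mean_junction_count_near_buffon_estimate(self, n):
        counts = [
            nw.build_network(
                nw.sample_wires(params(n=n, length=8.0, disp=0.0, seed=s))
            ).n_junctions
            for s in range(20)
        ]
        est = nw.expected_junctions(n, 8.0, 900.0)
        assert abs(np.mean(counts) - est) <= 0.15 * est

    def test_longer_wires_make_more_junctions(self):
        def mean_edges(length):
            return np.mean([
                nw.build_network(
                    nw.sample_wires(params(n=200, length=length, seed=s))
                ).graph.number_of_edges()
                for s in range(10)
            ])

        means = [mean_edges(l) for l in (6.0, 7.0, 8.0, 9.0)]
        assert all(a < b for a, b in zip(means, means[1:]))


class TestEnsemble:
    def test_grid_cardinality_and_distinct_params(self):
        nets = nw.generate_ensemble(
            {"n_wires": [100, 500], "mean_length": [6, 9], "dispersion": [0, 0.5]},
        )
        assert len(nets) == 8
        combos = {
            (n.params.n_wires, n.params.mean_length, n.params.dispersion)
            for n in nets
        }
        assert len(combos) == 8

    def test_replicates_multiply_count(self):
        nets = nw.generate_ensemble(
            {"n_wires": [50], "mean_length": [8], "dispersion": [0]}, replicates=3
        )
        assert len(nets) == 3
        assert len({n.params.seed for n in nets}) == 3

    def test_same_master_seed_reproduces_ensemble(self):
        grid = {"n_wires": [60], "mean_length": [7, 8], "dispersion": [0, 0.2]}
        a = nw.generate_ensemble(grid, seed=5)
        b = nw.generate_ensemble(grid, seed=5)
        assert [n.wires for n in a] == [n.wires for n in b]
        assert [sorted(n.graph.edges) for n in a] == [sorted(n.graph.edges) for n in b]

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            nw.generate_ensemble({"n_wires": [], "mean_length": [8], "dispersion": [0]})

    def test_member_recreatable_from_recorded_params(self):
        net = nw.generate_ensemble(
            {"n_wires": [80], "mean_length": [8], "dispersion": [0.2]}, seed=3
        )[0]
        again = nw.build_network(nw.sample_wires(net.params), net.params)
        assert sorted(again.graph.edges) == sorted(net.graph.edges)
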