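import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specimenflow.network import (FlowNetwork, apply_weight_threshold,
                                  build_flow_network, collapse_undirected,
                                  compute_metrics, density,
                                  giant_component_fraction, metrics_by_slice,
                                  modularity_louvain, network_complexity,
                                  network_size, node_strengths, reciprocity,
                                  top_k_edges)

import oracles


def net_from_edges(edges, domestic=None):
    return FlowNetwork(edges=dict(edges), domestic=dict(domestic or {}))


def random_digraph(rng, max_nodes=12):
    n = rng.randint(2, max_nodes)
    nodes = [f"C{i:02d}" for i in range(n)]
    edges = {}
    for o in nodes:
        for h in nodes:
            if o != h and rng.random() < 0.25:
                edges[(o, h)] = rng.randint(1, 20)
    return edges


class TestBuild:
    def test_additive_aggregation(self, make_record):
        records = [make_record("KEN", "USA", 1), make_record("KEN", "USA", 1),
                   make_record("KEN", "USA", 2)]
        net = build_flow_network(records)
        assert net.edges == {("KEN", "USA"): 4}
        assert net.nodes == {"KEN", "USA"}

    def test_self_loop_to_domestic_ledger(self, make_record):
        net = build_flow_network([make_record("USA", "USA", 5)])
        assert net.edges == {}
        assert net.domestic == {"USA": 5}
        assert net.nodes == set()

    def test_hand_traced_six_record_slice(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        assert net.edges == {("KEN", "USA"): 3, ("BRA", "USA"): 4,
                             ("USA", "KEN"): 6, ("BRA", "NOR"): 7}
        assert net.domestic == {"USA": 5}
        assert network_size(net) == 4
        assert network_complexity(net) == 4
        assert density(net) == pytest.approx(4 / 12)
        assert reciprocity(net) == pytest.approx(0.5)
        assert giant_component_fraction(net) == 1.0

    def test_family_and_period_slicing(self, six_record_slice, make_record):
        records = six_record_slice + [
            make_record("KEN", "USA", 9, family="Canidae"),
            make_record("KEN", "USA", 9, year=2000),
        ]
        net = build_flow_network(records, family="Felidae",
                                 period="1930-1959")
        assert net.edges[("KEN", "USA")] == 3

    def test_empty_slice_is_valid(self):
        net = build_flow_network([])
        assert network_size(net) == 0
        assert network_complexity(net) == 0
        assert density(net) == 0.0
        assert reciprocity(net) is None
        assert giant_component_fraction(net) is None


class TestMetricExamples:
    def test_density_formula(self):
        # bidirectional 5-cycle: 5 nodes, 10 edges -> 10/20
        edges = {}
        for i in range(5):
            a, b = f"N{i}", f"N{(i + 1) % 5}"
            edges[(a, b)] = 1
            edges[(b, a)] = 1
        assert density(net_from_edges(edges)) == pytest.approx(0.5)

    def test_complete_digraph_density_one(self):
        edges = {(f"N{i}", f"N{j}"): 1
                 for i in range(4) for j in range(4) if i != j}
        assert density(net_from_edges(edges)) == 1.0

    def test_single_edge_density(self):
        assert density(net_from_edges({("A", "B"): 1})) == 0.5

    def test_reciprocity_two_thirds(self):
        net = net_from_edges({("A", "B"): 1, ("B", "A"): 9, ("A", "C"): 2})
        assert reciprocity(net) == pytest.approx(2 / 3)

    def test_reciprocity_symmetric_is_one(self):
        net = net_from_edges({("A", "B"): 1, ("B", "A"): 1,
                              ("B", "C"): 4, ("C", "B"): 2})
        assert reciprocity(net) == 1.0

    def test_reciprocity_no_mutual_pairs(self):
        net = net_from_edges({("A", "B"): 1, ("B", "C"): 1})
        assert reciprocity(net) == 0.0

    def test_star_network_size(self):
        edges = {(f"S{i}", "HUB"): 1 for i in range(5)}
        assert network_size(net_from_edges(edges)) == 6

    def test_giant_fraction_split(self):
        net = net_from_edges({("A", "B"): 1, ("C", "D"): 1})
        assert giant_component_fraction(net) == 0.5

    def test_edge_weight_blindness(self):
        a = net_from_edges({("A", "B"): 1, ("B", "A"): 1})
        b = net_from_edges({("A", "B"): 99, ("B", "A"): 1})
        assert reciprocity(a) == reciprocity(b) == 1.0


class TestOracleEquivalence:
    def test_200_random_graphs(self):
        rng = random.Random(1234)
        for _ in range(200):
            edges = random_digraph(rng)
            net = net_from_edges(edges)
            nodes = net.nodes
            assert density(net) == pytest.approx(
                oracles.density_bruteforce(edges, nodes), abs=0)
            rec = reciprocity(net)
            orc = oracles.reciprocity_bruteforce(edges)
            if orc is None:
                assert rec is None
            else:
                assert rec == pytest.approx(orc, abs=0)
            gf = giant_component_fraction(net)
            ogf = oracles.giant_fraction_unionfind(edges, nodes)
            if ogf is None:
                assert gf is None
            else:
                assert gf == pytest.approx(ogf, abs=0)


class TestLouvain:
    def test_two_triangles_partition_and_modularity(self):
        edges = {("A", "B"): 1, ("B", "C"): 1, ("C", "A"): 1,
                 ("D", "E"): 1, ("E", "F"): 1, ("F", "D"): 1}
        net = net_from_edges(edges)
        q, partition = modularity_louvain(net, seed=7)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert partition["A"] == partition["B"] == partition["C"]
        assert partition["D"] == partition["E"] == partition["F"]
        assert partition["A"] != partition["D"]
        # exhaustive-search optimum agrees
        undirected = {tuple(sorted(k)): w for k, w in edges.items()}
        best = oracles.max_modularity_exhaustive(undirected, list(net.nodes))
        assert q == pytest.approx(best, abs=1e-9)

    def test_single_community_q_zero(self):
        edges = {("A", "B"): 2, ("B", "C"): 1, ("C", "A"): 3}
        g = collapse_undirected(net_from_edges(edges))
        undirected = {tuple(sorted(k)): w for k, w in edges.items()}
        q = oracles.modularity_undirected(
            undirected, {n: 0 for n in g.nodes})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism(self):
        rng = random.Random(5)
        edges = random_digraph(rng, max_nodes=10)
        net = net_from_edges(edges)
        assert modularity_louvain(net, seed=3) == modularity_louvain(net,
                                                                     seed=3)

    def test_louvain_bounded_by_exhaustive(self):
        rng = random.Random(99)
        for _ in range(10):
            edges = random_digraph(rng, max_nodes=6)
            net = net_from_edges(edges)
            if not net.edges:
                continue
            q, _ = modularity_louvain(net, seed=0)
            und = {}
            for (o, h), w in edges.items():
                key = tuple(sorted((o, h)))
                und[key] = und.get(key, 0) + w
            best = oracles.max_modularity_exhaustive(und, sorted(net.nodes))
            assert q >= -1e-12  # never worse than the trivial partition
            assert q <= best + 1e-9

    def test_collapse_sums_antiparallel_weights(self):
        net = net_from_edges({("A", "B"): 3, ("B", "A"): 4})
        g = collapse_undirected(net)
        assert g["A"]["B"]["weight"] == 7

    def test_empty_net_raises(self):
        with pytest.raises(ValueError):
            modularity_louvain(net_from_edges({}), seed=0)


class TestStrengths:
    def test_pure_importer_and_exporter(self):
        net = net_from_edges({("KEN", "USA"): 10})
        stats = {s.country: s for s in node_strengths(net)}
        assert stats["USA"].net_balance == 1.0
        assert stats["KEN"].net_balance == -1.0

    def test_mixed_balance(self):
        net = net_from_edges({("A", "B"): 6, ("B", "C"): 2})
        s = {x.country: x for x in node_strengths(net)}
        assert s["B"].in_strength == 6 and s["B"].out_strength == 2
        assert s["B"].net_balance == pytest.approx(0.5)

    def test_conservation(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        stats = node_strengths(net)
        total = net.total_weight()
        assert sum(s.in_strength for s in stats) == total
        assert sum(s.out_strength for s in stats) == total
        assert sum(s.net for s in stats) == 0

    def test_domestic_only_country_reported(self):
        net = net_from_edges({("A", "B"): 1}, domestic={"Z": 7})
        s = {x.country: x for x in node_strengths(net)}
        assert s["Z"].domestic == 7
        assert s["Z"].net_balance is None

    def test_net_balance_antisymmetry(self):
        rng = random.Random(77)
        edges = random_digraph(rng)
        fwd = {s.country: s.net_balance
               for s in node_strengths(net_from_edges(edges))}
        rev_edges = {(h, o): w for (o, h), w in edges.items()}
        rev = {s.country: s.net_balance
               for s in node_strengths(net_from_edges(rev_edges))}
        for c, nb in fwd.items():
            if nb is None:
                assert rev[c] is None
            else:
                assert rev[c] == pytest.approx(-nb)


class TestTopEdgesAndThreshold:
    def test_fewer_than_k_returns_all(self):
        net = net_from_edges({("A", "B"): 1, ("B", "C"): 2, ("C", "A"): 3})
        assert len(top_k_edges(net, 200)) == 3

    def test_tie_break_by_code(self):
        net = net_from_edges({("B", "C"): 5, ("A", "B"): 5, ("C", "A"): 1})
        assert top_k_edges(net, 2) == [("A", "B", 5), ("B", "C", 5)]

    def test_k1_max_weight(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        assert top_k_edges(net, 1) == [("BRA", "NOR", 7)]

    def test_threshold_one_is_identity(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        out = apply_weight_threshold(net, 1)
        assert out.edges == net.edges

    def test_threshold_removes_all(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        out = apply_weight_threshold(net, 10**9)
        assert out.edges == {} and network_size(out) == 0

    def test_fixture_at_threshold_five(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        out = apply_weight_threshold(net, 5)
        assert out.edges == {("USA", "KEN"): 6, ("BRA", "NOR"): 7}
        assert out.nodes == {"USA", "KEN", "BRA", "NOR"}

    @given(st.integers(min_value=1, max_value=25))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotone(self, w):
        rng = random.Random(4)
        edges = random_digraph(rng)
        net = net_from_edges(edges)
        a = apply_weight_threshold(net, w)
        b = apply_weight_threshold(net, w + 1)
        assert network_size(b) <= network_size(a)
        assert network_complexity(b) <= network_complexity(a)


class TestMetricsBySlice:
    def test_twelve_slices(self, six_record_slice, make_record):
        records = []
        for fam in ("Canidae", "Felidae", "Mustelidae"):
            for year in (1910, 1940, 1970, 2000):
                records.append(make_record("KEN", "USA", 1, family=fam,
                                           year=year))
        tab = metrics_by_slice(records)
        assert len(tab) == 12
        assert set(tab["family"]) == {"Canidae", "Felidae", "Mustelidae"}

    def test_compute_metrics_bundle(self, six_record_slice):
        net = build_flow_network(six_record_slice)
        m = compute_metrics(net, seed=0)
        assert m.nodes == 4 and m.edges == 4
        assert m.edges_to_nodes == pytest.approx(1.0)
        assert 0 <= m.density <= 1
        assert m.modularity is not None
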