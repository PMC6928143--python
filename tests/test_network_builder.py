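"""Greedy subnetwork construction, scoring, hubs, and coverage arithmetic."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from momnet.knowledge_base import InteractionGraph, KnowledgeBase, PathwayDefinition
from momnet.network_builder import (
    MolecularNetwork,
    build_networks,
    coverage_percent,
    extract_hubs,
    score_network,
)


def graph_from_edges(edges, extra_nodes=()):
    graph = InteractionGraph()
    for node in extra_nodes:
        graph.add_node(node)
    for a, b in edges:
        graph.add_edge(a, b)
    return graph


def greedy_reference(eligible, graph, max_size):
    """Independent re-implementation of the stated seed-and-extend rule."""
    eligible = {e for e in eligible if e in graph}
    assigned, networks = set(), []
    while eligible - assigned:
        seed = sorted(
            eligible - assigned, key=lambda n: (-graph.degree(n), n)
        )[0]
        members = {seed}
        assigned.add(seed)
        while len(members) < max_size:
            candidates = set()
            for m in members:
                candidates |= graph.neighbors(m)
            candidates -= members
            candidates -= {c for c in candidates if c in eligible and c in assigned}
            if not candidates:
                break

            def gain(c):
                reach = graph.neighbors(c) | {c}
                return len(
                    (reach & eligible) - assigned - members
                )

            best = sorted(
                candidates, key=lambda c: (-gain(c), -graph.degree(c), c)
            )[0]
            members.add(best)
            if best in eligible:
                assigned.add(best)
        networks.append(frozenset(members))
    return networks


class TestBuildNetworks:
    def test_clique_of_eligible_lands_in_one_network(self):
        nodes = ["A", "B", "C", "D", "E"]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        graph = graph_from_edges(edges)
        networks = build_networks(set(nodes), graph)
        assert len(networks) == 1
        assert set(nodes) <= networks[0].nodes

    def test_disconnected_components_never_span(self):
        graph = graph_from_edges([("A", "B"), ("C", "D")])
        networks = build_networks({"A", "C"}, graph)
        assert len(networks) == 2
        for network in networks:
            assert not ({"A", "B"} & network.nodes and {"C", "D"} & network.nodes)

    def test_matches_independent_greedy_on_toy_graph(self):
        edges = [
            ("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"),
            ("E", "F"), ("F", "G"), ("G", "H"), ("H", "I"), ("I", "J"),
            ("J", "K"), ("K", "L"), ("B", "H"), ("D", "J"), ("C", "K"),
        ]
        graph = graph_from_edges(edges)
        eligible = {"A", "E", "I", "L"}
        for max_size in (4, 6, 35):
            ours = [n.nodes for n in build_networks(eligible, graph, max_size)]
            assert ours == greedy_reference(eligible, graph, max_size)

    def test_eligible_nodes_partitioned_and_size_capped(self, default_bundle):
        _, kb, truth = default_bundle
        eligible = {f"GENE{i:04d}" for i in range(1, 120)} | set(truth.planted_hubs)
        networks = build_networks(eligible, kb.graph, max_size=20)
        seen = set()
        for network in networks:
            assert len(network.nodes) <= 20
            assert network.eligible_nodes <= network.nodes
            assert not (network.eligible_nodes & seen)
            seen |= network.eligible_nodes

    def test_deterministic_across_runs(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("B", "D")]
        graph = graph_from_edges(edges)
        first = build_networks({"A", "C"}, graph)
        second = build_networks({"A", "C"}, graph)
        assert first == second

    def test_eligible_absent_from_graph_gives_empty(self):
        graph = graph_from_edges([("A", "B")])
        assert build_networks({"Z"}, graph) == []

    def test_max_size_domain(self):
        with pytest.raises(ValueError):
            build_networks({"A"}, graph_from_edges([("A", "B")]), max_size=1)


def kb_of_n(n):
    graph = InteractionGraph()
    ids = [f"G{i:02d}" for i in range(n)]
    for ident in ids:
        graph.add_node(ident)
    return KnowledgeBase(
        graph=graph,
        pathways=(PathwayDefinition(name="P", members=frozenset(ids)),),
        universe=frozenset(ids),
    )


class TestScoreNetwork:
    def test_no_eligible_scores_zero(self):
        kb = kb_of_n(10)
        network = MolecularNetwork(
            network_id=1, nodes=frozenset({"G00", "G01"}), eligible_nodes=frozenset()
        )
        assert score_network(network, set(), kb) == 0.0

    def test_full_overlap_five_of_ten(self):
        kb = kb_of_n(10)
        members = frozenset({"G00", "G01", "G02", "G03", "G04"})
        network = MolecularNetwork(network_id=1, nodes=members, eligible_nodes=members)
        score = score_network(network, set(members), kb)
        assert score == pytest.approx(-math.log10(1 / 252), rel=1e-9)

    def test_always_non_negative(self):
        kb = kb_of_n(12)
        network = MolecularNetwork(
            network_id=1,
            nodes=frozenset({"G00", "G01", "G02"}),
            eligible_nodes=frozenset({"G00"}),
        )
        assert score_network(network, {"G00", "G05"}, kb) >= 0.0


class TestExtractHubs:
    def test_star_center_is_the_only_hub(self):
        edges = [("HUB", leaf) for leaf in ("A", "B", "C", "D", "E")]
        graph = graph_from_edges(edges)
        nodes = frozenset({"HUB", "A", "B", "C", "D", "E"})
        network = MolecularNetwork(network_id=1, nodes=nodes, eligible_nodes=frozenset())
        hubs = extract_hubs(network, graph)
        assert [(h.identifier, h.degree) for h in hubs] == [("HUB", 5)]

    def test_cycle_has_no_hubs(self):
        nodes = ["A", "B", "C", "D", "E", "F"]
        edges = list(zip(nodes, nodes[1:] + nodes[:1]))
        graph = graph_from_edges(edges)
        network = MolecularNetwork(
            network_id=1, nodes=frozenset(nodes), eligible_nodes=frozenset()
        )
        assert extract_hubs(network, graph) == []

    def test_degree_counted_within_network_only(self):
        # node X has 5 neighbours in the graph but only 4 inside the network
        edges = [("X", n) for n in ("A", "B", "C", "D", "E")]
        graph = graph_from_edges(edges)
        network = MolecularNetwork(
            network_id=1,
            nodes=frozenset({"X", "A", "B", "C", "D"}),
            eligible_nodes=frozenset(),
        )
        assert extract_hubs(network, graph) == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 24), st.integers(0, 24)).filter(
                lambda e: e[0] != e[1]
            ),
            max_size=120,
        ),
        st.integers(1, 8),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_degree_filter(self, raw_edges, min_links):
        graph = InteractionGraph()
        for i in range(25):
            graph.add_node(f"N{i:02d}")
        for a, b in raw_edges:
            graph.add_edge(f"N{a:02d}", f"N{b:02d}")
        nodes = frozenset(f"N{i:02d}" for i in range(0, 25, 2))
        network = MolecularNetwork(
            network_id=1, nodes=nodes, eligible_nodes=frozenset()
        )
        hubs = extract_hubs(network, graph, min_links=min_links)
        edges = [(a, b) for a, b, _ in graph.edges()]
        brute = {
            n: sum(1 for a, b in edges if n in (a, b) and (a in nodes and b in nodes))
            for n in nodes
        }
        expected = {n for n, d in brute.items() if d >= min_links}
        assert {h.identifier for h in hubs} == expected
        for hub in hubs:
            assert hub.degree == brute[hub.identifier]

    def test_min_links_domain(self):
        graph = graph_from_edges([("A", "B")])
        network = MolecularNetwork(
            network_id=1, nodes=frozenset({"A", "B"}), eligible_nodes=frozenset()
        )
        with pytest.raises(ValueError):
            extract_hubs(network, graph, min_links=0)


class TestCoveragePercent:
    @pytest.mark.parametrize(
        "n_eligible,n_nodes,expected",
        [(23, 35, 66), (18, 35, 51), (0, 35, 0), (35, 35, 100), (1, 8, 13)],
    )
    def test_rounds_half_away_from_zero(self, n_eligible, n_nodes, expected):
        nodes = frozenset(f"N{i}" for i in range(n_nodes))
        eligible = frozenset(f"N{i}" for i in range(n_eligible))
        network = MolecularNetwork(network_id=1, nodes=nodes, eligible_nodes=eligible)
        assert coverage_percent(network) == expected
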