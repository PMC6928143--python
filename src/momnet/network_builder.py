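"""Scored molecular subnetworks and hub-molecule extraction.

The commercial platform the study used assembles each dataset's
network-eligible molecules, together with knowledge-base filler
molecules, into connected subnetworks of bounded size (35 nodes) and
scores each one by -log10 of the right-tail probability of its
eligible-molecule overlap.  Its algorithm is undisclosed, so this module
implements a documented, deterministic seed-and-extend greedy with the
same observable properties: a size cap, mixed eligible/filler membership,
connectivity, a -log10 p score, and sparse hub structure.

A hub-molecule is a node adjacent (via direct- or indirect-relationship
edges, i.e. within the induced subgraph, not by reachability) to at
least five other nodes of its network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from .enrichment import hypergeometric_tail
from .knowledge_base import InteractionGraph, KnowledgeBase

__all__ = [
    "MolecularNetwork",
    "HubMolecule",
    "build_networks",
    "score_network",
    "extract_hubs",
    "coverage_percent",
    "MAX_NETWORK_SIZE",
    "MIN_HUB_LINKS",
]

MAX_NETWORK_SIZE = 35
MIN_HUB_LINKS = 5


@dataclass(frozen=True)
class MolecularNetwork:
    """A connected scored subnetwork built around eligible molecules."""

    network_id: int
    nodes: frozenset[str]
    eligible_nodes: frozenset[str]
    score: float = 0.0
    function_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.eligible_nodes <= self.nodes:
            raise ValueError("eligible_nodes must be a subset of nodes")
        if self.score < 0:
            raise ValueError("network score must be non-negative")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class HubMolecule:
    """A node with at least ``min_links`` neighbours inside its network."""

    identifier: str
    network_id: int
    degree: int
    dataset_serial: int = 0


def build_networks(
    eligible: Iterable[str],
    graph: InteractionGraph,
    max_size: int = MAX_NETWORK_SIZE,
) -> list[MolecularNetwork]:
    """Deterministic seed-and-extend construction of molecular networks.

    Repeatedly seed with the not-yet-assigned eligible node of highest
    full-graph degree (lexicographic tie-break), then greedily add the
    neighbouring candidate that maximizes (number of new eligible
    connections, full-graph degree, lexicographically-smallest name)
    until the network reaches ``max_size`` or no connected candidate
    remains.  Each eligible node is assigned to at most one network;
    non-eligible filler nodes may recur across networks.  Scores are not
    set here (see :func:`score_network`).
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    eligible_in_graph = {e for e in eligible if e in graph}
    if not eligible_in_graph:
        return []

    assigned: set[str] = set()
    networks: list[MolecularNetwork] = []

    def new_eligible_connections(candidate: str, members: set[str]) -> int:
        """Unassigned eligible nodes the candidate would newly bring in reach."""
        reach = graph.neighbors(candidate) | {candidate}
        return sum(
            1
            for node in reach
            if node in eligible_in_graph and node not in assigned and node not in members
        )

    while True:
        seeds = eligible_in_graph - assigned
        if not seeds:
            break
        seed = min(seeds, key=lambda n: (-graph.degree(n), n))
        members: set[str] = {seed}
        assigned.add(seed)
        frontier: set[str] = set(graph.neighbors(seed))
        while len(members) < max_size:
            candidates = {
                c
                for c in frontier
                if c not in members and not (c in eligible_in_graph and c in assigned)
            }
            if not candidates:
                break
            best = min(
                candidates,
                key=lambda c: (
                    -new_eligible_connections(c, members),
                    -graph.degree(c),
                    c,
                ),
            )
            members.add(best)
            frontier |= graph.neighbors(best)
            if best in eligible_in_graph:
                assigned.add(best)
        networks.append(
            MolecularNetwork(
                network_id=len(networks) + 1,
                nodes=frozenset(members),
                eligible_nodes=frozenset(members & eligible_in_graph),
            )
        )
    return networks


def score_network(
    network: MolecularNetwork,
    eligible: Iterable[str],
    kb: KnowledgeBase,
) -> float:
    """Network score: -log10 of the right-tail overlap probability.

    The overlap model draws K = |network nodes| from the N-molecule KB
    universe and asks how improbable it is to hit k = |eligible nodes in
    the network| of the dataset's n eligible molecules by chance.  A
    probability of 1 scores 0.
    """
    eligible = set(eligible)
    N = len(kb.universe)
    n = len(eligible & kb.universe)
    K = len(network.nodes)
    k = len(eligible & network.nodes)
    p = hypergeometric_tail(k, K, n, N)
    return -math.log10(p) if p < 1.0 else 0.0


def attach_score(
    network: MolecularNetwork, eligible: Iterable[str], kb: KnowledgeBase
) -> MolecularNetwork:
    """Return a copy of ``network`` with its score filled in."""
    return replace(network, score=score_network(network, eligible, kb))


def extract_hubs(
    network: MolecularNetwork,
    graph: InteractionGraph,
    min_links: int = MIN_HUB_LINKS,
    dataset_serial: int = 0,
) -> list[HubMolecule]:
    """Nodes adjacent to at least ``min_links`` other nodes of the network.

    Degree is counted within the subgraph induced by the network's nodes,
    counting direct- and indirect-relationship edges alike.  Hubs are
    sorted by degree descending, ties by name.
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    missing = network.nodes - graph.nodes
    if missing:
        raise KeyError(f"network nodes absent from graph: {sorted(missing)[:3]}")
    hubs = [
        HubMolecule(
            identifier=node,
            network_id=network.network_id,
            degree=graph.subgraph_degree(node, network.nodes),
            dataset_serial=dataset_serial,
        )
        for node in network.nodes
        if graph.subgraph_degree(node, network.nodes) >= min_links
    ]
    hubs.sort(key=lambda h: (-h.degree, h.identifier))
    return hubs


def coverage_percent(network: MolecularNetwork) -> int:
    """Integer percent of network nodes that are dataset molecules.

    Rounds half away from zero, reproducing the conventional reporting of
    e.g. 23/35 as 66% and 18/35 as 51%.
    """
    if not network.nodes:
        raise ValueError("coverage undefined for an empty network")
    return int(math.floor(100 * len(network.eligible_nodes) / len(network.nodes) + 0.5))
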