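"""Knowledge base: interaction graph + pathway gene sets.

Stands in for the proprietary curated knowledge base a commercial pathway
platform queries.  The graph is an undirected molecular-interaction
network whose edges are labelled ``direct`` or ``indirect``; pathways are
named gene sets (GMT) optionally tagged as cancer-related and/or assigned
to a named panel.  The ``universe`` is the identifier background used for
over-representation statistics: by default the union of all pathway
annotations, the stated comparison background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

from .omics_io import FormatError, ValidationError

__all__ = [
    "InteractionGraph",
    "PathwayDefinition",
    "KnowledgeBase",
    "load_gene_sets",
    "load_interactions",
    "write_gene_sets",
    "write_interactions",
]

log = logging.getLogger(__name__)

RELATION_TYPES = ("direct", "indirect")


class InteractionGraph:
    """Undirected interaction network with direct/indirect edge labels.

    Thin domain wrapper over :class:`networkx.Graph`; both relation types
    contribute equally to adjacency and degree.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, identifier: str, node_class: str = "other") -> None:
        self._g.add_node(identifier, node_class=node_class)

    def add_edge(self, a: str, b: str, relation: str = "direct") -> None:
        if relation not in RELATION_TYPES:
            raise FormatError(f"unknown relation type {relation!r}")
        if a == b:
            log.warning("dropping self-loop on %s", a)
            return
        if self._g.has_edge(a, b):
            # conflicting labels collapse to 'direct'
            if relation == "direct":
                self._g.edges[a, b]["relation"] = "direct"
            return
        for n in (a, b):
            if n not in self._g:
                self.add_node(n)
        self._g.add_edge(a, b, relation=relation)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._g

    def edges(self) -> list[tuple[str, str, str]]:
        return [(a, b, d["relation"]) for a, b, d in self._g.edges(data=True)]

    def node_class(self, identifier: str) -> str:
        return self._g.nodes[identifier].get("node_class", "other")

    def neighbors(self, node: str) -> set[str]:
        """Adjacent nodes, regardless of relation type."""
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        return set(self._g.neighbors(node))

    def degree(self, node: str) -> int:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        return self._g.degree[node]

    def subgraph_degree(self, node: str, members: Iterable[str]) -> int:
        """Degree of ``node`` within the subgraph induced by ``members``."""
        members = set(members)
        return sum(1 for n in self.neighbors(node) if n in members)

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()


def neighbors(graph: InteractionGraph, node: str) -> set[str]:
    """Module-level alias for :meth:`InteractionGraph.neighbors`."""
    return graph.neighbors(node)


@dataclass(frozen=True)
class PathwayDefinition:
    """A named canonical-pathway gene set with optional annotations."""

    name: str
    members: frozenset[str]
    cancer_related: bool = False
    panel_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("pathway name must be non-empty")
        if not self.members:
            raise ValidationError(f"pathway {self.name!r} has no members")


@dataclass(frozen=True)
class KnowledgeBase:
    """Interaction graph, pathway collection, and statistical universe."""

    graph: InteractionGraph
    pathways: tuple[PathwayDefinition, ...]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        names = [p.name for p in self.pathways]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate pathway names in knowledge base")
        union = frozenset().union(*(p.members for p in self.pathways)) if self.pathways else frozenset()
        universe = self.universe or (union | self.graph.nodes)
        if not union <= universe or not self.graph.nodes <= universe:
            raise ValidationError("universe must cover pathway members and graph nodes")
        object.__setattr__(self, "universe", frozenset(universe))

    def is_empty(self) -> bool:
        return not self.graph.nodes and not self.pathways

    def known_identifiers(self) -> frozenset[str]:
        """Identifiers the KB can map: graph nodes plus pathway members."""
        members = (
            frozenset().union(*(p.members for p in self.pathways))
            if self.pathways
            else frozenset()
        )
        return frozenset(self.graph.nodes) | members

    def pathway(self, name: str) -> PathwayDefinition:
        for p in self.pathways:
            if p.name == name:
                return p
        raise KeyError(name)

    def pathway_labels(self) -> dict[str, tuple[bool, Optional[str]]]:
        return {p.name: (p.cancer_related, p.panel_label) for p in self.pathways}


# ---------------------------------------------------------------------------
# readers / writers


def _parse_gmt_description(desc: str) -> tuple[bool, Optional[str]]:
    """Parse ``cancer_related=1;panel=<label>`` tags from a GMT description."""
    cancer = False
    panel: Optional[str] = None
    for token in desc.split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" in token:
            key, _, value = token.partition("=")
            key, value = key.strip(), value.strip()
            if key == "cancer_related":
                cancer = value in ("1", "true", "True", "yes")
            elif key == "panel":
                panel = value or None
    return cancer, panel


def load_gene_sets(path: str | Path) -> tuple[PathwayDefinition, ...]:
    """Read pathway gene sets from a GMT file.

    Each line: ``name <TAB> description <TAB> member [<TAB> member ...]``.
    The description field may carry ``cancer_related=1;panel=<label>`` tags.
    """
    pathways: list[PathwayDefinition] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no members")
            cancer, panel = _parse_gmt_description(desc)
            pathways.append(
                PathwayDefinition(
                    name=name, members=members, cancer_related=cancer, panel_label=panel
                )
            )
    return tuple(pathways)


def load_interactions(path: str | Path) -> InteractionGraph:
    """Read an interaction graph from a SIF-style TSV.

    Each line: ``source <TAB> relation <TAB> target`` with relation in
    {direct, indirect}.  Duplicate and reversed-duplicate edges collapse;
    conflicting relation labels resolve to ``direct``; self-loops are
    dropped with a warning.  The result is independent of line order.
    """
    graph = InteractionGraph()
    pending: dict[frozenset[str], str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'source<TAB>relation<TAB>target'"
                )
            a, relation, b = (f.strip() for f in fields)
            a, b = a.upper(), b.upper()
            if relation not in RELATION_TYPES:
                raise FormatError(
                    f"{path}: line {lineno}: unknown relation {relation!r}"
                )
            if a == b:
                log.warning("%s: line %d: dropping self-loop on %s", path, lineno, a)
                continue
            key = frozenset((a, b))
            if key in pending:
                if relation == "direct":
                    pending[key] = "direct"
            else:
                pending[key] = relation
    for key in sorted(pending, key=sorted):
        a, b = sorted(key)
        graph.add_edge(a, b, pending[key])
    return graph


def write_gene_sets(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for p in pathways:
            tags = []
            if p.cancer_related:
                tags.append("cancer_related=1")
            if p.panel_label:
                tags.append(f"panel={p.panel_label}")
            desc = ";".join(tags) or "na"
            handle.write("\t".join([p.name, desc, *sorted(p.members)]) + "\n")


def write_interactions(graph: InteractionGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b, relation in sorted(graph.edges()):
            handle.write(f"{a}\t{relation}\t{b}\n")
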