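"""Signed directed regulatory networks.

A :class:`SignedNetwork` is a directed graph whose edges carry a regulatory
sign (+1 activation, -1 inhibition, 0 unidentified) and whose nodes carry a
layer-relevant *kind* (receptor / regulatory / marker / phenotype) and a
molecular *species* (protein / miRNA / complex / other). It wraps a
:class:`networkx.DiGraph`, which callers may access directly for standard
graph algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import networkx as nx

VALID_SIGNS = (1, -1, 0)


class NodeKind(str, Enum):
    RECEPTOR = "receptor"
    REGULATORY = "regulatory"
    MARKER = "marker"
    PHENOTYPE = "phenotype"


class Species(str, Enum):
    PROTEIN = "protein"
    MIRNA = "miRNA"
    COMPLEX = "complex"
    OTHER = "other"


class NetworkError(ValueError):
    """Raised on structurally invalid networks or edges."""


@dataclass
class SignedNetwork:
    """Directed graph with signed edges and typed nodes.

    The underlying :class:`networkx.DiGraph` stores the sign on the ``sign``
    edge attribute and ``kind`` / ``species`` node attributes.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        kinds: dict[str, NodeKind] | None = None,
        species: dict[str, Species] | None = None,
    ) -> "SignedNetwork":
        net = cls()
        for s, t, sign in edges:
            net.add_edge(s, t, sign)
        for node, kind in (kinds or {}).items():
            net.set_kind(node, kind)
        for node, sp in (species or {}).items():
            net.set_species(node, sp)
        return net

    def add_node(
        self,
        node: str,
        kind: NodeKind = NodeKind.REGULATORY,
        species: Species = Species.PROTEIN,
    ) -> None:
        if not node or not isinstance(node, str):
            raise NetworkError(f"node id must be a non-empty string, got {node!r}")
        if node not in self.graph:
            self.graph.add_node(node, kind=NodeKind(kind), species=Species(species))

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in VALID_SIGNS:
            raise NetworkError(f"edge sign must be one of {VALID_SIGNS}, got {sign!r}")
        self.add_node(source)
        self.add_node(target)
        if self.graph.has_edge(source, target):
            raise NetworkError(f"duplicate edge {source} -> {target}")
        self.graph.add_edge(source, target, sign=int(sign))

    # -- accessors --------------------------------------------------------

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for s, t, data in self.graph.edges(data=True):
            yield s, t, data["sign"]

    def sign(self, source: str, target: str) -> int:
        return self.graph.edges[source, target]["sign"]

    def has_edge(self, source: str, target: str) -> bool:
        return self.graph.has_edge(source, target)

    def kind(self, node: str) -> NodeKind:
        return self.graph.nodes[node]["kind"]

    def species(self, node: str) -> Species:
        return self.graph.nodes[node]["species"]

    def set_kind(self, node: str, kind: NodeKind) -> None:
        self.add_node(node)
        self.graph.nodes[node]["kind"] = NodeKind(kind)

    def set_species(self, node: str, sp: Species) -> None:
        self.add_node(node)
        self.graph.nodes[node]["species"] = Species(sp)

    def in_edges(self, node: str) -> list[tuple[str, int]]:
        """Regulators of *node* as (source, sign) pairs, sorted by source."""
        return sorted(
            (s, data["sign"]) for s, _, data in self.graph.in_edges(node, data=True)
        )

    def neighbors_undirected(self, node: str) -> set[str]:
        """First neighbors in either direction."""
        return set(self.graph.successors(node)) | set(self.graph.predecessors(node))

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.graph.copy())

    # -- comparisons ------------------------------------------------------

    def structurally_equal(self, other: "SignedNetwork") -> bool:
        """Same node set and same signed edge set (kinds/species ignored)."""
        return set(self.graph.nodes) == set(other.graph.nodes) and set(
            self.edges()
        ) == set(other.edges())

    def is_signed_subgraph_of(self, other: "SignedNetwork") -> bool:
        """Every node exists in *other* and every edge exists with equal sign."""
        if not set(self.graph.nodes) <= set(other.graph.nodes):
            return False
        return all(
            other.has_edge(s, t) and other.sign(s, t) == sign
            for s, t, sign in self.edges()
        )
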