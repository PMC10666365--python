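"""Three-node feedback-loop enumeration and topological node properties.

A feedback motif here is a simple directed 3-cycle. Its loop sign is the
product of its nonzero edge signs (positive/negative feedback); any
"unidentified" sign-0 edge makes the loop sign undetermined. Motifs are kept
in a canonical rotation starting at the lexicographically smallest node so
that equality and ordering are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .network import SignedNetwork


@dataclass(frozen=True)
class FeedbackMotif:
    """A simple directed 3-cycle with signed edges, in canonical rotation."""

    nodes: tuple[str, str, str]
    edges: tuple[tuple[str, str, int], ...]
    loop_sign: str  # positive | negative | undetermined

    @classmethod
    def from_cycle(cls, cycle: tuple[str, str, str], net: SignedNetwork) -> "FeedbackMotif":
        """Canonicalize a node cycle (a -> b -> c -> a) against *net*'s signs."""
        start = min(range(3), key=lambda i: cycle[i])
        nodes = tuple(cycle[(start + i) % 3] for i in range(3))
        edges = tuple(
            (nodes[i], nodes[(i + 1) % 3], net.sign(nodes[i], nodes[(i + 1) % 3]))
            for i in range(3)
        )
        signs = [sign for _, _, sign in edges]
        if 0 in signs:
            loop_sign = "undetermined"
        else:
            loop_sign = "positive" if signs[0] * signs[1] * signs[2] > 0 else "negative"
        return cls(nodes=nodes, edges=edges, loop_sign=loop_sign)  # type: ignore[arg-type]

    @property
    def motif_id(self) -> str:
        """Stable string identifier, e.g. ``A>B>C``."""
        return ">".join(self.nodes)


def enumerate_feedback_loops(
    net: SignedNetwork, exclude_neutral: bool = False
) -> list[FeedbackMotif]:
    """All distinct simple directed 3-cycles, sorted by canonical form.

    Self-loops and 2-cycles never qualify. With ``exclude_neutral`` the
    enumeration runs on the subgraph without sign-0 edges, mirroring an
    analysis that drops "unidentified" interactions.
    """
    graph = net.graph
    if exclude_neutral:
        graph = nx.DiGraph(
            (s, t) for s, t, data in graph.edges(data=True) if data["sign"] != 0
        )
    motifs = {
        FeedbackMotif.from_cycle(tuple(cycle), net)
        for cycle in nx.simple_cycles(graph, length_bound=3)
        if len(cycle) == 3
    }
    return sorted(motifs, key=lambda m: m.nodes)


@dataclass(frozen=True)
class TopologyReport:
    """Node degree (in + out, signs ignored) and normalized betweenness."""

    degree: dict[str, int]
    betweenness: dict[str, float]


def compute_topology(net: SignedNetwork) -> TopologyReport:
    """Degree and directed shortest-path betweenness for every node.

    Betweenness is normalized by (n-1)(n-2) so it lies in [0, 1]; edge signs
    are ignored for both properties.
    """
    graph = net.graph
    degree = {node: deg for node, deg in graph.degree()}
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    return TopologyReport(degree=degree, betweenness=betweenness)
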