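"""Core regulatory network assembly.

Top-ranked feedback motifs are merged (node/edge union), then expanded with
receptor proteins (first neighbors of motif nodes, forming the input layer)
and with the four EMT marker proteins together with every direct connection
to the core. The result is a three-layer core: input (receptors), regulatory
(motif constituents), and output markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .logic import DEFAULT_MARKERS
from .motifs import FeedbackMotif
from .network import NodeKind, SignedNetwork


class Layer(str, Enum):
    INPUT = "input"
    REGULATORY = "regulatory"
    OUTPUT_MARKER = "output-marker"


class AssemblyError(ValueError):
    """Raised when receptor/marker expansion references unknown nodes."""


@dataclass
class CoreNetwork:
    """A layered signed core: the network plus the layer partition."""

    net: SignedNetwork
    layers: dict[str, Layer]
    receptors: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)

    def nodes_in_layer(self, layer: Layer) -> list[str]:
        return sorted(n for n, l in self.layers.items() if l is layer)

    def regulatory_nodes(self) -> list[str]:
        return self.nodes_in_layer(Layer.REGULATORY)


def merge_motifs(selected: Sequence[FeedbackMotif]) -> SignedNetwork:
    """Union of motif nodes and signed motif edges."""
    if not selected:
        raise AssemblyError("cannot merge an empty motif selection")
    merged = SignedNetwork()
    for motif in selected:
        for node in motif.nodes:
            merged.add_node(node)
        for s, t, sign in motif.edges:
            if not merged.has_edge(s, t):
                merged.add_edge(s, t, sign)
    return merged


def expand_with_receptors(
    core: SignedNetwork, full: SignedNetwork, receptors: Sequence[str]
) -> SignedNetwork:
    """Add listed receptors that are first neighbors of core nodes.

    Connecting edges (either direction) are copied from the full network;
    receptors with no adjacency to the core are skipped with a warning.
    """
    expanded = core.copy()
    core_nodes = set(core.graph.nodes)
    for receptor in receptors:
        if receptor not in full:
            raise AssemblyError(f"receptor {receptor!r} absent from full network")
        touching = full.neighbors_undirected(receptor) & core_nodes
        if not touching:
            warnings.warn(
                f"receptor {receptor} has no direct connection to the core; skipped",
                stacklevel=2,
            )
            continue
        expanded.add_node(receptor, kind=NodeKind.RECEPTOR)
        expanded.set_kind(receptor, NodeKind.RECEPTOR)
        for node in sorted(touching):
            if full.has_edge(receptor, node) and not expanded.has_edge(receptor, node):
                expanded.add_edge(receptor, node, full.sign(receptor, node))
            if full.has_edge(node, receptor) and not expanded.has_edge(node, receptor):
                expanded.add_edge(node, receptor, full.sign(node, receptor))
    return expanded


def expand_with_markers(
    core: SignedNetwork,
    full: SignedNetwork,
    markers: Sequence[str] = DEFAULT_MARKERS,
    receptors: Sequence[str] = (),
) -> CoreNetwork:
    """Add the EMT markers plus all their direct edges to/from the core.

    Markers are mandatory output nodes: one with no core adjacency is still
    added (isolated, with a warning). Marker-to-marker edges present in the
    full network are copied too. Layers are then assigned: listed receptors
    -> input, markers -> output-marker, everything else -> regulatory.
    """
    expanded = core.copy()
    for marker in markers:
        if marker not in full:
            raise AssemblyError(f"marker {marker!r} absent from full network")
        expanded.add_node(marker, kind=NodeKind.MARKER)
        expanded.set_kind(marker, NodeKind.MARKER)
    target_nodes = set(expanded.graph.nodes)
    attached = set()
    for marker in markers:
        for node in sorted(full.neighbors_undirected(marker) & target_nodes):
            if full.has_edge(marker, node) and not expanded.has_edge(marker, node):
                expanded.add_edge(marker, node, full.sign(marker, node))
                attached.add(marker)
            if full.has_edge(node, marker) and not expanded.has_edge(node, marker):
                expanded.add_edge(node, marker, full.sign(node, marker))
                attached.add(marker)
        # edges already copied into the core also count as attachment
        if expanded.neighbors_undirected(marker):
            attached.add(marker)
    for marker in markers:
        if marker not in attached:
            warnings.warn(
                f"marker {marker} has no direct connection to the core; "
                f"added as isolated output node",
                stacklevel=2,
            )

    layers: dict[str, Layer] = {}
    receptor_set = set(receptors)
    for node in expanded.graph.nodes:
        if node in receptor_set:
            layers[node] = Layer.INPUT
            expanded.set_kind(node, NodeKind.RECEPTOR)
        elif node in markers:
            layers[node] = Layer.OUTPUT_MARKER
        else:
            layers[node] = Layer.REGULATORY
    # carry species annotations over from the full network where present
    for node in expanded.graph.nodes:
        if node in full:
            expanded.set_species(node, full.species(node))
    return CoreNetwork(
        net=expanded,
        layers=layers,
        receptors=sorted(receptor_set & set(expanded.graph.nodes)),
        markers=list(markers),
    )


def assemble_core(
    selected: Sequence[FeedbackMotif],
    full: SignedNetwork,
    receptors: Sequence[str],
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> CoreNetwork:
    """merge -> receptor expansion -> marker expansion, in one call."""
    merged = merge_motifs(selected)
    with_receptors = expand_with_receptors(merged, full, receptors)
    return expand_with_markers(with_receptors, full, markers, receptors)
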