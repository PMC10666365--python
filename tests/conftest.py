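"""Shared fixtures: the worked 4-node toy, the bundled melanoma-style core,
and generators for random models used by the brute-force oracles."""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np
import pytest

from melanocore import (
    CoreNetwork,
    FoldChangeProfile,
    Layer,
    SignedNetwork,
    infer_gates,
    melanoma_fixture,
)
from melanocore.logic import FREE, BooleanModel, Gate, GateKind, Polarity


@pytest.fixture(scope="session")
def fig2_network() -> SignedNetwork:
    """The worked 4-node toy: X1 -> X2 -| X4, X2/X4 -> X3, X3 -> X4."""
    return SignedNetwork.from_edges(
        [
            ("X1", "X2", 1),
            ("X4", "X2", -1),
            ("X2", "X3", 1),
            ("X4", "X3", 1),
            ("X3", "X4", 1),
        ]
    )


@pytest.fixture(scope="session")
def fig2_fc() -> FoldChangeProfile:
    """Fold-change signs (+, -, +, +) for X1..X4."""
    return FoldChangeProfile({"X1": 1.0, "X2": -0.7, "X3": 0.5, "X4": 0.9})


@pytest.fixture(scope="session")
def fig2_core(fig2_network) -> CoreNetwork:
    return CoreNetwork(
        net=fig2_network,
        layers={n: Layer.REGULATORY for n in fig2_network.graph.nodes},
        receptors=[],
        markers=[],
    )


@pytest.fixture(scope="session")
def fig2_model(fig2_core, fig2_fc) -> BooleanModel:
    model, _ = infer_gates(fig2_core, fig2_fc)
    return model


@pytest.fixture(scope="session")
def melanoma():
    """(core, fc, annot) of the bundled melanoma-style fixture."""
    return melanoma_fixture()


@pytest.fixture(scope="session")
def melanoma_model(melanoma) -> BooleanModel:
    core, fc, _ = melanoma
    model, _ = infer_gates(core, fc)
    return model


# ---------------------------------------------------------------------------
# random model generators for oracle tests


def random_digraph(seed: int, n_nodes: int = 12, density: float = 0.15) -> SignedNetwork:
    """Seeded random signed digraph (no self-loops)."""
    rng = np.random.default_rng(seed)
    net = SignedNetwork()
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    for node in nodes:
        net.add_node(node)
    for i, s in enumerate(nodes):
        for j, t in enumerate(nodes):
            if i != j and rng.random() < density:
                net.add_edge(s, t, int(rng.choice([1, -1, 0], p=[0.5, 0.4, 0.1])))
    return net


def random_acyclic_model(
    seed: int, n_nodes: int = 10, forest: bool = False
) -> BooleanModel:
    """Random acyclic Boolean model with a mix of clamped and free inputs.

    With ``forest=True`` every node regulates at most one downstream node, so
    no free input reaches any node along two distinct paths.
    """
    rng = np.random.default_rng(seed)
    nodes = [f"N{i}" for i in range(n_nodes)]
    used: set[str] = set()
    gates: dict[str, Gate] = {}
    clamps: dict[str, object] = {}
    for i, node in enumerate(nodes):
        available = [n for n in nodes[:i] if not (forest and n in used)]
        k = int(rng.integers(0, min(len(available), 3) + 1)) if available else 0
        if k == 0:
            gates[node] = Gate(GateKind.INPUT)
            clamps[node] = [0, 1, FREE][int(rng.integers(0, 3))]
            continue
        chosen = rng.choice(len(available), size=k, replace=False)
        regs = tuple(
            (
                available[j],
                Polarity.ACTIVATOR if rng.random() < 0.6 else Polarity.INHIBITOR,
            )
            for j in chosen
        )
        used.update(r for r, _ in regs)
        if k == 1:
            gates[node] = Gate(GateKind.IDENTITY, regs)
        else:
            gates[node] = Gate(
                GateKind.AND if rng.random() < 0.5 else GateKind.OR, regs
            )
    return BooleanModel(gates, clamps)  # type: ignore[arg-type]


def exhaustive_two_valued(model: BooleanModel) -> dict[str, int | None]:
    """Oracle: evaluate the acyclic model for every completion of free inputs.

    Returns each node's value when it is identical across all completions,
    else ``None``.
    """
    free = [
        n
        for n, g in model.gates.items()
        if g.kind is GateKind.INPUT and model.clamps.get(n, FREE) == FREE
    ]
    dep = nx.DiGraph()
    dep.add_nodes_from(model.gates)
    for node, gate in model.gates.items():
        for reg, _ in gate.regulators:
            dep.add_edge(reg, node)
    order = list(nx.topological_sort(dep))
    outcomes: dict[str, set[int]] = {n: set() for n in model.gates}
    for combo in product((0, 1), repeat=len(free)):
        assignment = dict(zip(free, combo))
        values: dict[str, int] = {}
        for node in order:
            gate = model.gates[node]
            if gate.kind is GateKind.INPUT:
                clamp = model.clamps.get(node, FREE)
                values[node] = assignment[node] if clamp == FREE else clamp
            else:
                values[node] = gate.evaluate(values)  # all-known => two-valued
        for node, value in values.items():
            outcomes[node].add(value)
    return {n: (vs.pop() if len(vs) == 1 else None) for n, vs in outcomes.items()}


def brute_force_three_cycles(net: SignedNetwork) -> set[tuple[str, str, str]]:
    """Oracle: canonical 3-cycles by iterating all ordered node triples."""
    nodes = net.node_ids
    found = set()
    for a in nodes:
        for b in nodes:
            for c in nodes:
                if len({a, b, c}) != 3:
                    continue
                if net.has_edge(a, b) and net.has_edge(b, c) and net.has_edge(c, a):
                    start = min(range(3), key=lambda i: (a, b, c)[i])
                    cycle = tuple((a, b, c)[(start + i) % 3] for i in range(3))
                    found.add(cycle)
    return found


def brute_force_betweenness(net: SignedNetwork) -> dict[str, float]:
    """Oracle: normalized directed betweenness via explicit path enumeration.

    For every ordered pair (s, t) all shortest paths are enumerated with a
    depth-limited DFS (no Brandes accumulation), and each intermediate node
    is credited its fraction of paths.
    """
    graph = net.graph
    nodes = net.node_ids
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        lengths = nx.single_source_shortest_path_length(graph, s)
        for t in nodes:
            if t == s or t not in lengths:
                continue
            paths: list[list[str]] = []
            _collect_paths(graph, lengths[t], s, t, [s], paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                if through:
                    score[v] += through / len(paths)
    norm = (n - 1) * (n - 2)
    return {v: (score[v] / norm if norm else 0.0) for v in nodes}


def _collect_paths(graph, budget, current, target, prefix, out) -> None:
    if current == target:
        out.append(list(prefix))
        return
    if budget == 0:
        return
    for succ in graph.successors(current):
        if succ not in prefix:
            _collect_paths(graph, budget - 1, succ, target, prefix + [succ], out)
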