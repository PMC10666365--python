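"""Seeded synthetic inputs with the causal structure the pipeline assumes.

Two generators and one bundled fixture:

* :func:`generate_network` emits a random signed digraph with planted 3-node
  feedback loops, in-degree-0 receptor nodes wired into loop constituents,
  and four marker nodes — the shape of a curated regulatory map;
* :func:`generate_ground_truth_model` assigns a random Boolean gate to every
  node, computes the model's logical steady state, and emits a fold-change
  profile whose signs equal those steady states (with a controllable
  fraction of flipped signs), so gate calibration has a known ground truth;
* :func:`melanoma_fixture` is a hand-built, minimal melanoma-style core
  (synthetic, not the map's own 48-node core) whose calibrated model
  reproduces the published stimulus-response behavior: baseline markers
  (ZEB1, CDH1, VIM, SNAI1) = (1, 0, 0, 1) at EMT level 3, MDM2 or MIR25
  inhibition dropping EMT to 1, AKT1 activation raising it to 4, and
  fragility confined to AKT1 and MDM2.

All generators are pure functions of (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import CoreNetwork, Layer
from .io import AnnotationTable, FoldChangeProfile
from .logic import BooleanModel, Gate, GateKind, Polarity, logical_steady_state
from .motifs import FeedbackMotif
from .network import NodeKind, SignedNetwork, Species

SYNTH_MARKERS = ("ZEB1", "CDH1", "VIM", "SNAI1")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study condition.

    ``n_nodes`` counts regulatory-layer nodes; receptors and the four markers
    are added on top. ``sign_mix`` gives (activation, inhibition, neutral)
    edge-sign probabilities. ``fc_noise`` is the fraction of fold-change
    signs flipped away from the ground-truth steady state.
    """

    seed: int = 0
    n_nodes: int = 30
    n_planted_loops: int = 5
    edge_density: float = 0.05
    sign_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    n_receptors: int = 10
    fc_noise: float = 0.0
    fc_magnitude: float = 1.5

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("need at least 4 regulatory nodes")
        if not 0 < self.edge_density < 1:
            raise ValueError("edge_density must be in (0, 1)")
        if abs(sum(self.sign_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.sign_mix):
            raise ValueError("sign_mix must be non-negative and sum to 1")
        if not 0 <= self.fc_noise <= 1:
            raise ValueError("fc_noise must be in [0, 1]")
        if self.fc_magnitude <= 0:
            raise ValueError("fc_magnitude must be positive")
        if self.n_planted_loops < 0 or self.n_receptors < 0:
            raise ValueError("counts must be non-negative")


def _draw_sign(rng: np.random.Generator, mix: tuple[float, float, float]) -> int:
    return int(rng.choice([1, -1, 0], p=mix))


def generate_network(
    scenario: SyntheticScenario,
) -> tuple[SignedNetwork, list[FeedbackMotif]]:
    """Random signed digraph with planted 3-cycles, receptors and markers."""
    rng = np.random.default_rng(scenario.seed)
    regulatory = [f"G{i:03d}" for i in range(scenario.n_nodes)]
    net = SignedNetwork()
    for node in regulatory:
        net.add_node(node, kind=NodeKind.REGULATORY)

    planted_triples: list[tuple[str, str, str]] = []
    for _ in range(scenario.n_planted_loops):
        a, b, c = rng.choice(scenario.n_nodes, size=3, replace=False)
        triple = (regulatory[a], regulatory[b], regulatory[c])
        for s, t in zip(triple, triple[1:] + triple[:1]):
            if not net.has_edge(s, t):
                net.add_edge(s, t, _draw_sign(rng, scenario.sign_mix))
        planted_triples.append(triple)

    for i, source in enumerate(regulatory):
        for j, target in enumerate(regulatory):
            if i == j or net.has_edge(source, target):
                continue
            if rng.random() < scenario.edge_density:
                net.add_edge(source, target, _draw_sign(rng, scenario.sign_mix))

    loop_nodes = sorted({n for t in planted_triples for n in t}) or regulatory
    for i in range(scenario.n_receptors):
        receptor = f"R{i:02d}"
        net.add_node(receptor, kind=NodeKind.RECEPTOR)
        for target in rng.choice(loop_nodes, size=min(2, len(loop_nodes)), replace=False):
            sign = _draw_sign(rng, scenario.sign_mix) or 1  # inputs never neutral
            if not net.has_edge(receptor, str(target)):
                net.add_edge(receptor, str(target), sign)

    p_act, p_inh, _ = scenario.sign_mix
    for marker in SYNTH_MARKERS:
        net.add_node(marker, kind=NodeKind.MARKER)
        sources = rng.choice(regulatory, size=2, replace=False)
        for source in sources:
            sign = _draw_sign(rng, scenario.sign_mix) or 1
            # the epithelial marker is predominantly repressed when inhibition exists
            if marker == "CDH1" and p_inh > 0 and rng.random() < 0.7:
                sign = -1
            if not net.has_edge(str(source), marker):
                net.add_edge(str(source), marker, sign)

    motifs = {FeedbackMotif.from_cycle(t, net) for t in planted_triples}
    return net, sorted(motifs, key=lambda m: m.nodes)


def generate_ground_truth_model(
    net: SignedNetwork, scenario: SyntheticScenario
) -> tuple[BooleanModel, FoldChangeProfile, dict[str, GateKind]]:
    """Random gates + clamps, with fold changes emitted from the model's LSS.

    Returns the model, the (possibly noise-corrupted) fold-change profile,
    and the planted gate kind per node for recovery checks. Nodes whose
    steady state stays unknown are emitted as missing fold changes.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    gates: dict[str, Gate] = {}
    clamps: dict[str, object] = {}
    planted: dict[str, GateKind] = {}
    for node in sorted(net.graph.nodes):
        regulators = tuple(
            (source, Polarity.ACTIVATOR if sign > 0 else Polarity.INHIBITOR)
            for source, sign in net.in_edges(node)
            if sign != 0
        )
        if not regulators:
            gates[node] = Gate(GateKind.INPUT)
            clamps[node] = int(rng.integers(0, 2))
            planted[node] = GateKind.INPUT
        elif len(regulators) == 1:
            gates[node] = Gate(GateKind.IDENTITY, regulators)
            planted[node] = GateKind.IDENTITY
        else:
            kind = GateKind.AND if rng.random() < 0.5 else GateKind.OR
            gates[node] = Gate(kind, regulators)
            planted[node] = kind
    model = BooleanModel(gates, clamps)  # type: ignore[arg-type]

    lss = logical_steady_state(model)
    known = [node for node in model.node_ids if lss[node] is not None]
    magnitudes = rng.lognormal(mean=np.log(scenario.fc_magnitude), sigma=0.5, size=len(known))
    values = {
        node: float(mag) if lss[node] == 1 else -float(mag)
        for node, mag in zip(known, magnitudes)
    }
    n_flip = int(round(scenario.fc_noise * len(known)))
    if n_flip:
        for index in rng.choice(len(known), size=n_flip, replace=False):
            node = known[index]
            values[node] = -values[node]
    return model, FoldChangeProfile(values), planted


def generate_annotations(
    net: SignedNetwork, seed: int, dp_rate: float = 0.3, gp_max: float = 5.0
) -> AnnotationTable:
    """Random disease-pathway flags (Bernoulli) and GP scores (uniform)."""
    rng = np.random.default_rng(seed + 2)
    nodes = sorted(net.graph.nodes)
    return AnnotationTable(
        dp_member={n: bool(rng.random() < dp_rate) for n in nodes},
        gp_score={n: float(rng.uniform(0, gp_max)) for n in nodes},
    )


# ---------------------------------------------------------------------------
# bundled melanoma-style fixture (synthetic)

_FIXTURE_RECEPTORS = (
    "AR", "ESR1", "FGFR1", "FLT4", "NR2F2",
    "NR4A1", "TGFBR1", "TGFBR2", "THRA", "THRB",
)

_FIXTURE_EDGES: tuple[tuple[str, str, int], ...] = (
    # receptor inputs
    ("ESR1", "TWIST1", 1), ("AR", "TWIST1", 1), ("FLT4", "TWIST1", 1),
    ("TGFBR1", "E2F1", 1), ("TGFBR2", "E2F1", 1),
    ("NR2F2", "MIR25", 1), ("NR4A1", "MIR25", 1),
    ("NR2F2", "TP53", 1), ("TGFBR1", "TP53", 1), ("THRB", "TP53", 1),
    ("THRA", "AKT1", 1), ("FGFR1", "AKT1", 1),
    # regulatory layer
    ("AKT1", "MDM2", 1), ("E2F1", "MDM2", 1), ("TP53", "MDM2", 1),
    ("MDM2", "TP53", -1),  # MDM2-p53 negative feedback
    ("AKT1", "VIM", 1),
    ("MDM2", "CDH1", -1), ("MIR25", "CDH1", -1), ("ZEB1", "CDH1", -1),
    ("CDH1", "CTNNB1", -1), ("CDH1", "SNAI2", -1),
    ("CTNNB1", "SNAI1", 1), ("SNAI2", "SNAI1", 1),
    ("E2F1", "ZEB1", 1), ("TWIST1", "ZEB1", 1),
)

# log2 fold changes, invasive vs non-invasive; four receptors are unmeasured
_FIXTURE_FC: dict[str, float] = {
    "ESR1": 2.1, "FGFR1": 1.4, "NR2F2": 0.9, "NR4A1": 1.7,
    "TGFBR1": 1.2, "THRA": -1.1,
    "E2F1": 2.8, "TP53": 0.8, "TWIST1": 1.6, "MIR25": 1.9,
    "AKT1": -0.9, "MDM2": 2.2, "CTNNB1": 1.3, "SNAI2": 1.0,
    "ZEB1": 2.4, "CDH1": -2.6, "VIM": -1.2, "SNAI1": 1.8,
}

_FIXTURE_DP = ("AKT1", "MDM2", "E2F1", "CDH1", "FGFR1", "TP53")

_FIXTURE_GP: dict[str, float] = {
    "AKT1": 4.5, "MDM2": 4.2, "E2F1": 4.8, "TP53": 5.0, "CDH1": 3.9,
    "CTNNB1": 3.1, "TWIST1": 2.4, "MIR25": 2.0, "SNAI2": 1.8, "ZEB1": 3.6,
    "VIM": 2.9, "SNAI1": 3.3, "FGFR1": 2.7, "TGFBR1": 2.2, "ESR1": 1.5,
    "NR2F2": 0.8, "NR4A1": 0.9, "THRA": 0.6, "THRB": 0.5, "AR": 1.1,
    "FLT4": 1.0, "TGFBR2": 1.9,
}


def melanoma_fixture() -> tuple[CoreNetwork, FoldChangeProfile, AnnotationTable]:
    """The bundled melanoma-style core (synthetic stand-in for the real core).

    A 22-node, 26-edge three-layer network: the ten receptor proteins as the
    input layer, an eight-node regulatory layer around the AKT1 -> MDM2 axis
    (with the MDM2 -| CDH1 repression, the CDH1 -| CTNNB1 -> SNAI1 relay and
    the MDM2-p53 negative feedback loop), and the four EMT markers as
    outputs. Fold-change signs are consistent with the model's steady state,
    so calibration matches every measured node.
    """
    net = SignedNetwork.from_edges(_FIXTURE_EDGES)
    layers: dict[str, Layer] = {}
    for node in net.graph.nodes:
        if node in _FIXTURE_RECEPTORS:
            net.set_kind(node, NodeKind.RECEPTOR)
            layers[node] = Layer.INPUT
        elif node in SYNTH_MARKERS:
            net.set_kind(node, NodeKind.MARKER)
            layers[node] = Layer.OUTPUT_MARKER
        else:
            layers[node] = Layer.REGULATORY
    net.set_species("MIR25", Species.MIRNA)
    core = CoreNetwork(
        net=net,
        layers=layers,
        receptors=sorted(_FIXTURE_RECEPTORS),
        markers=list(SYNTH_MARKERS),
    )
    fc = FoldChangeProfile(dict(_FIXTURE_FC))
    annot = AnnotationTable(
        dp_member={n: n in _FIXTURE_DP for n in sorted(net.graph.nodes)},
        gp_score=dict(_FIXTURE_GP),
    )
    return core, fc, annot
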