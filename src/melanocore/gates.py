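"""Fold-change-calibrated gate inference for the core network.

The translation from signed topology to Boolean functions follows a simple
calibration recipe against the signs of log2 fold changes (invasive vs
non-invasive expression): a node's implied Boolean state is 1 for a positive
fold change and 0 for a negative one, and the gate combining its regulators
is chosen so that the gate's output on the regulators' implied states
reproduces the target's implied state.

* no regulators  -> INPUT, clamped to the fold-change sign (missing -> free);
* one regulator  -> IDENTITY (negated literal when the edge inhibits);
* >= 2 regulators -> the OR-of-literals and AND-of-literals candidates are
  evaluated on the regulators' implied states; the matching candidate wins.
  When both match (a tie) OR is kept, treating independent regulation as the
  default; when neither can be confirmed the node falls back to OR and is
  flagged unresolved in the calibration report.

Sign-0 ("unidentified") edges are excluded from gates by default; an option
admits them as activators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import CoreNetwork, Layer
from .io import FoldChangeProfile
from .logic import (
    FREE,
    BooleanModel,
    Gate,
    GateKind,
    Polarity,
    Value,
    logical_steady_state,
    simulate_synchronous,
)


@dataclass(frozen=True)
class GateCall:
    """Calibration outcome for one node."""

    node: str
    gate: GateKind
    n_regulators: int
    resolution: str  # input | identity | or | and | tie-or | unresolved-or | no-fc-or
    note: str = ""


@dataclass
class CalibrationReport:
    calls: list[GateCall] = field(default_factory=list)

    @property
    def unresolved(self) -> list[str]:
        return [c.node for c in self.calls if c.resolution.startswith("unresolved")]

    def for_node(self, node: str) -> GateCall:
        for call in self.calls:
            if call.node == node:
                return call
        raise KeyError(node)


def infer_gates(
    core: CoreNetwork,
    fc: FoldChangeProfile,
    include_neutral: bool = False,
) -> tuple[BooleanModel, CalibrationReport]:
    """Build a Boolean model of the core, calibrated against fold-change signs."""
    gates: dict[str, Gate] = {}
    clamps: dict[str, object] = {}
    report = CalibrationReport()

    for node in sorted(core.net.graph.nodes):
        regulators = tuple(
            (source, Polarity.ACTIVATOR if sign >= 0 else Polarity.INHIBITOR)
            for source, sign in core.net.in_edges(node)
            if sign != 0 or include_neutral
        )
        if not regulators:
            gates[node] = Gate(GateKind.INPUT)
            state = fc.sign_state(node)
            clamps[node] = FREE if state is None else state
            report.calls.append(
                GateCall(
                    node,
                    GateKind.INPUT,
                    0,
                    "input",
                    "free (no fold change)" if state is None else f"clamped {state}",
                )
            )
            continue
        if len(regulators) == 1:
            gates[node] = Gate(GateKind.IDENTITY, regulators)
            report.calls.append(GateCall(node, GateKind.IDENTITY, 1, "identity"))
            continue

        gates[node], call = _calibrate_multi(node, regulators, fc)
        report.calls.append(call)

    return BooleanModel(gates, clamps), report  # type: ignore[arg-type]


def _calibrate_multi(
    node: str, regulators: tuple[tuple[str, Polarity], ...], fc: FoldChangeProfile
) -> tuple[Gate, GateCall]:
    n = len(regulators)
    reg_states: dict[str, Value] = {
        source: fc.sign_state(source) for source, _ in regulators
    }
    target = fc.sign_state(node)
    or_gate = Gate(GateKind.OR, regulators)
    and_gate = Gate(GateKind.AND, regulators)

    if all(v is None for v in reg_states.values()):
        return or_gate, GateCall(
            node, GateKind.OR, n, "no-fc-or", "all regulator fold changes missing"
        )
    if target is None:
        return or_gate, GateCall(
            node, GateKind.OR, n, "no-fc-or", "target fold change missing"
        )

    or_matches = or_gate.evaluate(reg_states) == target
    and_matches = and_gate.evaluate(reg_states) == target
    if or_matches and and_matches:
        return or_gate, GateCall(
            node, GateKind.OR, n, "tie-or", "AND also matches; OR kept as default"
        )
    if or_matches:
        return or_gate, GateCall(node, GateKind.OR, n, "or")
    if and_matches:
        return and_gate, GateCall(node, GateKind.AND, n, "and")
    return or_gate, GateCall(
        node,
        GateKind.OR,
        n,
        "unresolved-or",
        "neither OR nor AND reproduces the target fold-change sign",
    )


@dataclass
class ValidationReport:
    """Per-node comparison of the model's steady state against FC signs."""

    matches: list[str]
    mismatches: list[str]
    undetermined: list[str]
    state: dict[str, Value]
    reached_fixed_point: bool

    @property
    def fraction_matched(self) -> float:
        compared = len(self.matches) + len(self.mismatches)
        return len(self.matches) / compared if compared else 1.0


def calibrated_state(
    model: BooleanModel, fc: FoldChangeProfile
) -> tuple[dict[str, Value], bool]:
    """The model state used for calibration checks.

    The clamp-determined logical steady state is computed first; nodes it
    leaves unknown (e.g. inside feedback cycles) are seeded with their
    fold-change-sign states and the synchronous map is run to its attractor.
    Returns the state and whether a fixed point was reached (on a cyclic
    attractor the clamp-determined values are returned instead).
    """
    lss = logical_steady_state(model)
    seed = {
        node: lss[node] if lss[node] is not None else fc.sign_state(node)
        for node in model.gates
    }
    if seed == lss:  # nothing new to seed; avoid needless simulation
        return lss, True
    attractor = simulate_synchronous(model, seed)
    if attractor.is_fixed_point:
        return attractor.fixed_state(), True
    return lss, False


def validate_calibration(
    model: BooleanModel, fc: FoldChangeProfile
) -> ValidationReport:
    """Check that steady-state node values reproduce fold-change signs."""
    state, fixed = calibrated_state(model, fc)
    matches, mismatches, undetermined = [], [], []
    for node in model.node_ids:
        expected = fc.sign_state(node)
        if expected is None:
            continue  # no observation to compare against
        value = state.get(node)
        if value is None:
            undetermined.append(node)
        elif value == expected:
            matches.append(node)
        else:
            mismatches.append(node)
    return ValidationReport(matches, mismatches, undetermined, state, fixed)


def model_layers(core: CoreNetwork) -> dict[str, Layer]:
    """Convenience re-export of the core's layer partition."""
    return dict(core.layers)
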