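"""Boolean models with three-valued (Kleene) semantics.

Each node carries a gate: ``INPUT`` (no regulators; the node's value comes
from a clamp), ``IDENTITY`` (one regulator, negated when the regulating edge
is inhibitory), or ``AND`` / ``OR`` over regulator literals. A literal is the
regulator itself for an activating edge and its negation for an inhibiting
edge. States are three-valued: 0, 1, or ``None`` for unknown, combined with
Kleene semantics (AND: any 0 -> 0, all 1 -> 1, else unknown; OR dually; NOT
flips and leaves unknown unknown).

Two propagation schemes are provided. :func:`logical_steady_state` computes
the maximal partial fixed point determined by the clamps alone -- the unique
assignment reached by iterating all gates from all-unknown, independent of
update order. :func:`simulate_synchronous` iterates the synchronous update
map from a concrete initial state and returns the attractor it falls into
(a fixed point or a cycle).

The phenotype readout is the ordinal EMT level
``EMT = ZEB1 + NOT(CDH1) + VIM + SNAI1`` in {0..4}; unknown markers widen it
to a tight integer interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Mapping

Value = int | None  # 0, 1, or None for unknown
Clamp = Literal[0, 1, "free"]

FREE: Clamp = "free"

DEFAULT_MARKERS = ("ZEB1", "CDH1", "VIM", "SNAI1")


class GateKind(str, Enum):
    INPUT = "INPUT"
    IDENTITY = "IDENTITY"
    AND = "AND"
    OR = "OR"


class Polarity(str, Enum):
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"


class ModelError(ValueError):
    """Raised on structurally invalid Boolean models or states."""


@dataclass(frozen=True)
class Gate:
    """Boolean function of one node: regulator literals plus a combinator."""

    kind: GateKind
    regulators: tuple[tuple[str, Polarity], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.regulators)
        if self.kind is GateKind.INPUT and n != 0:
            raise ModelError("INPUT gates take no regulators")
        if self.kind is GateKind.IDENTITY and n != 1:
            raise ModelError("IDENTITY gates take exactly one regulator")
        if self.kind in (GateKind.AND, GateKind.OR) and n < 2:
            raise ModelError(f"{self.kind.value} gates need >= 2 regulators")

    def evaluate(self, values: Mapping[str, Value]) -> Value:
        """Kleene evaluation of the gate on a (possibly partial) state."""
        if self.kind is GateKind.INPUT:
            return None
        literals = [
            _literal(values.get(reg), pol) for reg, pol in self.regulators
        ]
        if self.kind is GateKind.IDENTITY:
            return literals[0]
        if self.kind is GateKind.AND:
            if any(v == 0 for v in literals):
                return 0
            if all(v == 1 for v in literals):
                return 1
            return None
        # OR
        if any(v == 1 for v in literals):
            return 1
        if all(v == 0 for v in literals):
            return 0
        return None


def _literal(value: Value, polarity: Polarity) -> Value:
    if polarity is Polarity.INHIBITOR:
        return None if value is None else 1 - value
    return value


@dataclass
class BooleanModel:
    """Per-node gates plus input clamps.

    ``clamps`` assigns 0, 1 or ``"free"`` to INPUT nodes (and, during
    perturbation experiments, to any clamped node); a clamped node carries its
    clamp value at every step regardless of its gate.
    """

    gates: dict[str, Gate]
    clamps: dict[str, Clamp] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, gate in self.gates.items():
            for reg, _ in gate.regulators:
                if reg not in self.gates:
                    raise ModelError(
                        f"regulator {reg!r} of node {node!r} is not a model node"
                    )
        for node, clamp in self.clamps.items():
            if node not in self.gates:
                raise ModelError(f"clamped node {node!r} is not a model node")
            if clamp not in (0, 1, FREE):
                raise ModelError(f"clamp for {node!r} must be 0, 1 or 'free'")

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.gates)

    def with_clamps(self, extra: Mapping[str, int]) -> "BooleanModel":
        """A copy with additional clamps (perturbations) applied."""
        clamps: dict[str, Clamp] = dict(self.clamps)
        for node, value in extra.items():
            if node not in self.gates:
                raise ModelError(f"cannot clamp unknown node {node!r}")
            if value not in (0, 1):
                raise ModelError(f"perturbation clamp must be 0 or 1, got {value!r}")
            clamps[node] = value
        return BooleanModel(dict(self.gates), clamps)

    def fixed_values(self) -> dict[str, Value]:
        """Initial knowledge: clamped nodes known, everything else unknown."""
        values: dict[str, Value] = {node: None for node in self.gates}
        for node, clamp in self.clamps.items():
            if clamp != FREE:
                values[node] = clamp
        return values


def logical_steady_state(model: BooleanModel) -> dict[str, Value]:
    """Three-valued logical steady state (LSS) determined by the clamps.

    Starts from clamps-known / rest-unknown and re-evaluates every gate under
    Kleene semantics until nothing changes. Because the Kleene operators are
    monotone in the information order (unknown below 0 and 1), the iteration
    converges to a unique fixed point regardless of evaluation order; nodes
    the clamps do not determine stay unknown.
    """
    values = model.fixed_values()
    hard = {n for n, c in model.clamps.items() if c != FREE}
    changed = True
    while changed:
        changed = False
        for node in model.node_ids:
            if node in hard:
                continue
            new = model.gates[node].evaluate(values)
            if new is not None and values[node] != new:
                values[node] = new
                changed = True
    return values


def synchronous_step(model: BooleanModel, state: Mapping[str, Value]) -> dict[str, Value]:
    """One synchronous update; clamped nodes keep their clamp value."""
    nxt: dict[str, Value] = {}
    for node in model.gates:
        clamp = model.clamps.get(node, FREE)
        if clamp != FREE:
            nxt[node] = clamp  # type: ignore[assignment]
        elif model.gates[node].kind is GateKind.INPUT:
            nxt[node] = state.get(node)  # free inputs hold their state
        else:
            nxt[node] = model.gates[node].evaluate(state)
    return nxt


@dataclass(frozen=True)
class Attractor:
    """Attractor of the synchronous map: a fixed point or a state cycle."""

    states: tuple[tuple[tuple[str, Value], ...], ...]
    transient_length: int

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def fixed_state(self) -> dict[str, Value]:
        if not self.is_fixed_point:
            raise ModelError(f"attractor has period {self.period}, not a fixed point")
        return dict(self.states[0])


def simulate_synchronous(
    model: BooleanModel,
    initial: Mapping[str, Value],
    max_steps: int | None = None,
) -> Attractor:
    """Iterate the synchronous map from *initial* until a state repeats.

    ``initial`` must assign every model node (0/1, or ``None`` which is
    propagated with Kleene semantics). Clamped nodes are overridden by their
    clamps at every step, including step 0. Default ``max_steps`` is four
    times the node count, ample for the small regulatory cores this models;
    an error is raised if no state repeats within the budget.
    """
    missing = set(model.gates) - set(initial)
    if missing:
        raise ModelError(f"initial state misses nodes: {sorted(missing)}")
    if max_steps is None:
        max_steps = 4 * len(model.gates)

    state: dict[str, Value] = {
        node: model.clamps[node]  # type: ignore[dict-item]
        if model.clamps.get(node, FREE) != FREE
        else initial[node]
        for node in model.gates
    }
    order = model.node_ids
    seen: dict[tuple[Value, ...], int] = {}
    trajectory: list[dict[str, Value]] = []
    for step in range(max_steps + 1):
        key = tuple(state[n] for n in order)
        if key in seen:
            start = seen[key]
            cycle = trajectory[start:]
            return Attractor(
                states=tuple(tuple(sorted(s.items())) for s in cycle),
                transient_length=start,
            )
        seen[key] = step
        trajectory.append(state)
        state = synchronous_step(model, state)
    raise ModelError(f"no repeated state within {max_steps} synchronous steps")


@dataclass(frozen=True)
class EmtLevel:
    """Ordinal EMT level, possibly an interval when markers are unknown."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 4):
            raise ModelError(f"EMT interval [{self.lo}, {self.hi}] out of range")

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2

    def delta(self, baseline: "EmtLevel") -> tuple[int, int]:
        """Interval difference self - baseline."""
        return (self.lo - baseline.hi, self.hi - baseline.lo)

    def __str__(self) -> str:
        return str(self.lo) if self.is_point else f"[{self.lo},{self.hi}]"


def emt_level(
    state: Mapping[str, Value], markers: tuple[str, str, str, str] = DEFAULT_MARKERS
) -> EmtLevel:
    """EMT = ZEB1 + NOT(CDH1) + VIM + SNAI1 with interval closure.

    ``markers`` names the (ZEB1-like, CDH1-like, VIM-like, SNAI1-like) nodes in
    that order; the second contributes negated. Unknown markers contribute
    [0, 1] to the interval.
    """
    for m in markers:
        if m not in state:
            raise ModelError(f"marker {m!r} missing from state")
    zeb1, cdh1, vim, snai1 = (state[m] for m in markers)
    terms = [zeb1, None if cdh1 is None else 1 - cdh1, vim, snai1]
    lo = sum(t for t in terms if t is not None)
    hi = lo + sum(1 for t in terms if t is None)
    return EmtLevel(lo, hi)
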