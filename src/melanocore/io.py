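"""Readers and writers for the pipeline's external formats.

Formats handled:

* signed SIF — 3 whitespace/tab-separated columns ``source sign target``,
  ``#`` comments; signs +1 (activation), -1 (inhibition), 0 (unidentified);
* fold-change tables — TSV with header, node id and log2 fold change, where
  blank/NA cells mean *missing* (never zero);
* annotation tables — TSV with header: node id, disease-pathway membership
  flag, gene-prioritization score;
* weighting-scenario configs — YAML or JSON; a bundled default config ships
  13 scenarios;
* Boolean rules text — a bnet-style dialect, one ``target, expression`` line
  per node with ``&``/``|``/``!`` operators and ``0|1|free`` for inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
import yaml

from .logic import FREE, BooleanModel, Gate, GateKind, ModelError, Polarity
from .network import NetworkError, SignedNetwork

_SIGN_TOKENS = {
    "+1": 1,
    "1": 1,
    "activate": 1,
    "-1": -1,
    "inhibit": -1,
    "0": 0,
    "unknown": 0,
}


class ParseError(ValueError):
    """Raised on malformed input files, with the offending line number."""


# ---------------------------------------------------------------------------
# signed SIF


def read_signed_network(
    path: str | Path,
    duplicate_policy: Literal["error", "keep_first"] = "error",
) -> SignedNetwork:
    """Read a 3-column signed SIF file into a :class:`SignedNetwork`.

    Node kinds default to ``regulatory``; assembly assigns layers later.
    Duplicate (source, target) pairs follow *duplicate_policy*, except that
    duplicates with conflicting signs are always an error.
    """
    if duplicate_policy not in ("error", "keep_first"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    net = SignedNetwork()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 1:  # SIF convention: a lone field is an isolated node
            net.add_node(fields[0])
            continue
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 'source sign target', got {raw!r}"
            )
        source, token, target = fields
        if token not in _SIGN_TOKENS:
            raise ParseError(f"{path}:{lineno}: unknown sign token {token!r}")
        sign = _SIGN_TOKENS[token]
        if net.has_edge(source, target):
            if net.sign(source, target) != sign:
                raise ParseError(
                    f"{path}:{lineno}: duplicate edge {source}->{target} "
                    f"with conflicting sign"
                )
            if duplicate_policy == "error":
                raise ParseError(
                    f"{path}:{lineno}: duplicate edge {source}->{target}"
                )
            continue
        try:
            net.add_edge(source, target, sign)
        except NetworkError as exc:  # pragma: no cover - defensive
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_signed_network(net: SignedNetwork, path: str | Path) -> None:
    lines = ["# source\tsign\ttarget"]
    for s, t, sign in sorted(net.edges()):
        lines.append(f"{s}\t{sign:+d}\t{t}" if sign else f"{s}\t0\t{t}")
    # SIF convention: isolated nodes are written as a single bare field
    connected = {n for s, t, _ in net.edges() for n in (s, t)}
    for node in sorted(set(net.graph.nodes) - connected):
        lines.append(node)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# fold changes


@dataclass
class FoldChangeProfile:
    """Per-node log2 fold changes; absent nodes are *missing*, never zero.

    A zero fold change carries no sign information, so :meth:`sign_state`
    treats it as missing too.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __contains__(self, node: str) -> bool:
        return node in self.values

    def get(self, node: str) -> float | None:
        return self.values.get(node)

    def sign_state(self, node: str) -> int | None:
        """Boolean state implied by the fold-change sign: + -> 1, - -> 0."""
        value = self.values.get(node)
        if value is None or value == 0:
            return None
        return 1 if value > 0 else 0


def read_fold_changes(path: str | Path) -> FoldChangeProfile:
    """Read a TSV (node id, log2FC) table; NA/blank cells become missing."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need node-id and log2FC columns")
    values: dict[str, float] = {}
    for row_number, (node, raw) in enumerate(
        zip(frame.iloc[:, 0], frame.iloc[:, 1]), start=2
    ):
        if pd.isna(raw) or str(raw).strip().upper() in ("", "NA", "NAN"):
            continue
        try:
            value = float(raw)
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {row_number}: non-numeric log2FC {raw!r}"
            ) from exc
        if math.isnan(value):
            continue
        values[str(node)] = value
    return FoldChangeProfile(values)


def write_fold_changes(fc: FoldChangeProfile, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(fc.values.items()), columns=["node", "log2fc"]
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationTable:
    """Disease-pathway membership flags and gene-prioritization scores.

    Unlisted nodes are non-members with GP score 0.
    """

    dp_member: dict[str, bool] = field(default_factory=dict)
    gp_score: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, score in self.gp_score.items():
            if not math.isfinite(score) or score < 0:
                raise ParseError(f"GP score for {node!r} must be finite and >= 0")

    def is_member(self, node: str) -> bool:
        return self.dp_member.get(node, False)

    def gp(self, node: str) -> float:
        return self.gp_score.get(node, 0.0)


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV (node id, dp_member, gp_score) table."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 3:
        raise ParseError(f"{path}: need node-id, dp_member, gp_score columns")
    dp: dict[str, bool] = {}
    gp: dict[str, float] = {}
    for row_number, (node, member, score) in enumerate(
        zip(frame.iloc[:, 0], frame.iloc[:, 1], frame.iloc[:, 2]), start=2
    ):
        node = str(node)
        token = "" if pd.isna(member) else str(member).strip().lower()
        if token in _TRUTHY:
            dp[node] = True
        elif token in _FALSY:
            dp[node] = False
        else:
            raise ParseError(f"{path}: row {row_number}: bad membership {member!r}")
        try:
            gp[node] = float(score)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: row {row_number}: non-numeric GP score {score!r}"
            ) from exc
    return AnnotationTable(dp, gp)


def write_annotations(annot: AnnotationTable, path: str | Path) -> None:
    nodes = sorted(set(annot.dp_member) | set(annot.gp_score))
    frame = pd.DataFrame(
        {
            "node": nodes,
            "dp_member": [int(annot.is_member(n)) for n in nodes],
            "gp_score": [annot.gp(n) for n in nodes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# weighting scenarios


@dataclass(frozen=True)
class WeightScenario:
    """One weighting of the four scoring terms (topology halved-pair, DP, GP, |FC|)."""

    id: str
    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self) -> None:
        weights = (self.w1, self.w2, self.w3, self.w4)
        if any(w < 0 or not math.isfinite(w) for w in weights):
            raise ParseError(f"scenario {self.id!r}: weights must be finite and >= 0")
        if all(w == 0 for w in weights):
            raise ParseError(f"scenario {self.id!r}: at least one weight must be > 0")


def read_weight_scenarios(path: str | Path) -> list[WeightScenario]:
    """Read a YAML/JSON scenario config into file order."""
    payload = yaml.safe_load(Path(path).read_text())
    return _scenarios_from_payload(payload, str(path))


def default_weight_scenarios() -> list[WeightScenario]:
    """The bundled 13-scenario grid (see the packaged ``data/scenarios.yaml``)."""
    text = resources.files("melanocore").joinpath("data/scenarios.yaml").read_text()
    return _scenarios_from_payload(yaml.safe_load(text), "bundled scenarios")


def _scenarios_from_payload(payload: object, origin: str) -> list[WeightScenario]:
    if not isinstance(payload, dict) or "scenarios" not in payload:
        raise ParseError(f"{origin}: expected a top-level 'scenarios' list")
    scenarios = []
    for i, entry in enumerate(payload["scenarios"], start=1):
        try:
            scenarios.append(
                WeightScenario(
                    id=str(entry.get("id", f"s{i:02d}")),
                    w1=float(entry["w1"]),
                    w2=float(entry["w2"]),
                    w3=float(entry["w3"]),
                    w4=float(entry["w4"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{origin}: scenario #{i} malformed: {exc}") from exc
    return scenarios


# ---------------------------------------------------------------------------
# Boolean rules text (bnet-style dialect)


def write_boolean_model(model: BooleanModel, path: str | Path) -> None:
    """Write ``target, expression`` rules; INPUT nodes as ``target, 0|1|free``."""
    lines = ["# target, expression"]
    for node in model.node_ids:
        gate = model.gates[node]
        if gate.kind is GateKind.INPUT:
            lines.append(f"{node}, {model.clamps.get(node, FREE)}")
            continue
        op = " & " if gate.kind is GateKind.AND else " | "
        literals = [
            f"!{reg}" if pol is Polarity.INHIBITOR else reg
            for reg, pol in gate.regulators
        ]
        lines.append(f"{node}, {op.join(literals)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_boolean_model(path: str | Path) -> BooleanModel:
    """Read the rules dialect written by :func:`write_boolean_model`."""
    gates: dict[str, Gate] = {}
    clamps: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno}: expected 'target, expression'")
        target, expression = (part.strip() for part in line.split(",", 1))
        if expression in ("0", "1", FREE):
            gates[target] = Gate(GateKind.INPUT)
            clamps[target] = int(expression) if expression in ("0", "1") else FREE
            continue
        gates[target] = _parse_expression(expression, f"{path}:{lineno}")
    try:
        return BooleanModel(gates, clamps)  # type: ignore[arg-type]
    except ModelError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _parse_expression(expression: str, where: str) -> Gate:
    expression = expression.strip()
    if expression.startswith("(") and expression.endswith(")"):
        expression = expression[1:-1].strip()
    if "&" in expression and "|" in expression:
        raise ParseError(f"{where}: mixed AND/OR expressions are not supported")
    if "&" in expression:
        kind, parts = GateKind.AND, expression.split("&")
    elif "|" in expression:
        kind, parts = GateKind.OR, expression.split("|")
    else:
        kind, parts = GateKind.IDENTITY, [expression]
    regulators = []
    for part in parts:
        token = part.strip().strip("()").strip()
        if not token:
            raise ParseError(f"{where}: empty literal in {expression!r}")
        if token.startswith("!"):
            regulators.append((token[1:].strip(), Polarity.INHIBITOR))
        else:
            regulators.append((token, Polarity.ACTIVATOR))
    return Gate(kind, tuple(regulators))


# ---------------------------------------------------------------------------
# result tables


def write_tsv(rows: Iterable[dict[str, object]], path: str | Path) -> None:
    """Write a list of homogeneous dict rows as a TSV result table."""
    frame = pd.DataFrame(list(rows))
    frame.to_csv(path, sep="\t", index=False)
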