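"""In-silico perturbation screening on the calibrated Boolean model.

A perturbation is a permanent clamp: the targeted node is held at 0
(sustained inhibition) or 1 (sustained activation) and the logical steady
state is recomputed. The readout is the ordinal EMT level. The module
provides the baseline stimulus-response, exhaustive single and double clamp
screens, a single-failure robustness analysis, and the search for minimal
intervention sets driving EMT to its reachable extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

from .assembly import CoreNetwork, Layer
from .logic import (
    DEFAULT_MARKERS,
    BooleanModel,
    EmtLevel,
    ModelError,
    Value,
    emt_level,
    logical_steady_state,
)
from .network import Species

MAX_EVALUATIONS = 10_000


class ScreenError(ValueError):
    """Raised on invalid candidate sets or oversize screens."""


@dataclass(frozen=True)
class PerturbationResult:
    """One intervention with its marker states, EMT level and delta."""

    intervention: tuple[tuple[str, int], ...]  # sorted (node, clamp) pairs
    marker_states: tuple[tuple[str, Value], ...]
    emt: EmtLevel
    delta: tuple[int, int] | None  # interval emt - baseline emt

    @property
    def intervention_dict(self) -> dict[str, int]:
        return dict(self.intervention)

    def describe(self) -> str:
        if not self.intervention:
            return "baseline"
        return ",".join(f"{n}={v}" for n, v in self.intervention)


@dataclass(frozen=True)
class RobustnessReport:
    """Nodes whose single-state failure shifts the EMT level."""

    fragile_nodes: tuple[str, ...]
    tested: int


def regulatory_candidates(
    core: CoreNetwork, include_mirna: bool = True, include_inputs: bool = False
) -> list[str]:
    """Default screening candidates: the regulatory layer minus the markers.

    Perturbation screens keep miRNAs (they are druggable by antagomirs and
    the screen targets every regulatory node); the robustness analysis passes
    ``include_mirna=False`` because it models failures as mutation-type
    events on protein/gene nodes. ``include_inputs`` adds the receptor layer.
    """
    nodes = [
        n
        for n in core.regulatory_nodes()
        if include_mirna or core.net.species(n) is not Species.MIRNA
    ]
    if include_inputs:
        nodes += core.nodes_in_layer(Layer.INPUT)
    return sorted(set(nodes) - set(core.markers))


def _evaluate(
    model: BooleanModel,
    intervention: Mapping[str, int],
    markers: tuple[str, str, str, str],
    baseline: EmtLevel | None,
) -> PerturbationResult:
    perturbed = model.with_clamps(intervention) if intervention else model
    state = logical_steady_state(perturbed)
    emt = emt_level(state, markers)
    return PerturbationResult(
        intervention=tuple(sorted(intervention.items())),
        marker_states=tuple((m, state[m]) for m in markers),
        emt=emt,
        delta=None if baseline is None else emt.delta(baseline),
    )


def baseline_response(
    model: BooleanModel, markers: tuple[str, str, str, str] = DEFAULT_MARKERS
) -> PerturbationResult:
    """Unperturbed steady state and EMT level: the reference for all deltas."""
    return _evaluate(model, {}, markers, baseline=None)


def _check_candidates(
    candidates: Sequence[str], model: BooleanModel, markers: Sequence[str]
) -> None:
    for node in candidates:
        if node in markers:
            raise ScreenError(f"marker {node!r} cannot be a perturbation candidate")
        if node not in model.gates:
            raise ScreenError(f"candidate {node!r} is not a model node")


def single_screen(
    model: BooleanModel,
    candidates: Sequence[str],
    markers: tuple[str, str, str, str] = DEFAULT_MARKERS,
) -> list[PerturbationResult]:
    """Clamp every candidate to 0 and to 1; sorted by EMT, then intervention."""
    _check_candidates(candidates, model, markers)
    base = baseline_response(model, markers).emt
    results = [
        _evaluate(model, {node: value}, markers, base)
        for node in sorted(set(candidates))
        for value in (0, 1)
    ]
    return sorted(results, key=lambda r: (r.emt.lo, r.emt.hi, r.intervention))


def double_screen(
    model: BooleanModel,
    candidates: Sequence[str],
    markers: tuple[str, str, str, str] = DEFAULT_MARKERS,
) -> list[PerturbationResult]:
    """All unordered candidate pairs under every {0,1}^2 clamp combination."""
    unique = sorted(set(candidates))
    n_eval = len(unique) * (len(unique) - 1) * 2  # C(n,2) * 4
    if n_eval > MAX_EVALUATIONS:
        raise ScreenError(
            f"double screen would need {n_eval} evaluations "
            f"(cap {MAX_EVALUATIONS}); restrict the candidate list"
        )
    _check_candidates(candidates, model, markers)
    base = baseline_response(model, markers).emt
    seen: dict[tuple[tuple[str, int], ...], PerturbationResult] = {}
    for a, b in combinations(unique, 2):
        for va, vb in product((0, 1), repeat=2):
            result = _evaluate(model, {a: va, b: vb}, markers, base)
            seen.setdefault(result.intervention, result)
    return sorted(seen.values(), key=lambda r: (r.emt.lo, r.emt.hi, r.intervention))


def robustness_analysis(
    model: BooleanModel,
    candidates: Sequence[str],
    markers: tuple[str, str, str, str] = DEFAULT_MARKERS,
) -> RobustnessReport:
    """Single-failure analysis: flip each node against its baseline value.

    A node with a known baseline steady-state value is clamped to the
    opposite value; a node the baseline leaves unknown is tested at both
    values. The node is fragile iff the EMT level changes (interval midpoints
    compared when unknown markers persist).
    """
    _check_candidates(candidates, model, markers)
    baseline_state = logical_steady_state(model)
    baseline_emt = emt_level(baseline_state, markers)
    fragile = []
    for node in sorted(set(candidates)):
        value = baseline_state[node]
        flips = (1 - value,) if value is not None else (0, 1)
        for flip in flips:
            emt = _evaluate(model, {node: flip}, markers, baseline_emt).emt
            if emt.midpoint != baseline_emt.midpoint:
                fragile.append(node)
                break
    return RobustnessReport(fragile_nodes=tuple(fragile), tested=len(set(candidates)))


@dataclass(frozen=True)
class InterventionSearchResult:
    """Optimal intervention sets for one screening objective."""

    objective: str  # minimize | maximize
    optimum: EmtLevel
    interventions: tuple[PerturbationResult, ...]  # smallest sets first
    baseline: PerturbationResult


def find_minimal_interventions(
    model: BooleanModel,
    candidates: Sequence[str],
    max_size: int = 2,
    objective: str = "minimize",
    markers: tuple[str, str, str, str] = DEFAULT_MARKERS,
) -> InterventionSearchResult:
    """Exhaustive search for size <= *max_size* clamps optimizing EMT.

    Returns every intervention set achieving the optimal reachable EMT level,
    smallest sets first; with an empty candidate list only the baseline is
    reported. Intervals are compared on (lo, hi) for minimization and the
    reverse for maximization.
    """
    if max_size not in (1, 2):
        raise ScreenError("max_size must be 1 or 2 (exhaustive search)")
    if objective not in ("minimize", "maximize"):
        raise ScreenError(f"unknown objective {objective!r}")
    base = baseline_response(model, markers)
    pool: list[PerturbationResult] = [base]
    if candidates:
        pool += single_screen(model, candidates, markers)
        if max_size == 2 and len(set(candidates)) >= 2:
            pool += double_screen(model, candidates, markers)

    def rank(result: PerturbationResult) -> tuple[int, int]:
        key = (result.emt.lo, result.emt.hi)
        return key if objective == "minimize" else (-key[0], -key[1])

    best = min(rank(r) for r in pool)
    winners = sorted(
        (r for r in pool if rank(r) == best),
        key=lambda r: (len(r.intervention), r.intervention),
    )
    # keep only minimal sets: drop supersets of a reported smaller winner
    minimal: list[PerturbationResult] = []
    for result in winners:
        items = set(result.intervention)
        if any(set(kept.intervention) <= items and kept is not result for kept in minimal):
            continue
        minimal.append(result)
    return InterventionSearchResult(
        objective=objective,
        optimum=minimal[0].emt if minimal else base.emt,
        interventions=tuple(minimal),
        baseline=base,
    )


def results_table(results: Sequence[PerturbationResult]) -> list[dict[str, object]]:
    """Flatten screen results into TSV-ready rows."""
    rows = []
    for r in results:
        row: dict[str, object] = {"intervention": r.describe()}
        for marker, value in r.marker_states:
            row[marker] = "NaN" if value is None else value
        row["emt_lo"] = r.emt.lo
        row["emt_hi"] = r.emt.hi
        if r.delta is not None:
            row["delta_lo"], row["delta_hi"] = r.delta
        rows.append(row)
    return rows
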