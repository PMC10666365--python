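"""Multi-objective motif scoring and top-k selection.

Each motif i is scored under a weighting scenario j as

    score_ij = (w1j/2) * (ND_i/max ND + BC_i/max BC)
             +  w2j * DP_i/max DP  +  w3j * GP_i/max GP
             +  w4j * |FC|_i/max |FC|

where ND/BC/GP are aggregated (mean by default) over the motif's three
nodes, DP is the count of motif nodes in the disease pathway, |FC| is the
mean absolute log2 fold change over nodes with data, and every maximum is
taken over the motif batch. The halved topological pair keeps degree and
betweenness from dominating the non-topological evidence. A term whose batch
maximum is zero contributes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

from .io import AnnotationTable, FoldChangeProfile, WeightScenario
from .motifs import FeedbackMotif, TopologyReport

Aggregation = Literal["mean", "sum"]


@dataclass(frozen=True)
class MotifFeatures:
    """Per-motif raw features entering the ranking score."""

    motif: FeedbackMotif
    nd: float
    bc: float
    dp: int
    gp: float
    absfc: float
    fc_missing: bool  # True when no motif node had fold-change data

    def __post_init__(self) -> None:
        if not 0 <= self.dp <= 3:
            raise ValueError(f"dp must be in 0..3, got {self.dp}")


@dataclass(frozen=True)
class MotifScore:
    motif: FeedbackMotif
    scenario_id: str
    score: float


def featurize_motifs(
    motifs: Sequence[FeedbackMotif],
    topo: TopologyReport,
    annot: AnnotationTable,
    fc: FoldChangeProfile,
    aggregation: Aggregation = "mean",
) -> list[MotifFeatures]:
    """Aggregate node-level properties to motif level.

    ND, BC and GP are the mean (or sum) over the three motif nodes; DP is the
    disease-pathway membership count; |FC| averages only over nodes with a
    fold change — a motif with no data at all gets 0 and a flag.
    """
    agg = _aggregator(aggregation)
    features = []
    for motif in motifs:
        for node in motif.nodes:
            if node not in topo.degree:
                raise KeyError(f"motif node {node!r} missing from topology report")
        absfc_values = [
            abs(fc.get(node)) for node in motif.nodes if fc.get(node) is not None
        ]
        features.append(
            MotifFeatures(
                motif=motif,
                nd=agg([topo.degree[n] for n in motif.nodes]),
                bc=agg([topo.betweenness[n] for n in motif.nodes]),
                dp=sum(annot.is_member(n) for n in motif.nodes),
                gp=agg([annot.gp(n) for n in motif.nodes]),
                absfc=sum(absfc_values) / len(absfc_values) if absfc_values else 0.0,
                fc_missing=not absfc_values,
            )
        )
    return features


def _aggregator(aggregation: Aggregation):
    if aggregation == "mean":
        return lambda xs: sum(xs) / len(xs)
    if aggregation == "sum":
        return lambda xs: float(sum(xs))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def score_motifs(
    features: Sequence[MotifFeatures], scenario: WeightScenario
) -> list[MotifScore]:
    """Evaluate the weighted max-normalized score for one scenario."""
    if not features:
        raise ValueError("cannot score an empty feature batch")
    max_nd = max(f.nd for f in features)
    max_bc = max(f.bc for f in features)
    max_dp = max(f.dp for f in features)
    max_gp = max(f.gp for f in features)
    max_absfc = max(f.absfc for f in features)

    def norm(value: float, maximum: float) -> float:
        return value / maximum if maximum > 0 else 0.0

    return [
        MotifScore(
            motif=f.motif,
            scenario_id=scenario.id,
            score=(
                scenario.w1 / 2 * (norm(f.nd, max_nd) + norm(f.bc, max_bc))
                + scenario.w2 * norm(f.dp, max_dp)
                + scenario.w3 * norm(f.gp, max_gp)
                + scenario.w4 * norm(f.absfc, max_absfc)
            ),
        )
        for f in features
    ]


def select_top_motifs(
    scores_by_scenario: dict[str, Sequence[MotifScore]], k: int
) -> tuple[dict[str, list[MotifScore]], list[FeedbackMotif]]:
    """Top-k per scenario plus the deduplicated union of selected motifs.

    Ties break deterministically: score descending, then canonical motif id
    ascending. When a scenario has fewer than k motifs everything is taken,
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top: dict[str, list[MotifScore]] = {}
    union: dict[tuple[str, str, str], FeedbackMotif] = {}
    for scenario_id, scores in scores_by_scenario.items():
        ordered = sorted(scores, key=lambda s: (-s.score, s.motif.motif_id))
        if len(ordered) < k:
            warnings.warn(
                f"scenario {scenario_id}: only {len(ordered)} motifs available "
                f"for top-{k} selection",
                stacklevel=2,
            )
        top[scenario_id] = ordered[:k]
        for entry in top[scenario_id]:
            union.setdefault(entry.motif.nodes, entry.motif)
    return top, [union[key] for key in sorted(union)]
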