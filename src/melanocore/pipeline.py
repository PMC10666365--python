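"""End-to-end orchestration: motifs -> rank -> core -> model -> screen.

The pipeline consumes a single config mapping (usually loaded from YAML)
naming the signed network, fold-change and annotation tables, weighting
scenarios, receptor and marker lists, and writes every stage product plus a
reproducibility manifest into an output directory. Stages fail fast with
the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .assembly import assemble_core
from .gates import infer_gates, validate_calibration
from .io import (
    default_weight_scenarios,
    read_annotations,
    read_fold_changes,
    read_signed_network,
    read_weight_scenarios,
    write_boolean_model,
    write_signed_network,
    write_tsv,
)
from .logic import DEFAULT_MARKERS
from .motifs import compute_topology, enumerate_feedback_loops
from .ranking import featurize_motifs, score_motifs, select_top_motifs
from .screen import (
    baseline_response,
    find_minimal_interventions,
    regulatory_candidates,
    results_table,
    robustness_analysis,
    single_screen,
)

logger = logging.getLogger("melanocore")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict[str, Any]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> PipelineResult:
    """Execute the full workflow described by *config*.

    Required config keys: ``network`` (signed SIF path). Optional:
    ``fold_changes``, ``annotations``, ``scenarios`` (paths; bundled defaults
    used for scenarios), ``receptors`` / ``markers`` (lists or text-file
    paths), ``top_k`` (default 10), ``exclude_neutral_loops`` (default
    false), ``aggregation`` (mean|sum), ``screen_max_size`` (1|2).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs: dict[str, str] = {}

    def input_path(key: str) -> Path | None:
        value = config.get(key)
        if value is None:
            return None
        path = Path(value)
        if not path.exists():
            raise FileNotFoundError(f"config key '{key}': no such file {path}")
        inputs[key] = f"{path}:{_digest(path)}"
        return path

    # validate all inputs before any stage runs
    network_path = input_path("network")
    if network_path is None:
        raise FileNotFoundError("config must name a 'network' SIF file")
    fc_path = input_path("fold_changes")
    annot_path = input_path("annotations")
    scenario_path = input_path("scenarios")
    receptors = _read_list(config.get("receptors"))
    markers = _read_list(config.get("markers")) or list(DEFAULT_MARKERS)
    top_k = int(config.get("top_k", 10))

    counts: dict[str, int] = {}

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done", name)
        return result

    from .io import AnnotationTable, FoldChangeProfile  # local to keep surface tidy

    full = stage("load", lambda: read_signed_network(network_path, "keep_first"))
    fc = read_fold_changes(fc_path) if fc_path else FoldChangeProfile()
    annot = read_annotations(annot_path) if annot_path else AnnotationTable()
    scenarios = (
        read_weight_scenarios(scenario_path)
        if scenario_path
        else default_weight_scenarios()
    )

    # motifs
    def motif_stage():
        motifs = enumerate_feedback_loops(
            full, exclude_neutral=bool(config.get("exclude_neutral_loops", False))
        )
        (outdir / "motifs.json").write_text(
            json.dumps(
                [
                    {"nodes": m.nodes, "edges": m.edges, "loop_sign": m.loop_sign}
                    for m in motifs
                ],
                indent=1,
            )
        )
        return motifs

    motifs = stage("motifs", motif_stage)
    counts["motifs"] = len(motifs)
    logger.info("enumerated %d three-node feedback loops", len(motifs))

    # ranking
    def rank_stage():
        topo = compute_topology(full)
        features = featurize_motifs(
            motifs, topo, annot, fc, aggregation=config.get("aggregation", "mean")
        )
        scores = {s.id: score_motifs(features, s) for s in scenarios}
        top, union = select_top_motifs(scores, top_k)
        rows = []
        for scenario_id, entries in top.items():
            for rank, entry in enumerate(entries, start=1):
                rows.append(
                    {
                        "motif": entry.motif.motif_id,
                        "scenario": scenario_id,
                        "score": round(entry.score, 6),
                        "rank": rank,
                    }
                )
        write_tsv(rows, outdir / "ranking.tsv")
        return union

    selected = stage("rank", rank_stage) if motifs else []
    counts["selected_motifs"] = len(selected)

    # core assembly: fall back to the full network when there are no motifs
    def core_stage():
        if selected:
            core = assemble_core(selected, full, receptors, tuple(markers))
        else:
            raise ValueError("no motifs enumerated; cannot assemble a core")
        write_signed_network(core.net, outdir / "core.sif")
        (outdir / "layers.json").write_text(
            json.dumps({n: l.value for n, l in sorted(core.layers.items())}, indent=1)
        )
        return core

    core = stage("core", core_stage)
    counts["core_nodes"] = len(core.net)
    counts["core_edges"] = core.net.n_edges

    # Boolean model
    def model_stage():
        model, calibration = infer_gates(core, fc)
        write_boolean_model(model, outdir / "model.bnet")
        write_tsv(
            [
                {
                    "node": c.node,
                    "gate": c.gate.value,
                    "n_regulators": c.n_regulators,
                    "resolution": c.resolution,
                    "note": c.note,
                }
                for c in calibration.calls
            ],
            outdir / "calibration.tsv",
        )
        validation = validate_calibration(model, fc)
        write_tsv(
            [
                {"node": n, "status": status}
                for status, nodes in (
                    ("match", validation.matches),
                    ("mismatch", validation.mismatches),
                    ("undetermined", validation.undetermined),
                )
                for n in nodes
            ],
            outdir / "validation.tsv",
        )
        counts["unresolved_gates"] = len(calibration.unresolved)
        counts["calibration_mismatches"] = len(validation.mismatches)
        return model

    model = stage("build-model", model_stage)

    # screening
    def screen_stage():
        markers_t = tuple(markers)
        candidates = regulatory_candidates(core)
        base = baseline_response(model, markers_t)
        singles = single_screen(model, candidates, markers_t)
        write_tsv(results_table([base] + singles), outdir / "screen_single.tsv")
        robustness = robustness_analysis(
            model, regulatory_candidates(core, include_mirna=False), markers_t
        )
        minimal = find_minimal_interventions(
            model,
            candidates,
            max_size=int(config.get("screen_max_size", 2)),
            objective="minimize",
            markers=markers_t,
        )
        (outdir / "screen_summary.json").write_text(
            json.dumps(
                {
                    "baseline_emt": [base.emt.lo, base.emt.hi],
                    "min_emt": [minimal.optimum.lo, minimal.optimum.hi],
                    "minimal_interventions": [
                        r.describe() for r in minimal.interventions
                    ],
                    "fragile_nodes": list(robustness.fragile_nodes),
                },
                indent=1,
            )
        )
        return len(singles)

    counts["screen_rows"] = stage("screen", screen_stage)

    manifest = {
        "tool": "melanocore",
        "version": __version__,
        "config": {k: str(v) for k, v in config.items()},
        "inputs": inputs,
        "counts": counts,
        "seed": config.get("seed"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(outdir=outdir, manifest=manifest)


def _read_list(value: Any) -> list[str]:
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    path = Path(value)
    return [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
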