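"""Perturbation screening, robustness, and minimal-intervention search."""

from __future__ import annotations

import networkx as nx
import pytest

from melanocore import (
    baseline_response,
    double_screen,
    emt_level,
    find_minimal_interventions,
    logical_steady_state,
    regulatory_candidates,
    robustness_analysis,
    single_screen,
)
from melanocore.logic import BooleanModel, Gate, GateKind, Polarity
from melanocore.screen import ScreenError, results_table

ACT, INH = Polarity.ACTIVATOR, Polarity.INHIBITOR
MARKERS = ("ZEB1", "CDH1", "VIM", "SNAI1")


def _chain_to_markers() -> BooleanModel:
    """IN -> A -> B -| CDH1, with the other markers clamped off via inputs."""
    return BooleanModel(
        {
            "IN": Gate(GateKind.INPUT),
            "A": Gate(GateKind.IDENTITY, (("IN", ACT),)),
            "B": Gate(GateKind.IDENTITY, (("A", ACT),)),
            "CDH1": Gate(GateKind.IDENTITY, (("B", INH),)),
            "ZEB1": Gate(GateKind.INPUT),
            "VIM": Gate(GateKind.INPUT),
            "SNAI1": Gate(GateKind.INPUT),
            "LONE": Gate(GateKind.INPUT),  # no path to any marker
        },
        {"IN": 1, "ZEB1": 0, "VIM": 0, "SNAI1": 0, "LONE": 1},
    )


class TestFixtureScreen:
    def test_baseline_reproduces_initial_condition(self, melanoma_model):
        base = baseline_response(melanoma_model)
        assert dict(base.marker_states) == {"ZEB1": 1, "CDH1": 0, "VIM": 0, "SNAI1": 1}
        assert base.emt.lo == base.emt.hi == 3

    def test_known_single_perturbations(self, melanoma_model):
        results = {r.intervention: r for r in single_screen(
            melanoma_model, ["MDM2", "MIR25", "AKT1"]
        )}
        mdm2 = results[(("MDM2", 0),)]
        assert dict(mdm2.marker_states) == {"ZEB1": 1, "CDH1": 1, "VIM": 0, "SNAI1": 0}
        assert mdm2.emt.lo == 1 and mdm2.delta == (-2, -2)
        mir25 = results[(("MIR25", 0),)]
        assert dict(mir25.marker_states) == {"ZEB1": 1, "CDH1": 1, "VIM": 0, "SNAI1": 0}
        assert mir25.emt.lo == 1
        akt1 = results[(("AKT1", 1),)]
        assert dict(akt1.marker_states) == {"ZEB1": 1, "CDH1": 0, "VIM": 1, "SNAI1": 1}
        assert akt1.emt.lo == 4

    def test_mir25_inhibition_leaves_mdm2_active(self, melanoma_model):
        """MIR25 acts on CDH1 in parallel to MDM2, not through it."""
        state = logical_steady_state(melanoma_model.with_clamps({"MIR25": 0}))
        assert state["MDM2"] == 1 and state["CDH1"] == 1

    def test_clamping_a_node_at_its_steady_value_changes_nothing(self, melanoma_model):
        state = logical_steady_state(melanoma_model)
        [result] = [
            r for r in single_screen(melanoma_model, ["E2F1"])
            if r.intervention == (("E2F1", state["E2F1"]),)
        ]
        assert result.delta == (0, 0)

    def test_minimal_interventions_match_screen(self, melanoma, melanoma_model):
        core, _, _ = melanoma
        candidates = regulatory_candidates(core)
        down = find_minimal_interventions(
            melanoma_model, candidates, max_size=1, objective="minimize"
        )
        assert {r.describe() for r in down.interventions} == {"MDM2=0", "MIR25=0"}
        assert down.optimum.lo == down.optimum.hi == 1
        up = find_minimal_interventions(
            melanoma_model, candidates, max_size=1, objective="maximize"
        )
        assert {r.describe() for r in up.interventions} == {"AKT1=1"}
        assert up.optimum.lo == 4

    def test_double_co_inhibition_is_at_least_as_strong(self, melanoma_model):
        doubles = {r.intervention: r for r in double_screen(
            melanoma_model, ["MDM2", "AKT1"]
        )}
        both_off = doubles[(("AKT1", 0), ("MDM2", 0))]
        assert both_off.emt.lo <= 1

    def test_robustness_fragile_set_is_akt1_mdm2(self, melanoma, melanoma_model):
        core, _, _ = melanoma
        report = robustness_analysis(
            melanoma_model, regulatory_candidates(core, include_mirna=False)
        )
        assert report.fragile_nodes == ("AKT1", "MDM2")
        assert report.tested == 7

    def test_including_mirna_failures_adds_mir25(self, melanoma, melanoma_model):
        core, _, _ = melanoma
        report = robustness_analysis(
            melanoma_model, regulatory_candidates(core, include_mirna=True)
        )
        assert set(report.fragile_nodes) == {"AKT1", "MDM2", "MIR25"}


class TestScreenContracts:
    def test_marker_candidate_rejected(self, melanoma_model):
        with pytest.raises(ScreenError, match="marker"):
            single_screen(melanoma_model, ["CDH1"])

    def test_single_screen_has_both_clamp_values_sorted(self, melanoma_model):
        results = single_screen(melanoma_model, ["MDM2", "E2F1"])
        assert len(results) == 4
        assert [r.emt.lo for r in results] == sorted(r.emt.lo for r in results)
        assert {r.intervention for r in results} == {
            (("MDM2", 0),), (("MDM2", 1),), (("E2F1", 0),), (("E2F1", 1),)
        }

    def test_double_screen_combinatorial_count(self, melanoma_model):
        candidates = ["MDM2", "AKT1", "E2F1", "TP53"]
        results = double_screen(melanoma_model, candidates)
        assert len(results) == 6 * 4  # C(4,2) pairs x {0,1}^2

    def test_double_screen_cap(self, melanoma_model):
        too_many = [f"FAKE{i}" for i in range(200)]
        with pytest.raises(ScreenError, match="cap"):
            double_screen(melanoma_model, too_many)

    def test_rerun_is_deterministic(self, melanoma, melanoma_model):
        core, _, _ = melanoma
        candidates = regulatory_candidates(core)
        assert single_screen(melanoma_model, candidates) == single_screen(
            melanoma_model, candidates
        )

    def test_emt_self_consistency_across_table(self, melanoma, melanoma_model):
        core, _, _ = melanoma
        for result in single_screen(melanoma_model, regulatory_candidates(core)):
            recomputed = emt_level(dict(result.marker_states))
            assert (recomputed.lo, recomputed.hi) == (result.emt.lo, result.emt.hi)

    def test_empty_candidates_report_baseline_only(self, melanoma_model):
        result = find_minimal_interventions(melanoma_model, [], objective="minimize")
        assert [r.intervention for r in result.interventions] == [()]


class TestStructuralProperties:
    def test_every_chain_node_is_fragile(self):
        model = _chain_to_markers()
        report = robustness_analysis(model, ["A", "B"])
        assert set(report.fragile_nodes) == {"A", "B"}

    def test_node_without_path_to_markers_never_moves_emt(self):
        model = _chain_to_markers()
        # reachability oracle: LONE has no directed path to any marker
        dep = nx.DiGraph()
        dep.add_nodes_from(model.gates)
        for node, gate in model.gates.items():
            for reg, _ in gate.regulators:
                dep.add_edge(reg, node)
        assert not any(nx.has_path(dep, "LONE", m) for m in MARKERS if m in dep)
        for result in single_screen(model, ["LONE"]):
            assert result.delta == (0, 0)

    def test_planted_dominant_repressor_recovered(self):
        """A screen finds the planted CDH1 repressor as the minimizing clamp."""
        model = BooleanModel(
            {
                "IN": Gate(GateKind.INPUT),
                "REP": Gate(GateKind.IDENTITY, (("IN", ACT),)),
                "CDH1": Gate(GateKind.IDENTITY, (("REP", INH),)),
                "ZEB1": Gate(GateKind.INPUT),
                "VIM": Gate(GateKind.INPUT),
                "SNAI1": Gate(GateKind.INPUT),
            },
            {"IN": 1, "ZEB1": 1, "VIM": 0, "SNAI1": 1},
        )
        result = find_minimal_interventions(
            model, ["REP"], max_size=1, objective="minimize"
        )
        assert {r.describe() for r in result.interventions} == {"REP=0"}

    def test_results_table_rows_are_flat(self, melanoma_model):
        rows = results_table([baseline_response(melanoma_model)])
        assert rows[0]["intervention"] == "baseline"
        assert rows[0]["emt_lo"] == 3 and rows[0]["emt_hi"] == 3
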