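"""Motif featurization and the weighted max-normalized ranking score."""

from __future__ import annotations

import warnings

import pytest

from melanocore import (
    AnnotationTable,
    FeedbackMotif,
    FoldChangeProfile,
    MotifFeatures,
    SignedNetwork,
    TopologyReport,
    WeightScenario,
    compute_topology,
    default_weight_scenarios,
    enumerate_feedback_loops,
    featurize_motifs,
    score_motifs,
    select_top_motifs,
)


def _motif(a: str, b: str, c: str) -> FeedbackMotif:
    net = SignedNetwork.from_edges([(a, b, 1), (b, c, 1), (c, a, 1)])
    return enumerate_feedback_loops(net)[0]


def _features(motif, nd, bc, dp, gp, absfc, missing=False) -> MotifFeatures:
    return MotifFeatures(
        motif=motif, nd=nd, bc=bc, dp=dp, gp=gp, absfc=absfc, fc_missing=missing
    )


class TestFeaturize:
    def test_node_properties_average_and_dp_counts(self):
        motif = _motif("A", "B", "C")
        topo = TopologyReport(
            degree={"A": 2, "B": 4, "C": 6},
            betweenness={"A": 0.1, "B": 0.2, "C": 0.3},
        )
        annot = AnnotationTable(
            dp_member={"A": True, "B": True, "C": True},
            gp_score={"A": 1.0, "B": 2.0, "C": 3.0},
        )
        fc = FoldChangeProfile({"A": 1.0, "B": -2.0})
        [features] = featurize_motifs([motif], topo, annot, fc)
        assert features.nd == pytest.approx(4.0)
        assert features.bc == pytest.approx(0.2)
        assert features.dp == 3
        assert features.gp == pytest.approx(2.0)
        # |FC| averages only over the two measured nodes
        assert features.absfc == pytest.approx(1.5)
        assert not features.fc_missing

    def test_all_fold_changes_missing_flags_motif(self):
        motif = _motif("A", "B", "C")
        topo = TopologyReport(
            degree={"A": 1, "B": 1, "C": 1}, betweenness={"A": 0, "B": 0, "C": 0}
        )
        [features] = featurize_motifs([motif], topo, AnnotationTable(), FoldChangeProfile())
        assert features.absfc == 0.0 and features.fc_missing

    def test_missing_topology_node_raises(self):
        motif = _motif("A", "B", "C")
        topo = TopologyReport(degree={"A": 1}, betweenness={"A": 0})
        with pytest.raises(KeyError, match="B"):
            featurize_motifs([motif], topo, AnnotationTable(), FoldChangeProfile())

    def test_sum_aggregation(self):
        motif = _motif("A", "B", "C")
        topo = TopologyReport(
            degree={"A": 2, "B": 4, "C": 6},
            betweenness={"A": 0.0, "B": 0.0, "C": 0.0},
        )
        [features] = featurize_motifs(
            [motif], topo, AnnotationTable(), FoldChangeProfile(), aggregation="sum"
        )
        assert features.nd == pytest.approx(12.0)


class TestScore:
    def test_topology_only_fixed_point(self):
        m1, m2 = _motif("A", "B", "C"), _motif("D", "E", "F")
        features = [
            _features(m1, nd=6, bc=0.5, dp=0, gp=0, absfc=0),
            _features(m2, nd=3, bc=0.25, dp=0, gp=0, absfc=0),
        ]
        scores = score_motifs(features, WeightScenario("topo", 1, 0, 0, 0))
        assert scores[0].score == pytest.approx(1.0)  # attains both topo maxima
        assert scores[1].score == pytest.approx(0.5)

    def test_all_maxima_under_uniform_weights_scores_four(self):
        m1, m2 = _motif("A", "B", "C"), _motif("D", "E", "F")
        features = [
            _features(m1, nd=6, bc=0.5, dp=3, gp=4.0, absfc=2.0),
            _features(m2, nd=3, bc=0.1, dp=1, gp=1.0, absfc=0.5),
        ]
        scores = score_motifs(features, WeightScenario("uniform", 1, 1, 1, 1))
        assert scores[0].score == pytest.approx(4.0)

    def test_against_per_term_arithmetic_oracle(self):
        """Six tabulated motifs under weights (2,1,1,1), checked to 1e-12."""
        motifs = [_motif(*t) for t in
                  (("A", "B", "C"), ("D", "E", "F"), ("G", "H", "I"),
                   ("J", "K", "L"), ("M", "N", "O"), ("P", "Q", "R"))]
        table = [  # nd, bc, dp, gp, absfc
            (4.0, 0.10, 1, 2.5, 1.20),
            (6.0, 0.40, 3, 4.0, 0.30),
            (2.0, 0.05, 0, 0.5, 2.40),
            (5.0, 0.20, 2, 3.1, 1.90),
            (3.0, 0.35, 1, 1.2, 0.00),
            (1.0, 0.02, 0, 0.1, 0.75),
        ]
        features = [_features(m, *row) for m, row in zip(motifs, table)]
        scenario = WeightScenario("w2111", 2, 1, 1, 1)
        scores = score_motifs(features, scenario)
        max_nd, max_bc = 6.0, 0.40
        max_dp, max_gp, max_fc = 3, 4.0, 2.40
        for score, (nd, bc, dp, gp, fc) in zip(scores, table):
            expected = (
                2 / 2 * (nd / max_nd + bc / max_bc)
                + 1 * dp / max_dp
                + 1 * gp / max_gp
                + 1 * fc / max_fc
            )
            assert score.score == pytest.approx(expected, abs=1e-12)

    def test_zero_max_term_contributes_nothing(self):
        m1, m2 = _motif("A", "B", "C"), _motif("D", "E", "F")
        features = [
            _features(m1, nd=1, bc=0.0, dp=0, gp=0.0, absfc=0.0),
            _features(m2, nd=2, bc=0.0, dp=0, gp=0.0, absfc=0.0),
        ]
        scores = score_motifs(features, WeightScenario("u", 1, 1, 1, 1))
        assert scores[1].score == pytest.approx(0.5)  # only the degree half-term

    def test_linear_in_weights(self):
        m1, m2 = _motif("A", "B", "C"), _motif("D", "E", "F")
        features = [
            _features(m1, nd=4, bc=0.2, dp=2, gp=3.0, absfc=1.0),
            _features(m2, nd=2, bc=0.4, dp=1, gp=1.0, absfc=2.0),
        ]
        base = score_motifs(features, WeightScenario("w", 1, 2, 0.5, 3))
        tripled = score_motifs(features, WeightScenario("w3", 3, 6, 1.5, 9))
        for b, t in zip(base, tripled):
            assert t.score == pytest.approx(3 * b.score)

    def test_invariant_to_rescaling_a_raw_feature(self):
        m1, m2 = _motif("A", "B", "C"), _motif("D", "E", "F")
        features = [
            _features(m1, nd=4, bc=0.2, dp=2, gp=3.0, absfc=1.0),
            _features(m2, nd=2, bc=0.4, dp=1, gp=1.0, absfc=2.0),
        ]
        scaled = [
            _features(f.motif, f.nd * 7.5, f.bc, f.dp, f.gp, f.absfc) for f in features
        ]
        scenario = WeightScenario("w", 1, 1, 1, 1)
        for a, b in zip(score_motifs(features, scenario), score_motifs(scaled, scenario)):
            assert b.score == pytest.approx(a.score)

    def test_dominant_motif_ranks_first_under_all_positive_scenarios(self):
        dominant = _features(_motif("A", "B", "C"), 9, 0.9, 3, 5.0, 3.0)
        rest = [
            _features(_motif("D", "E", "F"), 3, 0.2, 1, 1.0, 0.5),
            _features(_motif("G", "H", "I"), 5, 0.4, 2, 2.0, 1.0),
        ]
        for scenario in default_weight_scenarios():
            scores = score_motifs([dominant] + rest, scenario)
            best = max(scores, key=lambda s: s.score)
            assert best.motif is dominant.motif


class TestSelection:
    def test_thirteen_by_ten_selection_count(self):
        motifs = [_motif(chr(65 + i), f"Y{i}", f"Z{i}") for i in range(15)]
        features = [
            _features(m, nd=15 - i, bc=0.5, dp=1, gp=1.0, absfc=1.0)
            for i, m in enumerate(motifs)
        ]
        scores = {
            s.id: score_motifs(features, s) for s in default_weight_scenarios()
        }
        top, union = select_top_motifs(scores, k=10)
        assert sum(len(v) for v in top.values()) == 130
        assert len(union) <= 130 and union  # duplicates collapsed across scenarios

    def test_truncation_warns_when_k_exceeds_pool(self):
        motif = _motif("A", "B", "C")
        scores = {"only": score_motifs([_features(motif, 1, 0.1, 1, 1, 1)],
                                       WeightScenario("only", 1, 1, 1, 1))}
        with pytest.warns(UserWarning, match="only 1 motifs"):
            top, union = select_top_motifs(scores, k=10)
        assert len(top["only"]) == 1 and len(union) == 1

    def test_ties_break_on_canonical_id(self):
        m_late = _motif("B", "X", "Y")
        m_early = _motif("A", "X", "Y")
        features = [
            _features(m_late, 2, 0.2, 1, 1, 1),
            _features(m_early, 2, 0.2, 1, 1, 1),
        ]
        scores = {"s": score_motifs(features, WeightScenario("s", 1, 1, 1, 1))}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            top, _ = select_top_motifs(scores, k=1)
        assert top["s"][0].motif.nodes[0] == "A"
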