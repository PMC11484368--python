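"""IC partial credit, entailment baseline, definition similarity, ICC,
confidence-gap analysis — each checked against brute-force oracles."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from ontorag.errors import (
    DegenerateVariance,
    EdgeNotAsserted,
    InsufficientData,
    InsufficientLevels,
    MalformedLogicalDefinition,
    UnknownTerm,
)
from ontorag.evaluation import (
    HashTokenBackend,
    RatingRecord,
    aggregate_prf,
    confidence_gap_correlation,
    definition_similarity,
    entail_subsumption,
    icc,
    icc_from_groups,
    information_content,
    is_more_general,
    read_ratings_csv,
    reasoner_baseline,
    score_relationships,
    write_ratings_csv,
)
from ontorag.ontology import SUBCLASS_OF, Curie, LogicalDefinition, Relationship

from .conftest import make_graph, random_dag
from .oracles import anova_icc, brute_entailed, brute_ic, brute_score_relationships


class TestInformationContent:
    def test_root_has_zero_ic(self, chain4):
        graph, curies, _ = chain4
        assert information_content(graph, curies["R"]) == 0.0

    def test_leaf_of_four_term_chain_is_two_bits(self, chain4):
        graph, curies, _ = chain4
        assert information_content(graph, curies["B"]) == pytest.approx(2.0)

    def test_intermediate_term(self, chain4):
        graph, curies, _ = chain4
        assert information_content(graph, curies["A"]) == pytest.approx(-math.log2(3 / 4))

    def test_unknown_term(self, chain4):
        graph, _c, _p = chain4
        with pytest.raises(UnknownTerm):
            information_content(graph, Curie("X", "9999"))

    def test_matches_bruteforce_closure_counting(self):
        rng = random.Random(3)
        for _ in range(20):
            graph, curies, _pred = random_dag(rng, n_max=20)
            for c in curies:
                assert information_content(graph, c) == pytest.approx(brute_ic(graph, c))

    def test_antitone_along_subclass(self):
        """An ancestor never carries more bits than its descendant."""
        rng = random.Random(9)
        for _ in range(20):
            graph, _curies, _pred = random_dag(rng, n_max=25)
            for s, p, o in graph.edges:
                if p == SUBCLASS_OF:
                    assert information_content(graph, o) <= information_content(graph, s) + 1e-12


class TestIsMoreGeneral:
    def test_grandparent_reachable(self):
        graph, c, _ = make_graph(
            {"A": "a", "B": "b", "C": "c"}, [("B", None, "A"), ("C", None, "B")]
        )
        assert is_more_general(graph, c["C"], SUBCLASS_OF, c["A"])

    def test_sibling_not_reachable(self):
        graph, c, _ = make_graph(
            {"A": "a", "B": "b", "C": "c", "S": "s"},
            [("B", None, "A"), ("S", None, "A"), ("C", None, "B")],
        )
        assert not is_more_general(graph, c["C"], SUBCLASS_OF, c["S"])

    def test_mixed_partof_and_isa_chain(self):
        graph, c, preds = make_graph(
            {"A": "a", "B": "b", "C": "c"},
            [("C", "part", "B"), ("B", None, "A")],
            predicates={"part": "part of"},
        )
        assert is_more_general(graph, c["C"], preds["part"], c["A"])


class TestScoreRelationships:
    def test_exact_singleton(self, chain4):
        graph, c, _ = chain4
        gold = [(SUBCLASS_OF, c["A"])]
        judgements = score_relationships(gold, gold, graph, c["B"])
        assert len(judgements) == 1
        assert judgements[0].category == "exact" and judgements[0].credit == 1.0

    def test_general_credit_on_five_term_chain(self, chain5):
        graph, c, _ = chain5
        gold = [(SUBCLASS_OF, c["B"])]
        predicted = [(SUBCLASS_OF, c["A"])]
        judgements = score_relationships(predicted, gold, graph, c["C"])
        assert judgements[0].category == "general"
        expected = (-math.log2(4 / 5)) / (-math.log2(2 / 5))
        assert judgements[0].credit == pytest.approx(expected)
        assert judgements[0].credit == pytest.approx(0.2435, abs=1e-4)

    def test_root_target_zero_credit(self, chain5):
        graph, c, _ = chain5
        judgements = score_relationships(
            [(SUBCLASS_OF, c["R"])], [(SUBCLASS_OF, c["B"])], graph, c["C"]
        )
        assert judgements[0].category == "general" and judgements[0].credit == 0.0

    def test_false_positive(self, chain5):
        graph, c, _ = chain5
        judgements = score_relationships(
            [(SUBCLASS_OF, c["D"])], [(SUBCLASS_OF, c["B"])], graph, c["C"]
        )
        assert judgements[0].category == "false_positive" and judgements[0].credit == 0.0

    def test_each_gold_edge_paired_once(self, chain5):
        graph, c, _ = chain5
        judgements = score_relationships(
            [(SUBCLASS_OF, c["A"]), (SUBCLASS_OF, c["A"])],
            [(SUBCLASS_OF, c["B"])],
            graph,
            c["C"],
        )
        categories = sorted(j.category for j in judgements)
        assert categories == ["false_positive", "general"]

    def test_subclass_only_filter(self, chain5):
        graph, c, preds = chain5
        judgements = score_relationships(
            [(SUBCLASS_OF, c["B"])],
            [(SUBCLASS_OF, c["B"])],
            graph,
            c["C"],
            task_filter="subclass_only",
        )
        assert len(judgements) == 1

    def test_matches_bruteforce_oracle_on_random_dags(self):
        """Exhaustive path-enumeration + closure-counting agreement."""
        rng = random.Random(23)
        for _ in range(40):
            graph, curies, pred = random_dag(rng, n_max=20)
            subject = rng.choice(curies[1:])
            gold = [(p, o) for s, p, o in graph.outgoing(subject)]
            pool = [SUBCLASS_OF, pred]
            predicted = []
            for _k in range(rng.randint(0, 5)):
                predicted.append((rng.choice(pool), rng.choice(curies)))
            if gold and rng.random() < 0.7:
                predicted.append(rng.choice(gold))
            got = score_relationships(predicted, gold, graph, subject)
            expected = brute_score_relationships(predicted, gold, graph, subject)
            assert [(j.predicted, j.category) for j in got] == [
                (p, cat) for p, cat, _cr in expected
            ]
            assert [j.credit for j in got] == pytest.approx([cr for _p, _c, cr in expected])


class TestAggregatePrf:
    def test_worked_example(self):
        from ontorag.evaluation import RelationshipJudgement

        judgements = [
            RelationshipJudgement(("p", "t1"), "exact", ("p", "t1"), 1.0),
            RelationshipJudgement(("p", "t2"), "general", ("p", "t3"), 0.5),
        ]
        s = aggregate_prf(judgements, n_gold=4)
        assert (s.precision, s.recall, s.f1) == (0.75, 0.375, 0.5)

    def test_perfect_predictions(self, chain4):
        graph, c, _ = chain4
        gold = [(SUBCLASS_OF, c["A"])]
        s = aggregate_prf(score_relationships(gold, gold, graph, c["B"]), 1)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_predictions_flagged(self):
        s = aggregate_prf([], n_gold=3)
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)
        assert s.flagged


class TestEntailment:
    def test_redundant_edge_recovered(self):
        graph, c, _ = make_graph(
            {"R": "r", "A": "a", "D": "d"},
            [("A", None, "R"), ("D", None, "A"), ("D", None, "R")],
        )
        assert entail_subsumption(graph, (c["D"], SUBCLASS_OF, c["R"]))

    def test_sole_path_not_recovered(self):
        graph, c, _ = make_graph(
            {"R": "r", "A": "a", "D": "d"},
            [("A", None, "R"), ("D", None, "A"), ("D", None, "R")],
        )
        assert not entail_subsumption(graph, (c["D"], SUBCLASS_OF, c["A"]))

    def test_genus_recovers_edge(self):
        graph, c, preds = make_graph(
            {"G": "g", "X": "x", "F": "f"},
            [("X", None, "G"), ("X", "p", "F")],
            predicates={"p": "part of"},
            logical={"X": ("G", [("p", "F")])},
        )
        assert entail_subsumption(graph, (c["X"], SUBCLASS_OF, c["G"]))

    def test_unasserted_edge_rejected(self, chain4):
        graph, c, _ = chain4
        with pytest.raises(EdgeNotAsserted):
            entail_subsumption(graph, (c["B"], SUBCLASS_OF, c["R"]))

    def test_matches_bruteforce_on_random_dags(self):
        rng = random.Random(31)
        for _ in range(25):
            graph, _curies, _pred = random_dag(rng, n_max=15)
            for edge in sorted(graph.edges, key=str):
                if edge[1] != SUBCLASS_OF:
                    continue
                ld = graph.logical_definitions.get(edge[0])
                genus = ld.genus if ld else None
                assert entail_subsumption(graph, edge) == brute_entailed(
                    graph.edges, edge, edge[0], edge[2], genus
                )


class TestReasonerBaseline:
    def test_redundant_edge_recovered(self):
        graph, c, _ = make_graph(
            {"R": "r", "A": "a", "D": "d"},
            [("A", None, "R"), ("D", None, "A"), ("D", None, "R")],
        )
        s = reasoner_baseline(graph, [c["D"]])
        assert s.precision == 1.0
        # of D's two asserted edges only the redundant one is recovered
        assert s.recall == 0.5

    def test_no_redundancy_recall_zero(self, chain4):
        graph, c, _ = chain4
        s = reasoner_baseline(graph, [c["B"], c["D"]])
        assert s.recall == 0.0 and s.flagged

    def test_precision_always_one_on_random_fixtures(self):
        """Structural theorem: every prediction is an asserted edge."""
        from ontorag.synthetic import FixtureSpec, generate_ontology

        for seed in range(5):
            graph = generate_ontology(FixtureSpec(n_terms=40, redundancy_rate=0.6, seed=seed))
            s = reasoner_baseline(graph, sorted(graph.terms))
            assert s.precision == 1.0


class TestDefinitionSimilarity:
    def test_identical_texts(self):
        p, r, f1 = definition_similarity("excretion of cystathionine", "excretion of cystathionine")
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_one_hot_worked_example(self):
        p, r, f1 = definition_similarity(
            "excretion of cystathionine", "excretion of excessive cystathionine"
        )
        assert p == 1.0
        assert r == 0.75
        assert f1 == pytest.approx(2 * 1.0 * 0.75 / 1.75)

    def test_disjoint_vocabulary_zero(self):
        p, r, f1 = definition_similarity("alpha beta", "gamma delta")
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_symmetry_swaps_p_and_r(self):
        a = definition_similarity("alpha beta gamma", "alpha beta")
        b = definition_similarity("alpha beta", "alpha beta gamma")
        assert a[0] == pytest.approx(b[1])
        assert a[1] == pytest.approx(b[0])
        assert a[2] == pytest.approx(b[2])

    def test_hash_token_backend(self):
        backend = HashTokenBackend(dimension=64, seed=1)
        p, r, f1 = definition_similarity("alpha beta", "alpha beta", backend)
        assert f1 == pytest.approx(1.0)

    def test_empty_text_rejected(self):
        from ontorag.evaluation import EmptyText

        with pytest.raises(EmptyText):
            definition_similarity("", "alpha")


def _ratings(groups, metric="score", confidence=None):
    records = []
    for ev, values in groups.items():
        for i, v in enumerate(values):
            records.append(
                RatingRecord(
                    term_id=f"t{i}",
                    source="model",
                    metric=metric,
                    value=v,
                    evaluator_id=ev,
                    confidence=confidence,
                )
            )
    return records


class TestICC:
    def test_hand_computed_example(self):
        result = icc_from_groups({"ev1": [1, 2, 3], "ev2": [4, 5, 6]})
        assert result.msb == pytest.approx(13.5)
        assert result.mse == pytest.approx(1.0)
        assert result.k == 3
        assert result.icc == pytest.approx(12.5 / 15.5)

    def test_within_constant_between_different_gives_one(self):
        result = icc(_ratings({"ev1": [2, 2, 2], "ev2": [5, 5, 5]}), "score")
        assert result.icc == pytest.approx(1.0)

    def test_single_evaluator_insufficient(self):
        with pytest.raises(InsufficientData):
            icc(_ratings({"ev1": [1, 2, 3]}), "score")

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVariance):
            icc(_ratings({"ev1": [3, 3], "ev2": [3, 3]}), "score")

    def test_confidence_filter_drops_low_confidence(self):
        low = _ratings({"ev1": [1, 1, 1], "ev2": [5, 5, 5]}, confidence=1)
        high = _ratings({"ev1": [1, 2, 3], "ev2": [3, 4, 5]}, confidence=4)
        result = icc(low + high, "score", min_confidence=3)
        expected = icc_from_groups({"ev1": [1, 2, 3], "ev2": [3, 4, 5]})
        assert result.icc == pytest.approx(expected.icc)

    def test_matches_anova_oracle_on_random_balanced_designs(self):
        rng = random.Random(7)
        for _ in range(30):
            n_ev = rng.randint(2, 6)
            n_per = rng.randint(2, 10)
            groups = {
                f"ev{j}": [rng.randint(1, 5) for _ in range(n_per)] for j in range(n_ev)
            }
            flat = [v for g in groups.values() for v in g]
            if len(set(flat)) == 1:
                continue
            result = icc(_ratings(groups), "score")
            expected_icc, msb, mse, k = anova_icc(list(groups.values()))
            assert result.icc == pytest.approx(expected_icc, abs=1e-12)
            assert result.icc <= 1.0
            # cross-check the mean squares against scipy's one-way ANOVA F
            if mse > 0:
                f = stats.f_oneway(*groups.values()).statistic
                assert result.msb / result.mse == pytest.approx(f)

    def test_unbalanced_uses_mean_group_size(self):
        result = icc(_ratings({"ev1": [1, 2], "ev2": [4, 5, 3, 3]}), "score")
        assert result.k == pytest.approx(3.0)


class TestConfidenceGap:
    def _records(self, gap_by_level):
        records = []
        for level, gap in gap_by_level.items():
            for i in range(3):
                records.append(
                    RatingRecord(f"t{i}", "curator", "score", 4, "ev1", confidence=level)
                )
                records.append(
                    RatingRecord(
                        f"t{i}", "model", "score", max(1, round(4 - gap)), "ev1",
                        confidence=level,
                    )
                )
        return records

    def test_perfectly_linear_gap_gives_r_one(self):
        result = confidence_gap_correlation(
            self._records({1: 0, 2: 1, 3: 2}), "curator", "model"
        )
        assert result.pearson_r == pytest.approx(1.0)
        assert result.gaps == [0, 1, 2]

    def test_three_point_worked_example(self):
        result = confidence_gap_correlation(
            self._records({1: 1, 2: 3, 3: 2}), "curator", "model"
        )
        assert result.pearson_r == pytest.approx(0.5)

    def test_zero_gaps_flagged(self):
        result = confidence_gap_correlation(
            self._records({1: 0, 2: 0, 3: 0}), "curator", "model"
        )
        assert result.flagged and math.isnan(result.pearson_r)

    def test_too_few_levels(self):
        with pytest.raises(InsufficientLevels):
            confidence_gap_correlation(self._records({1: 0, 2: 1}), "curator", "model")


class TestLogicalDefinitionScore:
    def _ld(self, pairs):
        return [Relationship(p, t) for p, t in pairs]

    def test_worked_example(self):
        from ontorag.evaluation import score_logical_definitions

        predicted = self._ld([("SubClassOf", "G"), ("HasPart", "X")])
        gold = self._ld([("SubClassOf", "G"), ("HasPart", "X"), ("InheresIn", "Y")])
        s = score_logical_definitions(predicted, gold)
        assert s.precision == 1.0
        assert s.recall == pytest.approx(2 / 3)
        assert s.f1 == pytest.approx(0.8)

    def test_identical_sets(self):
        ld = self._ld([("SubClassOf", "G"), ("HasPart", "X")])
        from ontorag.evaluation import score_logical_definitions

        s = score_logical_definitions(ld, ld)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_flagged(self):
        from ontorag.evaluation import score_logical_definitions

        s = score_logical_definitions([], self._ld([("SubClassOf", "G")]))
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0) and s.flagged

    def test_multiple_genera_malformed(self):
        from ontorag.evaluation import score_logical_definitions

        bad = self._ld([("SubClassOf", "G"), ("SubClassOf", "H")])
        with pytest.raises(MalformedLogicalDefinition):
            score_logical_definitions(bad, bad)


class TestRatingsCsv:
    def test_roundtrip(self, tmp_path):
        records = [
            RatingRecord("t1", "curator", "score", 5, "ev1", confidence=4, notes="fine"),
            RatingRecord("t1", "model", "accuracy", 3, "ev2", confidence=None),
        ]
        path = tmp_path / "ratings.csv"
        write_ratings_csv(records, str(path))
        back = read_ratings_csv(str(path))
        assert back == records
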