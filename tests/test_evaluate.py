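"""Cascade scoring: unit extraction, hand-counted examples, micro-count
conservation, symmetry, and brute-force oracle equivalence."""

import itertools

import pytest

from belkit.evaluate import (
    LEVELS,
    AnnotationSet,
    extract_units,
    score,
    score_as_iaa,
)
from belkit.parser import parse_statement
from belkit.simplify import SimplifyConfig, simplify

TRACK = SimplifyConfig.track()


def canon(text):
    return simplify(parse_statement(text), TRACK)


class TestUnitExtraction:
    def test_term_units_enumerate_entities(self):
        stmt = canon("p(HGNC:TIMP2) decreases act(p(HGNC:MMP2))")
        assert extract_units(stmt, "term") == {"HGNC:TIMP2", "HGNC:MMP2"}

    def test_function_units_pair_code_with_entities(self):
        stmt = canon("p(HGNC:TIMP2) decreases act(p(HGNC:MMP2))")
        assert extract_units(stmt, "function") == {("act", frozenset({"HGNC:MMP2"}))}
        assert extract_units(stmt, "function_secondary") == {"act"}

    def test_pmod_carrier_is_a_function_unit(self):
        stmt = canon("p(HGNC:MAP2K1) => p(HGNC:MAPK3, pmod(P))")
        assert ("pmod", frozenset({"HGNC:MAPK3"})) in extract_units(stmt, "function")

    def test_relationship_units_strip_functions(self):
        stmt = canon("p(HGNC:TIMP2) decreases act(p(HGNC:MMP2))")
        assert extract_units(stmt, "relationship") == {
            (frozenset({"HGNC:TIMP2"}), "decreases", frozenset({"HGNC:MMP2"}))
        }

    def test_statement_unit_is_the_canonical_rendering(self):
        stmt = canon("p(HGNC:TIMP2) decreases act(p(HGNC:MMP2))")
        assert extract_units(stmt, "statement") == {
            "p(HGNC:TIMP2) decreases act(p(HGNC:MMP2))"
        }

    def test_nested_statement_adds_inner_relationship_unit(self):
        stmt = canon(
            "p(HGNC:HGF) decreases (p(HGNC:FAS) increases bp(GOBP:apoptosis))"
        )
        assert len(extract_units(stmt, "relationship")) == 2

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            extract_units(canon("p(HGNC:A1) -> p(HGNC:B1)"), "chapter")


class TestScore:
    def test_identical_sets_are_perfect(self, small_corpus):
        aset = AnnotationSet.from_records(small_corpus)
        report = score(aset, aset)
        for level in LEVELS:
            assert report[level].precision == report[level].recall == 1.0
            assert report[level].f == 1.0

    def test_equivalent_prediction_scores_full_credit(self):
        gold = AnnotationSet.from_pairs(
            [("s1", parse_statement("cat(p(MGI:Crk)) directlyIncreases p(MGI:Bcar1,pmod(P))"))]
        )
        pred = AnnotationSet.from_pairs(
            [("s1", parse_statement("act(p(MGI:Crk)) -> p(MGI:Bcar1,pmod(P,S,41))"))]
        )
        report = score(gold, pred)
        assert report["statement"].f == 1.0

    def test_flipped_polarity_keeps_term_credit_only(self):
        gold = AnnotationSet.from_pairs(
            [("s1", parse_statement("cat(p(MGI:Crk)) directlyIncreases p(MGI:Bcar1,pmod(P))"))]
        )
        pred = AnnotationSet.from_pairs(
            [("s1", parse_statement("act(p(MGI:Crk)) decreases p(MGI:Bcar1,pmod(P))"))]
        )
        report = score(gold, pred)
        assert report["term"].f == 1.0
        assert report["function"].f == 1.0
        assert report["relationship"].f == 0.0
        assert report["statement"].f == 0.0

    def test_sentences_in_only_one_set_count(self):
        gold = AnnotationSet.from_pairs(
            [("s1", parse_statement("p(HGNC:A1) -> p(HGNC:B1)"))]
        )
        pred = AnnotationSet.from_pairs(
            [("s2", parse_statement("p(HGNC:A1) -> p(HGNC:B1)"))]
        )
        report = score(gold, pred)
        assert report["statement"].tp == 0
        assert report["statement"].fp == 1
        assert report["statement"].fn == 1

    def test_empty_prediction_precision_convention(self):
        gold = AnnotationSet.from_pairs(
            [("s1", parse_statement("p(HGNC:A1) -> p(HGNC:B1)"))]
        )
        report = score(gold, AnnotationSet())
        assert report["statement"].precision == 1.0
        assert report["statement"].recall == 0.0
        assert report["statement"].f == 0.0

    def test_micro_counts_conserve(self, small_corpus):
        from belkit.synth import PerturbSpec, perturb

        gold = AnnotationSet.from_records(small_corpus)
        result = perturb(
            small_corpus, PerturbSpec(flip_relationship=0.3, swap_entity=0.2, seed=5)
        )
        report = score(gold, result.predicted)
        gold_c = gold.canonical(TRACK)
        pred_c = result.predicted.canonical(TRACK)
        for level in LEVELS:
            n_gold = sum(
                len(set().union(*(extract_units(s, level) for s in stmts)))
                for stmts in gold_c.items.values()
                if stmts
            )
            n_pred = sum(
                len(set().union(*(extract_units(s, level) for s in stmts)))
                for stmts in pred_c.items.values()
                if stmts
            )
            assert report[level].tp + report[level].fn == n_gold
            assert report[level].tp + report[level].fp == n_pred

    def test_statement_credit_never_exceeds_relationship_credit(self, small_corpus):
        from belkit.synth import PerturbSpec, perturb

        gold = AnnotationSet.from_records(small_corpus)
        result = perturb(small_corpus, PerturbSpec(drop_function=0.4, seed=9))
        report = score(gold, result.predicted)
        assert report["statement"].tp <= report["relationship"].tp


class TestBruteForceOracle:
    """On tiny annotation sets the scorer must agree with a quadratic
    matcher that compares every gold unit against every predicted unit."""

    @staticmethod
    def brute_force(gold, pred, level):
        tp = fp = fn = 0
        for sid in set(gold.items) | set(pred.items):
            g_units = []
            for stmt in gold.items.get(sid, ()):  # collect with duplicates collapsed
                for u in extract_units(simplify(stmt, TRACK), level):
                    if u not in g_units:
                        g_units.append(u)
            p_units = []
            for stmt in pred.items.get(sid, ()):
                for u in extract_units(simplify(stmt, TRACK), level):
                    if u not in p_units:
                        p_units.append(u)
            matched = set()
            for gu in g_units:
                hit = False
                for j, pu in enumerate(p_units):
                    if j not in matched and gu == pu:
                        matched.add(j)
                        hit = True
                        break
                if hit:
                    tp += 1
                else:
                    fn += 1
            fp += len(p_units) - len(matched)
        return tp, fp, fn

    def test_matches_scorer_on_small_sets(self):
        texts = [
            "p(HGNC:A1) -> p(HGNC:B1)",
            "p(HGNC:A1) -| p(HGNC:B1)",
            "cat(p(HGNC:A1)) -> p(HGNC:B1, pmod(P))",
            "p(HGNC:C1) -> bp(GOBP:apoptosis)",
            "complex(p(HGNC:A1), p(HGNC:C1)) -> p(HGNC:B1)",
        ]
        stmts = [parse_statement(t) for t in texts]
        for k_gold in range(1, 4):
            for gold_combo in itertools.combinations(stmts, k_gold):
                for k_pred in range(0, 3):
                    for pred_combo in itertools.combinations(stmts, k_pred):
                        gold = AnnotationSet.from_pairs(
                            [("s1", s) for s in gold_combo]
                        )
                        pred = AnnotationSet.from_pairs(
                            [("s1", s) for s in pred_combo]
                        )
                        report = score(gold, pred)
                        for level in LEVELS:
                            expected = self.brute_force(gold, pred, level)
                            got = (
                                report[level].tp,
                                report[level].fp,
                                report[level].fn,
                            )
                            assert got == expected, (level, gold_combo, pred_combo)


class TestIaaAlias:
    def test_swapping_annotators_swaps_precision_and_recall(self, small_corpus):
        from belkit.synth import PerturbSpec, perturb

        a = AnnotationSet.from_records(small_corpus)
        b = perturb(small_corpus, PerturbSpec(drop_statement=0.2, seed=3)).predicted
        ab = score_as_iaa(a, b)
        ba = score_as_iaa(b, a)
        for level in LEVELS:
            assert ab[level].precision == pytest.approx(ba[level].recall)
            assert ab[level].recall == pytest.approx(ba[level].precision)
            assert ab[level].f == pytest.approx(ba[level].f)
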