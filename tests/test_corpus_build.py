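"""Selection filters (boundaries, dedup, idempotence) and corpus
statistics (category tallies, published-count shares, label arithmetic)."""

import pytest

from belkit.corpus_build import (
    FilterConfig,
    classification_stats,
    corpus_stats,
    count_entities,
    filter_corpus,
    shares_from_counts,
)
from belkit.corpus_io import ClassificationRecord, CorpusRecord
from belkit.parser import parse_statement, parse_term
from belkit.refstats import (
    load_classification_counts,
    load_training_distribution,
    reconstruct_classification_records,
)


def make_record(bel_id="b1", stmt="p(HGNC:A1) increases p(HGNC:B1)",
                sentence=None, pmid="12345678", sentence_id="s1"):
    sentence = sentence or ("A1 markedly increased B1 in all treated cell lines." )
    return CorpusRecord(bel_id, parse_statement(stmt), sentence_id, sentence, pmid)


class TestCountEntities:
    def test_simple_statement(self):
        assert count_entities(parse_statement("p(HGNC:TIMP2) decreases cat(p(HGNC:MMP2))")) == 2

    def test_complex_and_process(self):
        stmt = parse_statement("complex(p(MGI:Fos), p(MGI:Jun)) -> bp(GOBP:apoptosis)")
        assert count_entities(stmt) == 3

    def test_tloc_locations_do_not_count(self):
        stmt = parse_statement(
            'p(HGNC:A1) increases tloc(p(HGNC:NFE2L2), MESHCL:Cytoplasm, MESHCL:"Cell Nucleus")'
        )
        assert count_entities(stmt) == 2


class TestFilters:
    def test_evidence_length_bounds_are_inclusive(self):
        at_min = make_record(sentence="x" * 36)
        below = make_record(bel_id="b2", sentence="x" * 35, sentence_id="s2")
        at_max = make_record(bel_id="b3", sentence="x" * 425, sentence_id="s3")
        above = make_record(bel_id="b4", sentence="x" * 426, sentence_id="s4")
        result = filter_corpus([at_min, below, at_max, above])
        assert {r.bel_id for r in result.kept} == {"b1", "b3"}
        reasons = dict((r.bel_id, rules) for r, rules in result.rejected)
        assert reasons["b2"] == ["evidence-length"]
        assert reasons["b4"] == ["evidence-length"]

    def test_forbidden_functions(self):
        rec = make_record(stmt="composite(p(MGI:Il13),p(MGI:Ifng)) increases bp(GOBP:x1)")
        result = filter_corpus([rec])
        assert result.kept == []
        assert "forbidden-function" in result.rejected[0][1]

    def test_namespace_whitelist_ignores_tloc_locations(self):
        ok = make_record(
            stmt="a(CHEBI:x1) increases tloc(p(MGI:Stk16), GOCC:cytoplasm, GOCC:nucleus)"
        )
        assert filter_corpus([ok]).kept == [ok]
        bad = make_record(stmt="p(RGD:Fas) increases p(HGNC:B1)")
        assert "namespace" in filter_corpus([bad]).rejected[0][1]

    def test_entity_cap(self):
        rec = make_record(
            stmt="complex(p(HGNC:A1),p(HGNC:B1),p(HGNC:C1)) -> complex(p(HGNC:D1),p(HGNC:E1))"
        )
        assert "entity-count" in filter_corpus([rec]).rejected[0][1]

    def test_evidence_sharing_cap_rejects_all_sharers(self):
        shared = "This single evidence text supports a suspicious number of statements."
        recs = [
            make_record(bel_id=f"b{i}", stmt=f"p(HGNC:A{i}) increases p(HGNC:B{i})",
                        sentence=shared, sentence_id="s1")
            for i in range(5)
        ]
        result = filter_corpus(recs)
        assert result.kept == []
        assert all("evidence-sharing" in rules for _, rules in result.rejected)
        # four sharers are fine
        assert len(filter_corpus(recs[:4]).kept) == 4

    def test_deduplication_runs_first(self):
        a = make_record(bel_id="b1")
        b = make_record(bel_id="b2")  # identical statement + evidence + pmid
        result = filter_corpus([a, b])
        assert [r.bel_id for r in result.kept] == ["b1"]
        assert result.rejected == [(b, ["duplicate"])]

    def test_missing_pmid(self):
        rec = make_record(pmid="")
        assert "pmid-required" in filter_corpus([rec]).rejected[0][1]

    def test_variant_exclusion_profile(self):
        rec = make_record(stmt="p(HGNC:A1, sub(E, 545, K)) increases p(HGNC:B1)")
        assert filter_corpus([rec]).kept == [rec]
        assert "protein-variant" in filter_corpus(
            [rec], FilterConfig.sample_test()
        ).rejected[0][1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(evidence_len_min=100, evidence_len_max=50)


class TestCorpusStats:
    def test_generated_corpus_reproduces_quotas(self, small_corpus):
        from belkit.synth import SynthConfig, largest_remainder

        report = corpus_stats(small_corpus)
        config = SynthConfig(n_sentences=60, seed=42)
        n_statements = report.n_records
        n_fun = round(config.function_density * n_statements)
        fun_counts = largest_remainder(config.function_shares, n_fun)
        total_entities = 2 * n_statements + fun_counts["complex"]
        expected_terms = largest_remainder(config.term_shares, total_entities)
        for key in ("P", "A", "bp", "path"):
            assert report.term_counts[key] == expected_terms[key]
        for key, count in fun_counts.items():
            assert report.function_counts[key] == count

    def test_published_training_shares(self):
        dist = load_training_distribution()
        assert shares_from_counts(dist["term"])["P"] == 87
        f_shares = shares_from_counts(dist["function"])
        assert f_shares["act"] == 69
        assert shares_from_counts(dist["relationship"])["increases"] == 73

    def test_directly_relationships_fold_into_plain(self):
        recs = [
            make_record(bel_id="b1", stmt="p(HGNC:A1) => p(HGNC:B1)"),
            make_record(bel_id="b2", stmt="p(HGNC:A1) -> p(HGNC:C1)", sentence_id="s2",
                        sentence="A1 markedly increased C1 in our replication cohort."),
        ]
        report = corpus_stats(recs)
        assert report.relationship_counts == {"increases": 2, "decreases": 0}


class TestClassificationStats:
    def test_published_label_arithmetic(self):
        records = reconstruct_classification_records()
        stats = classification_stats(records)
        counts = load_classification_counts()
        assert stats.n == counts["n"]
        assert stats.fully_true == counts["fully_true"]
        assert stats.partially_true == counts["partially_true"]
        assert stats.changed_false_to_true == 226
        assert stats.fully_true_share == 37

    def test_all_fully_true_means_no_changes(self):
        stmt = parse_statement("p(HGNC:A1) -> p(HGNC:B1)")
        recs = [
            ClassificationRecord(f"c{i}", stmt, "123", "A1 increased B1.", True, True)
            for i in range(5)
        ]
        assert classification_stats(recs).changed_false_to_true == 0

    def test_empty_input(self):
        stats = classification_stats([])
        assert stats.n == 0
        assert stats.fully_true_share == 0
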