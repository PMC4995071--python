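"""Tri-occurrence retrieval: match conditions, window construction,
ranking, limits, and anti-monotonicity."""

import pytest

from belkit.corpus_io import CorpusFormatError
from belkit.parser import parse_statement
from belkit.retrieve import (
    Excerpt,
    SentenceDoc,
    SynonymDict,
    TriggerLexicon,
    find_excerpts,
    label_template,
    read_documents,
)

STMT = parse_statement("p(HGNC:AAA) increases p(HGNC:BBB)")
TRIGGERS = TriggerLexicon({"increases": frozenset({"upregulat", "induc"}),
                           "decreases": frozenset({"inhibit"})})


def doc(pmid, date, *sentences):
    return SentenceDoc(pmid, date, tuple(sentences))


class TestMatching:
    def test_constructed_single_sentence_match(self):
        docs = [doc("1", "2015-01-01", "AAA upregulates BBB.")]
        hits = find_excerpts(STMT, docs, triggers=TRIGGERS)
        assert len(hits) == 1
        assert hits[0].text == "AAA upregulates BBB."
        assert hits[0].n_sentences == 1

    def test_one_entity_only_is_no_match(self):
        docs = [doc("1", "2015-01-01", "AAA was upregulated in our assay.")]
        assert find_excerpts(STMT, docs, triggers=TRIGGERS) == []

    def test_wrong_polarity_trigger_is_no_match(self):
        docs = [doc("1", "2015-01-01", "AAA inhibits BBB.")]
        assert find_excerpts(STMT, docs, triggers=TRIGGERS) == []

    def test_entity_match_is_exact_not_prefix(self):
        docs = [doc("1", "2015-01-01", "AAAX upregulates BBB.")]
        assert find_excerpts(STMT, docs, triggers=TRIGGERS) == []

    def test_trigger_match_is_stem_prefix_and_case_insensitive(self):
        docs = [doc("1", "2015-01-01", "aaa strongly INDUCED bbb.")]
        assert len(find_excerpts(STMT, docs, triggers=TRIGGERS)) == 1

    def test_synonym_dictionary_expands_surface_forms(self):
        syn = SynonymDict({("HGNC", "AAA"): frozenset({"alpha factor"})})
        docs = [doc("1", "2015-01-01", "The alpha factor upregulates BBB.")]
        hits = find_excerpts(STMT, docs, synonyms=syn, triggers=TRIGGERS)
        assert len(hits) == 1
        # the bare name no longer matches once synonyms are defined
        docs = [doc("1", "2015-01-01", "AAA upregulates BBB.")]
        assert find_excerpts(STMT, docs, synonyms=syn, triggers=TRIGGERS) == []

    def test_two_sentence_window_when_single_sentences_fail(self):
        docs = [doc("1", "2015-01-01", "AAA was assayed first.", "It clearly upregulates BBB.")]
        hits = find_excerpts(STMT, docs, triggers=TRIGGERS)
        assert len(hits) == 1
        assert hits[0].n_sentences == 2

    def test_statement_without_two_sides_rejected(self):
        lonely = parse_statement("p(HGNC:AAA) increases p(HGNC:AAA)")
        # both sides present -> fine even if identical
        assert find_excerpts(lonely, [], triggers=TRIGGERS) == []
        with pytest.raises(ValueError, match="polarity"):
            find_excerpts(
                STMT,
                [],
                triggers=TriggerLexicon({"decreases": frozenset({"inhibit"})}),
            )


class TestRanking:
    def test_limit_and_newest_first(self):
        docs = [
            doc(f"{i:02d}", f"2010-{i + 1:02d}-01", "AAA upregulates BBB.")
            for i in range(12)
        ]
        hits = find_excerpts(STMT, docs, triggers=TRIGGERS, limit=10)
        assert len(hits) == 10
        dates = [h.date for h in hits]
        assert dates == sorted(dates, reverse=True)
        assert hits[0].date == "2010-12-01"

    def test_date_ties_break_on_pmid_then_start(self):
        docs = [
            doc("20", "2015-01-01", "AAA upregulates BBB."),
            doc("10", "2015-01-01", "AAA upregulates BBB.", "AAA induces BBB."),
        ]
        hits = find_excerpts(STMT, docs, triggers=TRIGGERS)
        assert [(h.pmid, h.start) for h in hits] == [("10", 0), ("10", 1), ("20", 0)]

    def test_undated_documents_sort_last(self):
        docs = [
            doc("1", None, "AAA upregulates BBB."),
            doc("2", "2001-01-01", "AAA induces BBB."),
        ]
        hits = find_excerpts(STMT, docs, triggers=TRIGGERS)
        assert [h.pmid for h in hits] == ["2", "1"]

    def test_deterministic(self):
        docs = [doc("1", "2015-01-01", "AAA upregulates BBB.")] * 3
        assert find_excerpts(STMT, docs, triggers=TRIGGERS) == find_excerpts(
            STMT, docs, triggers=TRIGGERS
        )

    def test_shrinking_the_lexicon_never_adds_excerpts(self):
        docs = [
            doc("1", "2015-01-01", "AAA upregulates BBB."),
            doc("2", "2014-01-01", "AAA induces BBB."),
        ]
        full = find_excerpts(STMT, docs, triggers=TRIGGERS)
        smaller = TriggerLexicon({"increases": frozenset({"upregulat"}),
                                  "decreases": frozenset({"inhibit"})})
        subset = find_excerpts(STMT, docs, triggers=smaller)
        assert set(subset) <= set(full)

    def test_every_returned_excerpt_reverifies_its_match(self):
        docs = [
            doc("1", "2015-01-01", "AAA upregulates BBB.", "Unrelated text."),
            doc("2", None, "BBB is induced by AAA treatment."),
        ]
        for hit in find_excerpts(STMT, docs, triggers=TRIGGERS):
            text = hit.text.lower()
            assert "aaa" in text and "bbb" in text
            assert any(s in text for s in ("upregulat", "induc"))


class TestTemplates:
    def test_template_populates_fields_unlabeled(self):
        excerpt = Excerpt("99", "2015-01-01", 0, "AAA upregulates BBB.", 1)
        rec = label_template(STMT, excerpt, bel_id="b9")
        assert rec.pmid == "99"
        assert rec.excerpt == "AAA upregulates BBB."
        assert not rec.labeled
        assert not rec.fully_supportive and not rec.partially_supportive

    def test_overlong_excerpt_rejected(self):
        excerpt = Excerpt("99", None, 0, "One. Two. Three.", 3)
        with pytest.raises(CorpusFormatError):
            label_template(STMT, excerpt)


class TestDocumentReader:
    def test_round_trip_of_collection_file(self, tmp_path):
        path = tmp_path / "docs.tsv"
        path.write_text(
            "pmid\tdate\tsentence_index\tsentence\n"
            "11\t2015-01-01\t0\tAAA upregulates BBB.\n"
            "11\t2015-01-01\t1\tSecond sentence.\n"
            "12\t\t0\tUndated document.\n"
        )
        docs = {d.pmid: d for d in read_documents(path)}
        assert docs["11"].sentences == ("AAA upregulates BBB.", "Second sentence.")
        assert docs["12"].date is None

    def test_non_contiguous_indices_rejected(self, tmp_path):
        path = tmp_path / "docs.tsv"
        path.write_text("11\t2015-01-01\t1\tOnly sentence one.\n")
        with pytest.raises(CorpusFormatError, match="contiguous"):
            read_documents(path)
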