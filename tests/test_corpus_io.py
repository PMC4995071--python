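"""File formats: round trips, header handling, escaping, ID integrity,
and the classification label invariant."""

import pytest

from belkit.corpus_io import (
    ClassificationRecord,
    CorpusFormatError,
    CorpusRecord,
    count_excerpt_sentences,
    group_by_sentence,
    join,
    read_bel,
    read_classification,
    read_sentence,
    read_tab,
    write_bel,
    write_classification,
    write_sentence,
    write_tab,
)
from belkit.parser import parse_statement


@pytest.fixture
def records():
    s1 = parse_statement("p(HGNC:A1) increases p(HGNC:B1)")
    s2 = parse_statement("p(HGNC:A1) decreases bp(GOBP:apoptosis)")
    sentence = "A1 markedly increased B1 while suppressing apoptosis in cells."
    return [
        CorpusRecord("S0001_1", s1, "S0001", sentence, "12345678"),
        CorpusRecord("S0001_2", s2, "S0001", sentence, "12345678"),
    ]


class TestTabFormat:
    def test_round_trip(self, records, tmp_path):
        path = tmp_path / "c.tab"
        write_tab(records, path)
        assert read_tab(path) == records
        # write∘read is byte-identical
        second = tmp_path / "c2.tab"
        write_tab(read_tab(path), second)
        assert path.read_bytes() == second.read_bytes()

    def test_header_is_optional_on_read(self, records, tmp_path):
        path = tmp_path / "c.tab"
        write_tab(records, path)
        no_header = "\n".join(path.read_text().splitlines()[1:]) + "\n"
        bare = tmp_path / "bare.tab"
        bare.write_text(no_header)
        assert read_tab(bare) == records

    def test_embedded_tabs_and_newlines_escape(self, tmp_path):
        s = parse_statement("p(HGNC:A1) increases p(HGNC:B1)")
        rec = CorpusRecord("b1", s, "s1", "line one\nwith\ttab", "123")
        path = tmp_path / "esc.tab"
        write_tab([rec], path)
        assert len(path.read_text().splitlines()) == 2
        assert read_tab(path)[0].sentence == "line one\nwith\ttab"

    def test_column_count_mismatch_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text("b1\tp(HGNC:A1) -> p(HGNC:B1)\ts1\ttext\n")  # 4 columns
        with pytest.raises(CorpusFormatError, match="bad.tab:1"):
            read_tab(path)

    def test_unparseable_statement_rejects_unless_lenient(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(
            "b1\tp(HGNC:A1) -> p(HGNC:B1)\ts1\tgood evidence text here\t123\n"
            "b2\tnot a statement\ts2\tmore evidence text here\t124\n"
        )
        with pytest.raises(CorpusFormatError, match="b2"):
            read_tab(path)
        kept = read_tab(path, lenient=True)
        assert [r.bel_id for r in kept] == ["b1"]

    def test_duplicate_bel_id_rejected(self, records, tmp_path):
        dup = records + [records[0]]
        with pytest.raises(CorpusFormatError, match="duplicate"):
            write_tab(dup, tmp_path / "dup.tab")

    def test_conflicting_sentence_id_rejected(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(
            "b1\tp(HGNC:A1) -> p(HGNC:B1)\ts1\tevidence text one\t123\n"
            "b2\tp(HGNC:A1) -| p(HGNC:B1)\ts1\tdifferent text entirely\t123\n"
        )
        with pytest.raises(CorpusFormatError, match="two different texts"):
            read_tab(path)

    def test_grouping_by_sentence(self, records):
        groups = group_by_sentence(records)
        assert set(groups) == {"S0001"}
        assert len(groups["S0001"]) == 2


class TestTrioFormat:
    def test_join_equals_tab_on_consistent_trio(self, records, tmp_path):
        write_bel(records, tmp_path / "c.BEL")
        write_sentence(records, tmp_path / "c.sentence")
        joined = join(read_bel(tmp_path / "c.BEL"), read_sentence(tmp_path / "c.sentence"))
        assert sorted(joined, key=lambda r: r.bel_id) == records

    def test_dangling_sentence_id_reported(self, records, tmp_path):
        write_bel(records, tmp_path / "c.BEL")
        (tmp_path / "c.sentence").write_text("sentence_id\tpmid\tsentence\n")
        with pytest.raises(CorpusFormatError, match="dangling"):
            join(read_bel(tmp_path / "c.BEL"), read_sentence(tmp_path / "c.sentence"))

    def test_empty_files_give_empty_records(self, tmp_path):
        (tmp_path / "e.BEL").write_text("bel_id\tbel_statement\n")
        (tmp_path / "e.sentence").write_text("sentence_id\tpmid\tsentence\n")
        assert join(read_bel(tmp_path / "e.BEL"), read_sentence(tmp_path / "e.sentence")) == []


class TestClassificationFormat:
    def make(self, fully, partially):
        return ClassificationRecord(
            "c1",
            parse_statement("p(HGNC:A1) -> p(HGNC:B1)"),
            "123",
            "A1 increased B1.",
            fully,
            partially,
        )

    def test_round_trip(self, tmp_path):
        recs = [self.make(True, True), self.make(False, True), self.make(False, False)]
        recs = [
            ClassificationRecord(f"c{i}", r.statement, r.pmid, r.excerpt,
                                 r.fully_supportive, r.partially_supportive)
            for i, r in enumerate(recs)
        ]
        path = tmp_path / "cls.tab"
        write_classification(recs, path)
        assert read_classification(path) == recs

    def test_fully_implies_partially(self, tmp_path):
        path = tmp_path / "bad.tab"
        path.write_text(
            "c1\tp(HGNC:A1) -> p(HGNC:B1)\t123\tA1 increased B1.\ttrue\tfalse\n"
        )
        with pytest.raises(CorpusFormatError, match="implies"):
            read_classification(path)

    def test_long_excerpt_warns_or_errors(self, tmp_path):
        excerpt = "First sentence here. Second sentence here. Third sentence here."
        path = tmp_path / "long.tab"
        path.write_text(
            f"c1\tp(HGNC:A1) -> p(HGNC:B1)\t123\t{excerpt}\tfalse\tfalse\n"
        )
        with pytest.warns(UserWarning, match="sentences"):
            read_classification(path)
        with pytest.raises(CorpusFormatError, match="sentences"):
            read_classification(path, strict_excerpt_limit=True)

    def test_sentence_counter_heuristic(self):
        assert count_excerpt_sentences("One sentence only.") == 1
        assert count_excerpt_sentences("First one. Second one.") == 2
        assert count_excerpt_sentences("Approx. 3 mg was used.") == 1
        assert count_excerpt_sentences("") == 0
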