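"""Readers and writers for the nanopub corpus file formats.

Three tab-separated formats carry the extraction corpora:

``.tab``
    five columns: BEL-ID, BEL statement, sentence ID, evidence sentence,
    PMID — one nanopub per line;
``.BEL``
    BEL-ID and BEL statement;
``.sentence``
    sentence ID, PMID and evidence sentence.

A ``.BEL``/``.sentence`` pair joined on the shared ID spaces carries the
same information as the ``.tab`` file.  The sentence-classification
format pairs a statement with a text excerpt of at most two sentences
and two boolean labels, *fully supportive* and *partially supportive*;
fully supportive implies partially supportive.

A header row is optional on read (recognized by its canonical column
names or a non-numeric PMID field) and always written.  Embedded tabs
and newlines in evidence text are escaped as ``\\t``/``\\n``.  Round
trips are identity: ``write`` then ``read`` reproduces the records,
``read`` then ``write`` reproduces the file up to header and newline
convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import BelStatement, render
from .parser import BelSyntaxError, parse_statement

__all__ = [
    "CorpusRecord",
    "ClassificationRecord",
    "CorpusFormatError",
    "read_tab",
    "write_tab",
    "read_bel",
    "read_sentence",
    "write_bel",
    "write_sentence",
    "join",
    "read_classification",
    "write_classification",
    "group_by_sentence",
    "count_excerpt_sentences",
]

TAB_HEADER = ("bel_id", "bel_statement", "sentence_id", "sentence", "pmid")
BEL_HEADER = ("bel_id", "bel_statement")
SENTENCE_HEADER = ("sentence_id", "pmid", "sentence")
CLASSIFICATION_HEADER = (
    "bel_id",
    "bel_statement",
    "pmid",
    "excerpt",
    "fully_supportive",
    "partially_supportive",
)


class CorpusFormatError(ValueError):
    """A malformed corpus file; the message carries line numbers."""


@dataclass(frozen=True)
class CorpusRecord:
    """One BEL nanopub as serialized in the corpus files: a statement,
    its evidence sentence and the PubMed citation."""

    bel_id: str
    statement: BelStatement
    sentence_id: str
    sentence: str
    pmid: str


@dataclass(frozen=True)
class ClassificationRecord:
    """A statement–excerpt pair with supportiveness labels.  ``fully``
    implies ``partially``; ``labeled=False`` marks a retrieval template
    awaiting manual annotation."""

    bel_id: str
    statement: BelStatement
    pmid: str
    excerpt: str
    fully_supportive: bool = False
    partially_supportive: bool = False
    labeled: bool = True


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out: List[str] = []
    i = 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def _read_rows(path, n_columns: int, header: Sequence[str]) -> List[Tuple[int, List[str]]]:
    rows: List[Tuple[int, List[str]]] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_columns:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected {n_columns} tab-separated columns, "
                f"got {len(fields)}"
            )
        rows.append((lineno, fields))
    if rows and _looks_like_header(rows[0][1], header):
        rows = rows[1:]
    return rows


def _looks_like_header(fields: List[str], header: Sequence[str]) -> bool:
    if [f.strip().lower() for f in fields] == list(header):
        return True
    # a PMID column holding something non-numeric marks a header row
    try:
        pmid_idx = list(header).index("pmid")
    except ValueError:
        return False
    return not fields[pmid_idx].strip().isdigit()


def _parse_statements(
    rows: Iterable[Tuple[int, str, str]], path, lenient: bool
) -> Dict[str, BelStatement]:
    """rows of (lineno, bel_id, statement text) -> {bel_id: ast};
    parse failures are collected and reject the file unless lenient."""
    parsed: Dict[str, BelStatement] = {}
    failures: List[str] = []
    for lineno, bel_id, text in rows:
        if bel_id in parsed:
            raise CorpusFormatError(f"{path}:{lineno}: duplicate BEL-ID {bel_id!r}")
        try:
            parsed[bel_id] = parse_statement(text)
        except BelSyntaxError as exc:
            failures.append(f"{path}:{lineno}: {bel_id}: {exc}")
    if failures and not lenient:
        raise CorpusFormatError(
            "unparseable statements:\n" + "\n".join(failures)
        )
    return parsed


def read_tab(path, lenient: bool = False) -> List[CorpusRecord]:
    """Read a five-column ``.tab`` corpus file.

    With ``lenient=True`` records whose statement does not parse are
    dropped instead of rejecting the whole file.
    """
    rows = _read_rows(path, 5, TAB_HEADER)
    parsed = _parse_statements(
        ((lineno, f[0], f[1]) for lineno, f in rows), path, lenient
    )
    records: List[CorpusRecord] = []
    sentence_texts: Dict[str, str] = {}
    for lineno, fields in rows:
        bel_id, _stmt, sid, sentence, pmid = fields
        if bel_id not in parsed:
            continue  # lenient drop
        sentence = _unescape(sentence)
        if sid in sentence_texts and sentence_texts[sid] != sentence:
            raise CorpusFormatError(
                f"{path}:{lineno}: sentence ID {sid!r} maps to two different texts"
            )
        sentence_texts[sid] = sentence
        if not pmid:
            raise CorpusFormatError(f"{path}:{lineno}: empty PMID for {bel_id!r}")
        records.append(CorpusRecord(bel_id, parsed[bel_id], sid, sentence, pmid))
    return records


def write_tab(records: Sequence[CorpusRecord], path) -> None:
    lines = ["\t".join(TAB_HEADER)]
    seen = set()
    for r in records:
        if r.bel_id in seen:
            raise CorpusFormatError(f"duplicate BEL-ID {r.bel_id!r} on write")
        seen.add(r.bel_id)
        lines.append(
            "\t".join(
                (r.bel_id, render(r.statement), r.sentence_id, _escape(r.sentence), r.pmid)
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bel(path, lenient: bool = False) -> Dict[str, BelStatement]:
    """Read a ``.BEL`` file into ``{bel_id: statement}``."""
    rows = _read_rows(path, 2, BEL_HEADER)
    filtered = []
    for lineno, fields in rows:
        if fields[0].strip().lower() == "bel_id":
            continue
        filtered.append((lineno, fields[0], fields[1]))
    return _parse_statements(filtered, path, lenient)


def read_sentence(path) -> Dict[str, Tuple[str, str]]:
    """Read a ``.sentence`` file into ``{sentence_id: (pmid, text)}``."""
    out: Dict[str, Tuple[str, str]] = {}
    for lineno, fields in _read_rows(path, 3, SENTENCE_HEADER):
        sid, pmid, sentence = fields
        if sid in out:
            raise CorpusFormatError(f"{path}:{lineno}: duplicate sentence ID {sid!r}")
        out[sid] = (pmid, _unescape(sentence))
    return out


def write_bel(records: Sequence[CorpusRecord], path) -> None:
    lines = ["\t".join(BEL_HEADER)]
    lines += [f"{r.bel_id}\t{render(r.statement)}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_sentence(records: Sequence[CorpusRecord], path) -> None:
    lines = ["\t".join(SENTENCE_HEADER)]
    seen = set()
    for r in records:
        if r.sentence_id in seen:
            continue
        seen.add(r.sentence_id)
        lines.append(f"{r.sentence_id}\t{r.pmid}\t{_escape(r.sentence)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def join(
    bel: Dict[str, BelStatement],
    sentences: Dict[str, Tuple[str, str]],
    pairing: Optional[Dict[str, str]] = None,
) -> List[CorpusRecord]:
    """Join ``.BEL`` statements with ``.sentence`` evidence.

    ``pairing`` maps BEL-ID to sentence ID; the link normally comes from
    the ``.tab`` file.  When omitted, the BEL-ID is assumed to extend
    its sentence ID with an underscore suffix (``S0001_2`` -> ``S0001``),
    the convention this package's writers use.  Dangling IDs on either
    side raise :class:`CorpusFormatError`.
    """
    if pairing is None:
        pairing = {bid: bid.rsplit("_", 1)[0] for bid in bel}
    records: List[CorpusRecord] = []
    dangling = [bid for bid in bel if bid not in pairing]
    dangling += [bid for bid, sid in pairing.items() if bid not in bel]
    dangling += [
        sid for sid in pairing.values() if sid not in sentences
    ]
    if dangling:
        raise CorpusFormatError(f"dangling IDs in join: {sorted(set(dangling))}")
    for bel_id, stmt in bel.items():
        sid = pairing[bel_id]
        pmid, text = sentences[sid]
        records.append(CorpusRecord(bel_id, stmt, sid, text, pmid))
    return records


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}

_SENTENCE_SPLIT = re.compile(r"[.!?]['\")\]]*\s+(?=[A-Z])")


def count_excerpt_sentences(excerpt: str) -> int:
    """Heuristic sentence count: terminal punctuation followed by space
    and a capital starts a new sentence."""
    text = excerpt.strip()
    if not text:
        return 0
    return len(_SENTENCE_SPLIT.split(text))


def _parse_bool(value: str, path, lineno: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise CorpusFormatError(f"{path}:{lineno}: not a boolean label: {value!r}")


def read_classification(
    path, lenient: bool = False, strict_excerpt_limit: bool = False
) -> List[ClassificationRecord]:
    """Read the sentence-classification corpus.

    A row with fully=true but partially=false violates the label
    implication and rejects the file.  Excerpts longer than two
    sentences warn, or raise when ``strict_excerpt_limit`` is set.
    """
    rows = _read_rows(path, 6, CLASSIFICATION_HEADER)
    parsed = _parse_statements(
        ((lineno, f[0], f[1]) for lineno, f in rows), path, lenient
    )
    records: List[ClassificationRecord] = []
    for lineno, fields in rows:
        bel_id, _stmt, pmid, excerpt, fully_s, partially_s = fields
        if bel_id not in parsed:
            continue
        fully = _parse_bool(fully_s, path, lineno)
        partially = _parse_bool(partially_s, path, lineno)
        if fully and not partially:
            raise CorpusFormatError(
                f"{path}:{lineno}: {bel_id!r} is fully supportive but not "
                "partially supportive (fully implies partially)"
            )
        excerpt = _unescape(excerpt)
        n_sent = count_excerpt_sentences(excerpt)
        if n_sent > 2:
            msg = (
                f"{path}:{lineno}: excerpt of {bel_id!r} spans {n_sent} sentences "
                "(limit is two)"
            )
            if strict_excerpt_limit:
                raise CorpusFormatError(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(
            ClassificationRecord(bel_id, parsed[bel_id], pmid, excerpt, fully, partially)
        )
    return records


def write_classification(records: Sequence[ClassificationRecord], path) -> None:
    lines = ["\t".join(CLASSIFICATION_HEADER)]
    for r in records:
        lines.append(
            "\t".join(
                (
                    r.bel_id,
                    render(r.statement),
                    r.pmid,
                    _escape(r.excerpt),
                    str(r.fully_supportive).lower(),
                    str(r.partially_supportive).lower(),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def group_by_sentence(records: Iterable[CorpusRecord]) -> Dict[str, List[CorpusRecord]]:
    """Group nanopubs sharing one evidence sentence (co-reference
    evidence yields several statements per sentence ID)."""
    out: Dict[str, List[CorpusRecord]] = {}
    for r in records:
        out.setdefault(r.sentence_id, []).append(r)
    return out
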