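"""Tri-occurrence candidate-evidence retrieval.

Given a BEL statement, the retriever scans a local sentence collection
for text windows of one or two consecutive sentences that contain (i) a
surface form of a subject-side entity, (ii) a surface form of an
object-side entity and (iii) a trigger word of the statement's
relationship polarity.  Candidates are sorted newest publication first
and capped (10 by default), mimicking the semi-automatic excerpt
proposal step that precedes manual supportiveness annotation.

Matching is deliberately shallow — token-boundary, case-insensitive,
stem-prefix on triggers — because entity recognition proper is out of
scope; the synonym dictionary stands in for a named-entity annotator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import re
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .corpus_io import ClassificationRecord, CorpusFormatError
from .model import BelStatement, NamespaceEntity
from .simplify import SimplifyConfig, simplify

__all__ = [
    "SentenceDoc",
    "TriggerLexicon",
    "SynonymDict",
    "Excerpt",
    "find_excerpts",
    "label_template",
    "read_documents",
]


@dataclass(frozen=True)
class SentenceDoc:
    """A document split into ordered sentences; ``date`` is an ISO 8601
    publication date or None (undated documents sort last)."""

    pmid: str
    date: Optional[str]
    sentences: Tuple[str, ...]


@dataclass(frozen=True)
class TriggerLexicon:
    """Trigger word stems per relationship polarity; matching is
    case-insensitive stem-prefix (``upregulat`` hits ``upregulates``)."""

    stems: Mapping[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        for polarity, stems in self.stems.items():
            if not stems:
                raise ValueError(f"empty trigger set for polarity {polarity!r}")

    @classmethod
    def default(cls) -> "TriggerLexicon":
        text = (
            resources.files("belkit").joinpath("data/triggers.tsv").read_text("utf-8")
        )
        return cls._parse(text.splitlines())

    @classmethod
    def from_file(cls, path) -> "TriggerLexicon":
        return cls._parse(Path(path).read_text(encoding="utf-8").splitlines())

    @classmethod
    def _parse(cls, lines: Iterable[str]) -> "TriggerLexicon":
        acc: Dict[str, Set[str]] = {}
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            polarity, stem = line.split("\t")
            acc.setdefault(polarity, set()).add(stem.lower())
        return cls({p: frozenset(s) for p, s in acc.items()})


@dataclass(frozen=True)
class SynonymDict:
    """Surface forms per (namespace, name); an entity absent from the
    dictionary matches its own name."""

    entries: Mapping[Tuple[str, str], FrozenSet[str]] = field(default_factory=dict)

    def surfaces(self, entity: NamespaceEntity) -> FrozenSet[str]:
        forms = self.entries.get((entity.namespace, entity.name))
        return forms if forms else frozenset({entity.name})

    @classmethod
    def from_file(cls, path) -> "SynonymDict":
        acc: Dict[Tuple[str, str], Set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ns, name, synonym = line.split("\t")
            acc.setdefault((ns, name), set()).add(synonym)
        return cls({k: frozenset(v) for k, v in acc.items()})


@dataclass(frozen=True)
class Excerpt:
    pmid: str
    date: Optional[str]
    start: int  # index of the first sentence in the window
    text: str
    n_sentences: int


def _boundary_pattern(surface: str, prefix: bool) -> re.Pattern:
    tail = r"[A-Za-z0-9]*" if prefix else ""
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(surface) + tail + r"(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


def _any_match(patterns: Sequence[re.Pattern], text: str) -> bool:
    return any(p.search(text) for p in patterns)


_POLARITY = {
    "increases": "increases",
    "directlyIncreases": "increases",
    "decreases": "decreases",
    "directlyDecreases": "decreases",
}


def find_excerpts(
    statement: BelStatement,
    docs: Sequence[SentenceDoc],
    synonyms: Optional[SynonymDict] = None,
    triggers: Optional[TriggerLexicon] = None,
    limit: int = 10,
) -> List[Excerpt]:
    """Candidate evidence windows for ``statement``, newest first.

    Each returned window (one or two consecutive sentences of one
    document) contains a subject-side entity synonym, an object-side
    entity synonym and a polarity trigger.  Two-sentence windows are
    returned only when neither component sentence qualifies alone, so
    the result list never contains a window nested in another.  Ties in
    publication date break on (pmid, window start).  Deterministic.
    """
    synonyms = synonyms or SynonymDict()
    triggers = triggers or TriggerLexicon.default()

    subject_entities = list(statement.subject.entities())
    obj = statement.object
    object_entities = list(obj.entities())
    if not subject_entities or not object_entities:
        raise ValueError(
            "tri-occurrence retrieval needs entities on both statement sides"
        )

    polarity = _POLARITY[statement.relationship]
    if polarity not in triggers.stems:
        raise ValueError(f"trigger lexicon has no stems for polarity {polarity!r}")

    subj_patterns = [
        _boundary_pattern(s, prefix=False)
        for e in subject_entities
        for s in sorted(synonyms.surfaces(e))
    ]
    obj_patterns = [
        _boundary_pattern(s, prefix=False)
        for e in object_entities
        for s in sorted(synonyms.surfaces(e))
    ]
    trig_patterns = [
        _boundary_pattern(s, prefix=True) for s in sorted(triggers.stems[polarity])
    ]

    def qualifies(text: str) -> bool:
        return (
            _any_match(subj_patterns, text)
            and _any_match(obj_patterns, text)
            and _any_match(trig_patterns, text)
        )

    hits: List[Excerpt] = []
    for doc in docs:
        single = [qualifies(s) for s in doc.sentences]
        for i, ok in enumerate(single):
            if ok:
                hits.append(Excerpt(doc.pmid, doc.date, i, doc.sentences[i], 1))
        for i in range(len(doc.sentences) - 1):
            if single[i] or single[i + 1]:
                continue
            window = doc.sentences[i] + " " + doc.sentences[i + 1]
            if qualifies(window):
                hits.append(Excerpt(doc.pmid, doc.date, i, window, 2))

    # identical windows (same pmid/position/extent) collapse
    seen: Set[Tuple[str, int, int]] = set()
    unique: List[Excerpt] = []
    for e in hits:
        key = (e.pmid, e.start, e.n_sentences)
        if key not in seen:
            seen.add(key)
            unique.append(e)
    hits = unique

    hits.sort(key=lambda e: (e.pmid, e.start))
    dated = [e for e in hits if e.date is not None]
    undated = [e for e in hits if e.date is None]
    dated.sort(key=lambda e: e.date, reverse=True)  # stable: ties keep order
    ordered = dated + undated
    return ordered[: max(limit, 0)]


def label_template(
    statement: BelStatement, excerpt: Excerpt, bel_id: str = ""
) -> ClassificationRecord:
    """An unlabeled classification record for manual supportiveness
    annotation of a retrieved excerpt."""
    if excerpt.n_sentences > 2:
        raise CorpusFormatError("excerpts are limited to two sentences")
    return ClassificationRecord(
        bel_id=bel_id,
        statement=statement,
        pmid=excerpt.pmid,
        excerpt=excerpt.text,
        fully_supportive=False,
        partially_supportive=False,
        labeled=False,
    )


def read_documents(path) -> List[SentenceDoc]:
    """Read a sentence collection: tab-separated pmid, date,
    sentence_index, sentence.  Indices must be contiguous from 0 within
    each document; an empty date field means undated."""
    rows: Dict[str, Dict[int, Tuple[Optional[str], str]]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        pmid, date, idx_s, sentence = fields
        if pmid.strip().lower() == "pmid":
            continue  # header
        try:
            idx = int(idx_s)
        except ValueError:
            raise CorpusFormatError(f"{path}:{lineno}: bad sentence index {idx_s!r}")
        rows.setdefault(pmid, {})[idx] = (date or None, sentence)
    docs: List[SentenceDoc] = []
    for pmid, by_idx in rows.items():
        if sorted(by_idx) != list(range(len(by_idx))):
            raise CorpusFormatError(
                f"document {pmid}: sentence indices are not contiguous from 0"
            )
        date = by_idx[0][0]
        docs.append(
            SentenceDoc(
                pmid=pmid,
                date=date,
                sentences=tuple(by_idx[i][1] for i in range(len(by_idx))),
            )
        )
    return docs
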