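"""Corpus selection filters and descriptive statistics.

The base-corpus selection keeps nanopubs whose evidence text can train a
text-mining system: a PubMed citation is present, the evidence is one or
two sentences long (36–425 characters), at most four nanopubs share one
evidence text (more usually means the "evidence" is a table or figure
reference), and the statement itself stays within the restricted
namespace, relationship, entity-count and function budget.

Statistics mirror the corpus report tables: unique sentence and
statement counts, term-type counts per entity occurrence (P/A/bp/path),
function-type counts (act-class, pmod, complex, tloc, deg, sub, trunc),
relationship counts with the ``directly*`` forms folded in, and
percentage shares rounded half-up to whole percents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .corpus_io import ClassificationRecord, CorpusRecord
from .model import (
    ACTIVITY_FUNCTIONS,
    BelStatement,
    BelTerm,
    render,
)

__all__ = [
    "FilterConfig",
    "FilterResult",
    "StatsReport",
    "ClassificationStats",
    "filter_corpus",
    "count_entities",
    "corpus_stats",
    "classification_stats",
    "shares_from_counts",
    "round_half_up_percent",
]

DEFAULT_NAMESPACES = frozenset({"HGNC", "MGI", "EGID", "MESHD", "CHEBI", "GOBP"})
CAUSAL_RELATIONSHIPS = frozenset(
    {"increases", "decreases", "directlyIncreases", "directlyDecreases"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Selection rules for building a base corpus from raw nanopubs.

    Defaults encode the published selection: evidence length 36–425
    characters inclusive, fewer than five nanopubs per evidence text,
    the four causal relationship types, the six-namespace whitelist, at
    most four named entities, and no ``composite()``/``rxn()``.
    ``exclude_variants`` additionally drops protein variants
    (sub/trunc/fus), as the re-annotated sample/test profiles do.
    """

    require_pmid: bool = True
    max_nanopubs_per_evidence: int = 4
    evidence_len_min: int = 36
    evidence_len_max: int = 425
    allowed_relationships: frozenset = CAUSAL_RELATIONSHIPS
    allowed_namespaces: frozenset = DEFAULT_NAMESPACES
    max_entities: int = 4
    forbidden_functions: frozenset = frozenset({"composite", "rxn"})
    exclude_variants: bool = False

    def __post_init__(self) -> None:
        if self.evidence_len_min > self.evidence_len_max:
            raise ValueError("evidence_len_min must be <= evidence_len_max")
        if self.max_nanopubs_per_evidence < 0 or self.max_entities < 0:
            raise ValueError("count limits must be >= 0")

    @classmethod
    def sample_test(cls) -> "FilterConfig":
        return cls(exclude_variants=True)


@dataclass
class FilterResult:
    kept: List[CorpusRecord]
    rejected: List[Tuple[CorpusRecord, List[str]]]


def count_entities(statement: BelStatement) -> int:
    """Number of namespace-entity occurrences in the subject and object
    terms.  Translocation location arguments do not count; fusion
    partner genes do."""
    return sum(1 for _ in statement.entities(include_locations=False))


def _statement_functions(statement: BelStatement) -> Set[str]:
    out: Set[str] = set()
    for top in statement.terms():
        for term in top.walk():
            out.add(term.function)
            for mod in term.modifications:
                out.add(mod.kind)
    return out


def _relationships(statement: BelStatement) -> Set[str]:
    out = {statement.relationship}
    if statement.object_is_statement:
        out |= _relationships(statement.object)
    return out


def _namespaces(statement: BelStatement) -> Set[str]:
    return {e.namespace for e in statement.entities(include_locations=False)}


def _record_rules(record: CorpusRecord, config: FilterConfig) -> List[str]:
    """Every individually checkable rule the record violates."""
    rules: List[str] = []
    if config.require_pmid and not record.pmid.strip().isdigit():
        rules.append("pmid-required")
    length = len(record.sentence.strip())
    if not (config.evidence_len_min <= length <= config.evidence_len_max):
        rules.append("evidence-length")
    bad_rel = _relationships(record.statement) - config.allowed_relationships
    if bad_rel:
        rules.append("relationship")
    bad_ns = _namespaces(record.statement) - config.allowed_namespaces
    if bad_ns:
        rules.append("namespace")
    if count_entities(record.statement) > config.max_entities:
        rules.append("entity-count")
    fns = _statement_functions(record.statement)
    if fns & config.forbidden_functions:
        rules.append("forbidden-function")
    if config.exclude_variants and fns & {"sub", "trunc", "fus"}:
        rules.append("protein-variant")
    return rules


def filter_corpus(
    records: Sequence[CorpusRecord], config: Optional[FilterConfig] = None
) -> FilterResult:
    """Apply the selection filters; returns kept records plus every
    rejected record with the full list of rules it violated.

    Deduplication (identical canonical statement + evidence + PMID) runs
    first, keeping the record with the smallest BEL-ID so the outcome
    does not depend on input order.  Idempotent: filtering the kept set
    again keeps everything.
    """
    config = config or FilterConfig()
    kept: List[CorpusRecord] = []
    rejected: List[Tuple[CorpusRecord, List[str]]] = []

    # dedup on (statement, evidence, pmid)
    by_key: Dict[Tuple[str, str, str], List[CorpusRecord]] = {}
    for r in records:
        key = (render(r.statement), r.sentence.strip(), r.pmid)
        by_key.setdefault(key, []).append(r)
    survivors: List[CorpusRecord] = []
    for group in by_key.values():
        group = sorted(group, key=lambda r: r.bel_id)
        survivors.append(group[0])
        for dup in group[1:]:
            rejected.append((dup, ["duplicate"]))

    # evidence-sharing cap, computed after dedup
    per_evidence: Dict[str, int] = {}
    for r in survivors:
        text = r.sentence.strip()
        per_evidence[text] = per_evidence.get(text, 0) + 1

    for r in sorted(survivors, key=lambda r: r.bel_id):
        rules = _record_rules(r, config)
        if per_evidence[r.sentence.strip()] > config.max_nanopubs_per_evidence:
            rules.append("evidence-sharing")
        if rules:
            rejected.append((r, rules))
        else:
            kept.append(r)
    return FilterResult(kept=kept, rejected=rejected)


# --- statistics -----------------------------------------------------------


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Whole-percent share with half-up rounding (0 when empty)."""
    if not denominator:
        return 0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def shares_from_counts(counts: Mapping[str, int]) -> Dict[str, int]:
    """Percentage share per category, rounded half-up to whole percents."""
    total = sum(counts.values())
    return {k: round_half_up_percent(v, total) for k, v in counts.items()}


TERM_TYPES = ("P", "A", "bp", "path")
FUNCTION_TYPES = ("act", "pmod", "complex", "tloc", "deg", "sub", "trunc")
RELATIONSHIP_TYPES = ("increases", "decreases")

_TERM_TYPE_BY_FUNCTION = {"p": "P", "a": "A", "bp": "bp", "path": "path"}


@dataclass
class StatsReport:
    """Corpus summary: counts and whole-percent shares per category.

    ``extra_term_counts`` tallies entity occurrences outside the printed
    four-way split (g/r/m abundances, named complexes); they are
    excluded from the term shares.
    """

    n_records: int
    n_sentences: int
    n_unique_statements: int
    term_counts: Dict[str, int]
    function_counts: Dict[str, int]
    relationship_counts: Dict[str, int]
    extra_term_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def term_shares(self) -> Dict[str, int]:
        return shares_from_counts(self.term_counts)

    @property
    def function_shares(self) -> Dict[str, int]:
        return shares_from_counts(self.function_counts)

    @property
    def relationship_shares(self) -> Dict[str, int]:
        return shares_from_counts(self.relationship_counts)

    def as_rows(self):
        yield ("records", "", self.n_records, "")
        yield ("unique_sentences", "", self.n_sentences, "")
        yield ("unique_statements", "", self.n_unique_statements, "")
        for cat, counts, shares in (
            ("term", self.term_counts, self.term_shares),
            ("function", self.function_counts, self.function_shares),
            ("relationship", self.relationship_counts, self.relationship_shares),
        ):
            for key, value in counts.items():
                yield (cat, key, value, shares[key])
        for key, value in self.extra_term_counts.items():
            yield ("term_extra", key, value, "")


def _tally_statement(
    stmt: BelStatement,
    term_counts: Dict[str, int],
    extra: Dict[str, int],
    function_counts: Dict[str, int],
) -> None:
    for top in stmt.terms():
        for term in top.walk():
            fn = term.function
            if term.entity is not None:
                ttype = _TERM_TYPE_BY_FUNCTION.get(fn)
                if ttype is not None:
                    term_counts[ttype] += 1
                else:
                    extra[fn] = extra.get(fn, 0) + 1
            if fn in ACTIVITY_FUNCTIONS:
                function_counts["act"] += 1
            elif fn == "complex":
                function_counts["complex"] += 1
            elif fn in ("tloc", "sec", "surf"):
                function_counts["tloc"] += 1
            elif fn == "deg":
                function_counts["deg"] += 1
            for mod in term.modifications:
                if mod.kind in ("pmod", "sub", "trunc"):
                    function_counts[mod.kind] += 1


def corpus_stats(records: Sequence[CorpusRecord]) -> StatsReport:
    """Tally the category distributions of a corpus.

    Term types count entity occurrences by their enclosing abundance or
    process function (p -> P, a -> A, bp, path); the activity family is
    folded into ``act`` and ``sec``/``surf`` into ``tloc``; relationship
    shares fold ``directly*`` into the plain forms.
    """
    term_counts = {t: 0 for t in TERM_TYPES}
    function_counts = {f: 0 for f in FUNCTION_TYPES}
    relationship_counts = {r: 0 for r in RELATIONSHIP_TYPES}
    extra: Dict[str, int] = {}
    sentences: Set[str] = set()
    statements: Set[str] = set()
    for r in records:
        sentences.add(r.sentence_id)
        statements.add(render(r.statement))
        _tally_statement(r.statement, term_counts, extra, function_counts)
        for rel in _iter_relationships(r.statement):
            folded = rel.replace("directlyIncreases", "increases").replace(
                "directlyDecreases", "decreases"
            )
            relationship_counts[folded] += 1
    return StatsReport(
        n_records=len(records),
        n_sentences=len(sentences),
        n_unique_statements=len(statements),
        term_counts=term_counts,
        function_counts=function_counts,
        relationship_counts=relationship_counts,
        extra_term_counts=extra,
    )


def _iter_relationships(stmt: BelStatement):
    yield stmt.relationship
    if stmt.object_is_statement:
        yield from _iter_relationships(stmt.object)


@dataclass(frozen=True)
class ClassificationStats:
    """Label arithmetic over a sentence-classification corpus."""

    n: int
    fully_true: int
    fully_false: int
    partially_true: int
    partially_false: int
    changed_false_to_true: int

    @property
    def fully_true_share(self) -> int:
        return round_half_up_percent(self.fully_true, self.n)

    @property
    def partially_true_share(self) -> int:
        return round_half_up_percent(self.partially_true, self.n)

    @property
    def changed_share(self) -> int:
        return round_half_up_percent(self.changed_false_to_true, self.n)


def classification_stats(records: Sequence[ClassificationRecord]) -> ClassificationStats:
    """True/false counts per label tier plus the number of excerpts that
    flip from false to true when the partially-supportive criterion
    replaces the fully-supportive one."""
    fully = sum(r.fully_supportive for r in records)
    partially = sum(r.partially_supportive for r in records)
    changed = sum(
        r.partially_supportive and not r.fully_supportive for r in records
    )
    n = len(records)
    return ClassificationStats(
        n=n,
        fully_true=fully,
        fully_false=n - fully,
        partially_true=partially,
        partially_false=n - partially,
        changed_false_to_true=changed,
    )
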