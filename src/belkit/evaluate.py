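"""Cascade scorer: precision/recall/F at term, function, relationship and
statement levels.

Automatically extracted BEL statements are rarely perfect, so the scorer
gives partial credit through a cascade of unit granularities.  Per
sentence, gold and predicted statements are canonicalized, decomposed
into unit sets at each level, and matched as sets; true/false
positives/negatives are micro-averaged over all sentences.

Levels (coarse to fine):

``term``
    every namespace entity occurring in a statement;
``function_secondary``
    the bare non-abundance function codes used;
``function``
    non-abundance functions paired with the entity set they contain
    (``act``, ``tloc``, ``deg``, ``complex`` and ``pmod`` carriers);
``relationship_secondary``
    the relationship plus the unordered pair of subject/object entity
    sets;
``relationship``
    subject entity set, relationship, object entity set as an ordered
    triple;
``statement``
    the whole canonical rendering.

A statement matched at statement level necessarily matches at every
coarser level.  The two ``*_secondary`` variants are this package's
definition of the argument-free levels (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, Iterable, Mapping, Optional, Set, Tuple

from .model import ACTIVITY_FUNCTIONS, BelStatement, render
from .simplify import SimplifyConfig, simplify

__all__ = [
    "LEVELS",
    "AnnotationSet",
    "LevelScore",
    "EvalReport",
    "extract_units",
    "score",
    "score_as_iaa",
]

LEVELS = (
    "term",
    "function",
    "function_secondary",
    "relationship",
    "relationship_secondary",
    "statement",
)


@dataclass(frozen=True)
class AnnotationSet:
    """Statements grouped by sentence ID.  Duplicates within a sentence
    collapse (statements live in frozensets)."""

    items: Dict[str, FrozenSet[BelStatement]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, BelStatement]]) -> "AnnotationSet":
        acc: Dict[str, Set[BelStatement]] = {}
        for sid, stmt in pairs:
            acc.setdefault(sid, set()).add(stmt)
        return cls({sid: frozenset(stmts) for sid, stmts in acc.items()})

    @classmethod
    def from_records(cls, records) -> "AnnotationSet":
        """Build from corpus records (anything with .sentence_id and
        .statement attributes)."""
        return cls.from_pairs((r.sentence_id, r.statement) for r in records)

    def canonical(self, config: SimplifyConfig) -> "AnnotationSet":
        return AnnotationSet(
            {
                sid: frozenset(simplify(s, config) for s in stmts)
                for sid, stmts in self.items.items()
            }
        )


def _term_units(stmt: BelStatement) -> Set[Hashable]:
    return {str(e) for e in stmt.entities()}


#: functions scored at the function level: the activity family, the
#: translocation family, degradation and complex formation (process
#: functions bp/path and plain abundances carry no function credit)
_SCORED_FUNCTIONS = ACTIVITY_FUNCTIONS | {"tloc", "sec", "surf", "deg", "complex"}


def _function_units(stmt: BelStatement, secondary: bool) -> Set[Hashable]:
    units: Set[Hashable] = set()
    for top in stmt.terms():
        for term in top.walk():
            fn = term.function
            if fn in _SCORED_FUNCTIONS:
                if secondary:
                    units.add(fn)
                else:
                    ents = frozenset(str(e) for e in term.entities())
                    units.add((fn, ents))
            for mod in term.modifications:
                if mod.kind != "pmod":
                    continue
                if secondary:
                    units.add("pmod")
                else:
                    ents = frozenset(str(e) for e in term.entities())
                    units.add(("pmod", ents))
    return units


def _side_entities(node) -> FrozenSet[str]:
    return frozenset(str(e) for e in node.entities())


def _relationship_units(stmt: BelStatement, secondary: bool) -> Set[Hashable]:
    units: Set[Hashable] = set()
    subj = _side_entities(stmt.subject)
    obj = _side_entities(stmt.object)
    if secondary:
        units.add((stmt.relationship, frozenset((subj, obj))))
    else:
        units.add((subj, stmt.relationship, obj))
    if stmt.object_is_statement:
        # a nested statement contributes its inner relationship too
        units |= _relationship_units(stmt.object, secondary)
    return units


def extract_units(statement: BelStatement, level: str) -> Set[Hashable]:
    """Decompose a (canonicalized) statement into its unit keys at
    ``level``."""
    if level == "term":
        return _term_units(statement)
    if level == "function":
        return _function_units(statement, secondary=False)
    if level == "function_secondary":
        return _function_units(statement, secondary=True)
    if level == "relationship":
        return _relationship_units(statement, secondary=False)
    if level == "relationship_secondary":
        return _relationship_units(statement, secondary=True)
    if level == "statement":
        return {render(statement)}
    raise ValueError(f"unknown cascade level {level!r}")


@dataclass(frozen=True)
class LevelScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class EvalReport:
    """Micro-averaged counts and ratios per cascade level."""

    levels: Dict[str, LevelScore]

    def __getitem__(self, level: str) -> LevelScore:
        return self.levels[level]

    def as_rows(self):
        for level in LEVELS:
            s = self.levels[level]
            yield (level, s.tp, s.fp, s.fn, s.precision, s.recall, s.f)


def _sentence_units(
    stmts: Iterable[BelStatement], level: str
) -> Set[Hashable]:
    units: Set[Hashable] = set()
    for stmt in stmts:
        units |= extract_units(stmt, level)
    return units


def score(
    gold: AnnotationSet,
    predicted: AnnotationSet,
    config: Optional[SimplifyConfig] = None,
) -> EvalReport:
    """Compare predicted against gold statements sentence by sentence.

    Both sets are canonicalized under ``config`` (full track rules by
    default).  Sentences present in only one set contribute false
    positives or false negatives; duplicated predictions neither help
    nor hurt (units are sets).
    """
    config = config or SimplifyConfig.track()
    gold_c = gold.canonical(config)
    pred_c = predicted.canonical(config)
    sids = set(gold_c.items) | set(pred_c.items)
    counts = {level: [0, 0, 0] for level in LEVELS}
    for sid in sids:
        g_stmts = gold_c.items.get(sid, frozenset())
        p_stmts = pred_c.items.get(sid, frozenset())
        for level in LEVELS:
            g = _sentence_units(g_stmts, level)
            p = _sentence_units(p_stmts, level)
            c = counts[level]
            c[0] += len(g & p)
            c[1] += len(p - g)
            c[2] += len(g - p)
    return EvalReport(
        {level: LevelScore(*counts[level]) for level in LEVELS}
    )


def score_as_iaa(
    annotator_a: AnnotationSet,
    annotator_b: AnnotationSet,
    config: Optional[SimplifyConfig] = None,
) -> EvalReport:
    """Inter-annotator agreement via the cascade scorer: the first
    annotator is the gold standard, the second is treated as a
    prediction.  Swapping the annotators swaps precision and recall and
    leaves F unchanged."""
    return score(annotator_a, annotator_b, config)
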