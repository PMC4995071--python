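"""Abstract syntax for BEL 1.0 statements.

A BEL statement is a subject term, a causal relationship and an object
(term or one nested statement).  Terms wrap namespace-grounded entities
(``HGNC:IL6``) in abundance, activity, transformation or process
functions; protein abundances may carry modification terms
(phosphorylation, substitution, truncation, fusion).

All nodes are immutable and hashable so statements can live in sets and
be compared structurally after canonicalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

# --- function code tables -------------------------------------------------

ABUNDANCE_FUNCTIONS = frozenset({"a", "p", "g", "r", "m"})
COMPLEX_FUNCTIONS = frozenset({"complex", "composite"})
ACTIVITY_FUNCTIONS = frozenset(
    {"act", "cat", "chap", "gtp", "kin", "pep", "phos", "ribo", "tscript", "tport"}
)
TRANSFORMATION_FUNCTIONS = frozenset({"deg", "sec", "surf", "tloc"})
PROCESS_FUNCTIONS = frozenset({"bp", "path"})
REACTION_FUNCTION = "rxn"

TERM_FUNCTIONS = (
    ABUNDANCE_FUNCTIONS
    | COMPLEX_FUNCTIONS
    | ACTIVITY_FUNCTIONS
    | TRANSFORMATION_FUNCTIONS
    | PROCESS_FUNCTIONS
    | {REACTION_FUNCTION}
)

MODIFICATION_FUNCTIONS = frozenset({"pmod", "sub", "trunc", "fus"})

#: short form -> long form for every function usable in statements.
LONG_FORMS = {
    "a": "abundance",
    "p": "proteinAbundance",
    "complex": "complexAbundance",
    "composite": "compositeAbundance",
    "g": "geneAbundance",
    "m": "microRNAAbundance",
    "r": "rnaAbundance",
    "pmod": "proteinModification",
    "sub": "substitution",
    "trunc": "truncation",
    "fus": "fusion",
    "deg": "degradation",
    "sec": "cellSecretion",
    "surf": "cellSurfaceExpression",
    "tloc": "translocation",
    "rxn": "reaction",
    "act": "molecularActivity",
    "cat": "catalyticActivity",
    "chap": "chaperoneActivity",
    "gtp": "gtpBoundActivity",
    "kin": "kinaseActivity",
    "pep": "peptidaseActivity",
    "phos": "phosphataseActivity",
    "ribo": "ribosylationActivity",
    "tscript": "transcriptionalActivity",
    "tport": "transportActivity",
    "bp": "biologicalProcess",
    "path": "pathology",
}

#: every accepted spelling -> short code (long forms plus legacy aliases).
FUNCTION_ALIASES = {short: short for short in LONG_FORMS}
FUNCTION_ALIASES.update({long: short for short, long in LONG_FORMS.items()})
# spelling with a lower-case 'a' circulates in older corpora
FUNCTION_ALIASES["microRNAabundance"] = "m"

RELATIONSHIPS = ("increases", "decreases", "directlyIncreases", "directlyDecreases")
RELATIONSHIP_SYMBOLS = {
    "->": "increases",
    "=>": "directlyIncreases",
    "-|": "decreases",
    "=|": "directlyDecreases",
}

GENE_NAMESPACES = frozenset({"HGNC", "MGI", "RGD", "EGID"})

# --- quoting --------------------------------------------------------------

_BARE_NAME = re.compile(r"^[A-Za-z0-9_]+$")


def needs_quotes(name: str) -> bool:
    """A name must be quoted exactly when it contains a character outside
    ``[A-Za-z0-9_]`` (space, hyphen, comma, bracket, symbol...)."""
    return not _BARE_NAME.match(name)


def quote_name(name: str) -> str:
    if needs_quotes(name):
        return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return name


# --- AST nodes ------------------------------------------------------------


@dataclass(frozen=True, order=True)
class NamespaceEntity:
    """An entity grounded in a controlled vocabulary, e.g. ``HGNC:IL6`` or
    ``CHEBI:"leukotriene D4"``.  Namespaces are an open set of opaque codes;
    no dictionary lookup is performed."""

    namespace: str
    name: str

    def __str__(self) -> str:
        return f"{self.namespace}:{quote_name(self.name)}"


@dataclass(frozen=True)
class Modification:
    """A protein modification term attached to a ``p()`` abundance.

    ``pmod`` (post-translational modification: type code, optional residue,
    optional position), ``sub`` (amino-acid substitution), ``trunc``
    (truncation at a residue) or ``fus`` (fusion with a partner gene).
    """

    kind: str  # pmod | sub | trunc | fus
    pmod_type: Optional[str] = None
    residue: Optional[str] = None
    position: Optional[int] = None
    sub_ref: Optional[str] = None
    sub_alt: Optional[str] = None
    fus_partner: Optional[NamespaceEntity] = None
    fus_breakpoints: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in MODIFICATION_FUNCTIONS:
            raise ValueError(f"unknown modification kind {self.kind!r}")


@dataclass(frozen=True)
class BelTerm:
    """A BEL term: a function applied to an entity, to inner terms, or (for
    ``rxn``) to reactant and product lists.

    ``locations`` holds the optional from/to compartment entities of a
    ``tloc()``.  Member order of ``complex``/``composite`` is preserved here;
    order-insensitive comparison is the canonicalizer's job.
    """

    function: str
    entity: Optional[NamespaceEntity] = None
    inner_terms: Tuple["BelTerm", ...] = ()
    modifications: Tuple[Modification, ...] = ()
    locations: Tuple[NamespaceEntity, ...] = ()
    reactants: Tuple["BelTerm", ...] = ()
    products: Tuple["BelTerm", ...] = ()

    def __post_init__(self) -> None:
        if self.function not in TERM_FUNCTIONS:
            raise ValueError(f"unknown function code {self.function!r}")

    def walk(self):
        """Yield this term and every term nested below it."""
        yield self
        for sub in self.inner_terms + self.reactants + self.products:
            yield from sub.walk()

    def entities(self, include_locations: bool = False, include_fusion: bool = True):
        """Yield every namespace entity in the term, depth first."""
        for term in self.walk():
            if term.entity is not None:
                yield term.entity
            if include_fusion:
                for mod in term.modifications:
                    if mod.fus_partner is not None:
                        yield mod.fus_partner
            if include_locations:
                yield from term.locations


@dataclass(frozen=True)
class BelStatement:
    """Subject, relationship, object.  The object may itself be a statement
    (one level of nesting only; the validator enforces the bound)."""

    subject: BelTerm
    relationship: str
    object: Union[BelTerm, "BelStatement"]

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship {self.relationship!r}")

    @property
    def object_is_statement(self) -> bool:
        return isinstance(self.object, BelStatement)

    def terms(self):
        """Yield the subject term and the (possibly nested) object terms."""
        yield self.subject
        if self.object_is_statement:
            yield from self.object.terms()
        else:
            yield self.object

    def entities(self, include_locations: bool = False):
        for term in self.terms():
            yield from term.entities(include_locations=include_locations)


# --- rendering ------------------------------------------------------------


def _fn(code: str, style: str) -> str:
    return LONG_FORMS[code] if style == "long" else code


def _render_modification(mod: Modification, style: str) -> str:
    if mod.kind == "pmod":
        args = [mod.pmod_type]
        if mod.residue is not None:
            args.append(mod.residue)
        if mod.position is not None:
            args.append(str(mod.position))
    elif mod.kind == "sub":
        args = [mod.sub_ref, str(mod.position), mod.sub_alt]
    elif mod.kind == "trunc":
        args = [str(mod.position)]
    else:  # fus
        args = [str(mod.fus_partner)]
        if mod.fus_breakpoints is not None:
            args += [str(b) for b in mod.fus_breakpoints]
    return f"{_fn(mod.kind, style)}({', '.join(args)})"


def render_term(term: BelTerm, style: str = "short") -> str:
    args = []
    if term.function == REACTION_FUNCTION:
        inner = ", ".join(render_term(t, style) for t in term.reactants)
        args.append(f"reactants({inner})")
        inner = ", ".join(render_term(t, style) for t in term.products)
        args.append(f"products({inner})")
    else:
        if term.entity is not None:
            args.append(str(term.entity))
        args.extend(render_term(t, style) for t in term.inner_terms)
        args.extend(_render_modification(m, style) for m in term.modifications)
        args.extend(str(loc) for loc in term.locations)
    return f"{_fn(term.function, style)}({', '.join(args)})"


def render_statement(stmt: BelStatement, style: str = "short") -> str:
    obj = (
        f"({render_statement(stmt.object, style)})"
        if stmt.object_is_statement
        else render_term(stmt.object, style)
    )
    return f"{render_term(stmt.subject, style)} {stmt.relationship} {obj}"


def render(node: Union[BelTerm, BelStatement], style: str = "short") -> str:
    """Deterministic canonical text for a term or statement.

    Long-form relationship names are always used; function codes follow
    ``style``.  Names are double-quoted exactly when they contain special
    characters, so ``parse(render(x)) == x`` for every valid node.
    """
    if style not in ("short", "long"):
        raise ValueError("style must be 'short' or 'long'")
    if isinstance(node, BelStatement):
        return render_statement(node, style)
    return render_term(node, style)
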