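"""Structural and namespace-compatibility validation of BEL ASTs.

Violations are data, not exceptions: each one names the rule that failed
and renders the offending subterm, so batch tools can collect them.

Compatibility rules mirror the corpus annotation conventions:

* chemical entities (ChEBI) appear only under ``a()``;
* disease entities (MESHD) only under ``path()``;
* biological-process entities (GOBP) only under ``bp()``;
* gene-namespace entities (HGNC, MGI, EGID, RGD) only under
  ``g()``/``r()``/``m()``/``p()``, and microRNA names (recognized here by
  the MIR name prefix — a heuristic, since namespaces are opaque) are
  additionally barred from ``p()``.

``tloc()`` location arguments (GOCC/MESHCL compartments) are exempt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Union

from .model import (
    ABUNDANCE_FUNCTIONS,
    ACTIVITY_FUNCTIONS,
    BelStatement,
    BelTerm,
    GENE_NAMESPACES,
    render,
)

__all__ = ["Violation", "validate", "is_valid"]


@dataclass(frozen=True)
class Violation:
    rule: str
    message: str
    where: str  # canonical rendering of the offending node

    def __str__(self) -> str:
        return f"[{self.rule}] {self.message}: {self.where}"


_MEMBER_FUNCTIONS = ABUNDANCE_FUNCTIONS | {"complex"}


def _is_microrna_name(name: str) -> bool:
    return name.upper().startswith("MIR")


def _check_modifications(term: BelTerm, out: List[Violation]) -> None:
    where = render(term)
    if term.modifications and term.function != "p":
        out.append(
            Violation("modification-carrier", "only p() may carry modifications", where)
        )
    for mod in term.modifications:
        if mod.kind == "pmod":
            if not mod.pmod_type:
                out.append(Violation("pmod-arity", "pmod requires a type code", where))
            if mod.position is not None and mod.residue is None:
                out.append(
                    Violation("pmod-arity", "pmod position requires a residue", where)
                )
        elif mod.kind == "sub":
            if not (mod.sub_ref and mod.sub_alt and mod.position is not None):
                out.append(
                    Violation("sub-arity", "sub requires ref, position and alt", where)
                )
        elif mod.kind == "trunc":
            if mod.position is None:
                out.append(Violation("trunc-arity", "trunc requires a position", where))
        elif mod.kind == "fus":
            if mod.fus_partner is None:
                out.append(Violation("fus-arity", "fus requires a partner entity", where))


def _check_entity_context(term: BelTerm, out: List[Violation]) -> None:
    ent = term.entity
    if ent is None:
        return
    where = render(term)
    ns = ent.namespace.upper()
    fn = term.function
    if not ent.name:
        out.append(Violation("entity-name", "entity name is empty", where))
    if ns == "CHEBI" and fn != "a":
        out.append(Violation("namespace-function", "CHEBI only under a()", where))
    elif ns == "MESHD" and fn != "path":
        out.append(Violation("namespace-function", "MESHD only under path()", where))
    elif ns == "GOBP" and fn != "bp":
        out.append(Violation("namespace-function", "GOBP only under bp()", where))
    elif ent.namespace in GENE_NAMESPACES:
        if fn not in ("g", "r", "m", "p"):
            out.append(
                Violation(
                    "namespace-function",
                    f"{ent.namespace} only under g()/r()/m()/p()",
                    where,
                )
            )
        elif fn == "p" and _is_microrna_name(ent.name):
            out.append(
                Violation(
                    "namespace-function",
                    "microRNA entities are valid under g()/m()/r() but not p()",
                    where,
                )
            )


def _check_term(term: BelTerm, out: List[Violation], top_level: bool) -> None:
    where = render(term)
    fn = term.function
    n_inner = len(term.inner_terms)

    if fn in ABUNDANCE_FUNCTIONS:
        if term.entity is None or n_inner:
            out.append(
                Violation("arity", f"{fn}() carries exactly one entity", where)
            )
        if term.locations:
            out.append(Violation("arity", f"{fn}() takes no location arguments", where))
    elif fn == "complex":
        named = term.entity is not None
        if named and n_inner:
            out.append(
                Violation("arity", "complex() is either named or compositional", where)
            )
        elif not named and n_inner < 2:
            out.append(Violation("arity", "complex() requires >=2 member terms", where))
        bad = [t for t in term.inner_terms if t.function not in _MEMBER_FUNCTIONS]
        if bad:
            out.append(
                Violation("arity", "complex() members must be abundance terms", where)
            )
    elif fn == "composite":
        if term.entity is not None or n_inner < 2:
            out.append(
                Violation("arity", "composite() requires >=2 member abundance terms", where)
            )
        if not top_level:
            out.append(
                Violation("nesting", "composite() may appear only at term top level", where)
            )
        bad = [t for t in term.inner_terms if t.function not in ABUNDANCE_FUNCTIONS]
        if bad:
            out.append(
                Violation("arity", "composite() members must be abundance terms", where)
            )
    elif fn in ACTIVITY_FUNCTIONS:
        ok = (
            term.entity is None
            and n_inner == 1
            and term.inner_terms[0].function in _MEMBER_FUNCTIONS
        )
        if not ok:
            out.append(
                Violation(
                    "arity", f"{fn}() carries exactly one abundance/complex term", where
                )
            )
    elif fn in ("deg", "sec", "surf", "tloc"):
        ok = (
            term.entity is None
            and n_inner == 1
            and term.inner_terms[0].function in _MEMBER_FUNCTIONS
        )
        if not ok:
            out.append(
                Violation("arity", f"{fn}() carries exactly one abundance term", where)
            )
        if fn == "tloc":
            if len(term.locations) not in (0, 2):
                out.append(
                    Violation("arity", "tloc() takes zero or two location entities", where)
                )
        elif term.locations:
            out.append(Violation("arity", f"{fn}() takes no location arguments", where))
    elif fn == "rxn":
        if not term.reactants or not term.products:
            out.append(
                Violation("arity", "rxn() requires reactants and products", where)
            )
        if term.entity is not None or n_inner:
            out.append(Violation("arity", "rxn() takes only reactant/product lists", where))

    _check_modifications(term, out)
    _check_entity_context(term, out)

    for sub in term.inner_terms + term.reactants + term.products:
        _check_term(sub, out, top_level=False)


def _check_statement(stmt: BelStatement, out: List[Violation], depth: int) -> None:
    _check_term(stmt.subject, out, top_level=True)
    if stmt.object_is_statement:
        if depth >= 1:
            out.append(
                Violation(
                    "nesting",
                    "nested statements may not contain nested statements",
                    render(stmt),
                )
            )
        _check_statement(stmt.object, out, depth + 1)
    else:
        _check_term(stmt.object, out, top_level=True)


def validate(
    node: Union[BelTerm, BelStatement],
    allowed_namespaces: Optional[Iterable[str]] = None,
) -> List[Violation]:
    """Return every rule violation in ``node`` (empty list = valid).

    ``allowed_namespaces``, when given, additionally flags subject/object
    entities grounded outside the listed namespaces (tloc locations are
    exempt); by default the namespace set is open.
    """
    out: List[Violation] = []
    if isinstance(node, BelStatement):
        _check_statement(node, out, depth=0)
        entity_source = node.entities()
    else:
        _check_term(node, out, top_level=True)
        entity_source = node.entities()
    if allowed_namespaces is not None:
        allowed = set(allowed_namespaces)
        for ent in entity_source:
            if ent.namespace not in allowed:
                out.append(
                    Violation(
                        "namespace-restriction",
                        f"namespace {ent.namespace} is not in the configured set",
                        str(ent),
                    )
                )
    return out


def is_valid(node: Union[BelTerm, BelStatement]) -> bool:
    return not validate(node)
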