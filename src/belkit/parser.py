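"""Tokenizer and recursive-descent parser for BEL 1.0 terms and statements.

Short and long function spellings parse to identical ASTs; relationship
arrows (``->``, ``=>``, ``-|``, ``=|``) normalize to their long names.
Both single and double quotation characters delimit names, Unicode curly
quotes and non-breaking spaces are normalized to ASCII first, and
whitespace between tokens is insignificant.

Structural problems (unbalanced parentheses, unknown function codes,
unquoted special characters) raise :class:`BelSyntaxError` with a
position; arity and namespace-compatibility problems are left to
:mod:`belkit.validate`, which reports them as data.
"""

from __future__ import annotations

import re
from typing import List, NamedTuple, Optional, Tuple, Union

from .model import (
    BelStatement,
    BelTerm,
    FUNCTION_ALIASES,
    MODIFICATION_FUNCTIONS,
    Modification,
    NamespaceEntity,
    RELATIONSHIPS,
    RELATIONSHIP_SYMBOLS,
)

__all__ = ["BelSyntaxError", "parse_term", "parse_statement", "parse"]


class BelSyntaxError(ValueError):
    """Syntax error with the offending position in the input string."""

    def __init__(self, message: str, position: int, text: str = ""):
        super().__init__(f"{message} (at position {position})")
        self.message = message
        self.position = position
        self.text = text


_UNICODE_MAP = str.maketrans(
    {
        "“": '"',
        "”": '"',
        "„": '"',
        "‘": "'",
        "’": "'",
        "‚": "'",
        " ": " ",
        "–": "-",
        "—": "-",
    }
)


def _normalize(text: str) -> str:
    return text.translate(_UNICODE_MAP)


class Token(NamedTuple):
    kind: str  # IDENT | QUOTED | PUNCT | ARROW
    value: str
    pos: int


_IDENT = re.compile(r"[A-Za-z0-9_]+")


def _tokenize(text: str) -> List[Token]:
    tokens: List[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "():,":
            tokens.append(Token("PUNCT", ch, i))
            i += 1
            continue
        if ch in "-=":
            # relationship arrows; whitespace may intrude (" = > " occurs
            # in the wild)
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j < n and text[j] in ">|":
                arrow = ch + text[j]
                tokens.append(Token("ARROW", RELATIONSHIP_SYMBOLS[arrow], i))
                i = j + 1
                continue
            raise BelSyntaxError(f"unexpected character {ch!r}", i, text)
        if ch in "\"'":
            j = i + 1
            chars: List[str] = []
            while j < n and text[j] != ch:
                if text[j] == "\\" and j + 1 < n:
                    chars.append(text[j + 1])
                    j += 2
                else:
                    chars.append(text[j])
                    j += 1
            if j >= n:
                raise BelSyntaxError("unterminated quoted name", i, text)
            tokens.append(Token("QUOTED", "".join(chars), i))
            i = j + 1
            continue
        m = _IDENT.match(text, i)
        if m:
            tokens.append(Token("IDENT", m.group(), i))
            i = m.end()
            continue
        raise BelSyntaxError(f"unexpected character {ch!r}", i, text)
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = _normalize(text)
        self.tokens = _tokenize(self.text)
        self.i = 0

    # -- token helpers ----------------------------------------------------

    def _peek(self, offset: int = 0) -> Optional[Token]:
        j = self.i + offset
        return self.tokens[j] if j < len(self.tokens) else None

    def _next(self) -> Token:
        tok = self._peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input", len(self.text), self.text)
        self.i += 1
        return tok

    def _expect(self, value: str) -> Token:
        tok = self._next()
        if tok.kind != "PUNCT" or tok.value != value:
            raise BelSyntaxError(f"expected {value!r}, found {tok.value!r}", tok.pos, self.text)
        return tok

    def _at_punct(self, value: str) -> bool:
        tok = self._peek()
        return tok is not None and tok.kind == "PUNCT" and tok.value == value

    # -- grammar ----------------------------------------------------------

    def parse_statement(self) -> BelStatement:
        stmt = self._statement()
        self._end()
        return stmt

    def parse_term(self) -> BelTerm:
        term = self._term()
        self._end()
        return term

    def _end(self) -> None:
        tok = self._peek()
        if tok is not None:
            msg = "unexpected trailing input"
            if tok.kind == "ARROW" or (tok.kind == "IDENT" and tok.value in RELATIONSHIPS):
                msg = "more than one top-level relationship"
            raise BelSyntaxError(msg, tok.pos, self.text)

    def _statement(self) -> BelStatement:
        subject = self._term()
        tok = self._next()
        if tok.kind == "ARROW":
            relationship = tok.value
        elif tok.kind == "IDENT" and tok.value in RELATIONSHIPS:
            relationship = tok.value
        else:
            raise BelSyntaxError(
                f"expected a relationship, found {tok.value!r}", tok.pos, self.text
            )
        obj: Union[BelTerm, BelStatement]
        if self._at_punct("("):
            # nested statement as object
            self._expect("(")
            obj = self._statement()
            self._expect(")")
        else:
            obj = self._term()
        return BelStatement(subject, relationship, obj)

    def _function_code(self) -> Tuple[str, int]:
        tok = self._next()
        if tok.kind != "IDENT":
            raise BelSyntaxError(f"expected a function code, found {tok.value!r}", tok.pos, self.text)
        code = FUNCTION_ALIASES.get(tok.value)
        if code is None:
            raise BelSyntaxError(f"unknown function code {tok.value!r}", tok.pos, self.text)
        return code, tok.pos

    def _term(self) -> BelTerm:
        code, pos = self._function_code()
        if code in MODIFICATION_FUNCTIONS:
            raise BelSyntaxError(
                f"modification function {code!r} cannot stand alone", pos, self.text
            )
        if code == "rxn":
            return self._reaction()
        self._expect("(")
        entity: Optional[NamespaceEntity] = None
        inner: List[BelTerm] = []
        mods: List[Modification] = []
        locations: List[NamespaceEntity] = []
        first = True
        while not self._at_punct(")"):
            if not first:
                self._expect(",")
            first = False
            kind, value = self._argument(code)
            if kind == "entity":
                if entity is None and not inner and not locations:
                    entity = value
                else:
                    locations.append(value)
            elif kind == "term":
                inner.append(value)
            else:
                mods.append(value)
        self._expect(")")
        return BelTerm(
            function=code,
            entity=entity,
            inner_terms=tuple(inner),
            modifications=tuple(mods),
            locations=tuple(locations),
        )

    def _argument(self, context: str):
        """One argument of a term: a nested term, a modification, or an
        entity.  Disambiguated by one token of lookahead."""
        tok = self._peek()
        if tok is None:
            raise BelSyntaxError("unexpected end of input", len(self.text), self.text)
        nxt = self._peek(1)
        if tok.kind == "IDENT" and nxt is not None and nxt.kind == "PUNCT" and nxt.value == "(":
            code = FUNCTION_ALIASES.get(tok.value)
            if code in MODIFICATION_FUNCTIONS:
                return "mod", self._modification()
            return "term", self._term()
        return "entity", self._entity()

    def _entity(self) -> NamespaceEntity:
        tok = self._next()
        if tok.kind != "IDENT":
            raise BelSyntaxError(f"expected a namespace code, found {tok.value!r}", tok.pos, self.text)
        namespace = tok.value
        colon = self._next()
        if colon.kind != "PUNCT" or colon.value != ":":
            raise BelSyntaxError("expected ':' after namespace code", colon.pos, self.text)
        name_tok = self._next()
        if name_tok.kind not in ("IDENT", "QUOTED"):
            raise BelSyntaxError("expected an entity name", name_tok.pos, self.text)
        if name_tok.kind == "QUOTED" and not name_tok.value:
            raise BelSyntaxError("empty entity name", name_tok.pos, self.text)
        return NamespaceEntity(namespace, name_tok.value)

    def _int(self, tok: Token) -> int:
        if tok.kind != "IDENT" or not tok.value.isdigit():
            raise BelSyntaxError(f"expected an integer, found {tok.value!r}", tok.pos, self.text)
        return int(tok.value)

    def _modification(self) -> Modification:
        code, pos = self._function_code()
        self._expect("(")
        if code == "pmod":
            tok = self._next()
            if tok.kind != "IDENT":
                raise BelSyntaxError("expected a modification type code", tok.pos, self.text)
            pmod_type = tok.value
            residue = None
            position = None
            if self._at_punct(","):
                self._expect(",")
                tok = self._next()
                if tok.value.isdigit():
                    # positional dialect pmod(P, 202) is not accepted:
                    # position requires a residue
                    raise BelSyntaxError(
                        "pmod position requires a residue code", tok.pos, self.text
                    )
                residue = tok.value
                if self._at_punct(","):
                    self._expect(",")
                    position = self._int(self._next())
            mod = Modification("pmod", pmod_type=pmod_type, residue=residue, position=position)
        elif code == "sub":
            ref = self._next().value
            self._expect(",")
            position = self._int(self._next())
            self._expect(",")
            alt = self._next().value
            mod = Modification("sub", sub_ref=ref, sub_alt=alt, position=position)
        elif code == "trunc":
            position = self._int(self._next())
            mod = Modification("trunc", position=position)
        else:  # fus
            partner = self._entity()
            breakpoints = None
            if self._at_punct(","):
                self._expect(",")
                b1 = self._int(self._next())
                self._expect(",")
                b2 = self._int(self._next())
                breakpoints = (b1, b2)
            mod = Modification("fus", fus_partner=partner, fus_breakpoints=breakpoints)
        self._expect(")")
        return mod

    def _reaction(self) -> BelTerm:
        self._expect("(")
        reactants = self._reaction_side("reactants")
        self._expect(",")
        products = self._reaction_side("products")
        self._expect(")")
        return BelTerm(function="rxn", reactants=reactants, products=products)

    def _reaction_side(self, keyword: str) -> Tuple[BelTerm, ...]:
        tok = self._next()
        if tok.kind != "IDENT" or tok.value != keyword:
            raise BelSyntaxError(f"expected {keyword!r}", tok.pos, self.text)
        self._expect("(")
        terms: List[BelTerm] = []
        first = True
        while not self._at_punct(")"):
            if not first:
                self._expect(",")
            first = False
            terms.append(self._term())
        self._expect(")")
        return tuple(terms)


def parse_term(text: str) -> BelTerm:
    """Parse a single BEL term expression into its AST."""
    return _Parser(text).parse_term()


def parse_statement(text: str) -> BelStatement:
    """Parse a BEL statement (subject, relationship, object)."""
    return _Parser(text).parse_statement()


def parse(text: str) -> Union[BelTerm, BelStatement]:
    """Parse a statement if the text contains a relationship, else a term."""
    p = _Parser(text)
    if any(
        t.kind == "ARROW" or (t.kind == "IDENT" and t.value in RELATIONSHIPS)
        for t in p.tokens
    ):
        return p.parse_statement()
    return p.parse_term()
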