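"""Text format for reagent-centric models.

The grammar follows the conventions of the reagent-centric process-algebra
style: semicolon-terminated definitions, species behaviour terms written
``(reaction, coeff) op`` with ``op`` one of ``>>`` (product), ``<<``
(reactant), ``(+)`` (activator), ``(-)`` (inhibitor), and a single
composition line giving initial molecule counts::

    // parameters
    l1 = 0.01;  l2 = 100;  l3 = 1;

    // kinetic laws (fMA = mass action; explicit arithmetic also allowed)
    kineticLawOf r_l1 : fMA(l1);
    kineticLawOf r_l2 : l2 * pB;

    // species behaviours
    B  = (r_l1, 1) << + (r_l2, 1) >>;
    p  = (r_l1, 1) << + (r_l2, 1) >>;
    pB = (r_l1, 1) >> + (r_l2, 1) <<;

    // environment-held species (optional)
    constant A;

    // composition
    B[100] <*> p[100] <*> pB[0]

``(reaction) op`` abbreviates stoichiometry 1. ``//`` starts a line comment.
Parse errors carry line and column; structural problems (missing law,
missing initial count, undeclared identifier) are reported by model
validation with the offending name.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import expressions as ex
from .model import (
    KineticLaw,
    Model,
    ModelError,
    Role,
    SpeciesBehaviour,
    canonicalise_mass_action,
    recognise_mass_action,
)


class ParseError(ValueError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


@dataclass(frozen=True)
class _Token:
    kind: str  # IDENT NUMBER OP EOF
    text: str
    line: int
    column: int


_MULTI_OPS = ("<*>", "<<", ">>")
_SINGLE_OPS = "=;:,()[]+-*/"


class _Tokenizer:
    def __init__(self, text: str, line: int = 1, column: int = 1):
        self.text = text
        self.line = line
        self.column = column

    def tokens(self) -> list[_Token]:
        out: list[_Token] = []
        text, i, n = self.text, 0, len(self.text)
        line, col = self.line, self.column
        while i < n:
            c = text[i]
            if c == "\n":
                i += 1
                line += 1
                col = 1
                continue
            if c in " \t\r":
                i += 1
                col += 1
                continue
            if text.startswith("//", i):
                while i < n and text[i] != "\n":
                    i += 1
                continue
            matched = next((op for op in _MULTI_OPS if text.startswith(op, i)), None)
            if matched:
                out.append(_Token("OP", matched, line, col))
                i += len(matched)
                col += len(matched)
                continue
            if c.isalpha() or c == "_":
                j = i
                while j < n and (text[j].isalnum() or text[j] == "_"):
                    j += 1
                out.append(_Token("IDENT", text[i:j], line, col))
                col += j - i
                i = j
                continue
            if c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()):
                j = i
                while j < n and (text[j].isdigit() or text[j] == "."):
                    j += 1
                if j < n and text[j] in "eE":
                    k = j + 1
                    if k < n and text[k] in "+-":
                        k += 1
                    if k < n and text[k].isdigit():
                        j = k
                        while j < n and text[j].isdigit():
                            j += 1
                out.append(_Token("NUMBER", text[i:j], line, col))
                col += j - i
                i = j
                continue
            if c in _SINGLE_OPS:
                out.append(_Token("OP", c, line, col))
                i += 1
                col += 1
                continue
            raise ParseError(f"unexpected character {c!r}", line, col)
        out.append(_Token("EOF", "", line, col))
        return out


# -- expression parsing over a token stream ---------------------------------


def _parse_expr_tokens(tokens: list[_Token], pos: int) -> tuple[ex.Expr, int]:
    return _parse_sum(tokens, pos)


def _parse_sum(tokens, pos):
    left, pos = _parse_term(tokens, pos)
    while tokens[pos].kind == "OP" and tokens[pos].text in "+-":
        op = tokens[pos].text
        right, pos = _parse_term(tokens, pos + 1)
        left = ex.BinOp(op, left, right)
    return left, pos


def _parse_term(tokens, pos):
    left, pos = _parse_atom(tokens, pos)
    while tokens[pos].kind == "OP" and tokens[pos].text in "*/":
        op = tokens[pos].text
        right, pos = _parse_atom(tokens, pos + 1)
        left = ex.BinOp(op, left, right)
    return left, pos


def _parse_atom(tokens, pos):
    tok = tokens[pos]
    if tok.kind == "NUMBER":
        return ex.Num(float(tok.text)), pos + 1
    if tok.kind == "IDENT":
        return ex.Sym(tok.text), pos + 1
    if tok.kind == "OP" and tok.text == "(":
        expr, pos = _parse_sum(tokens, pos + 1)
        closing = tokens[pos]
        if not (closing.kind == "OP" and closing.text == ")"):
            raise ParseError("expected ')'", closing.line, closing.column)
        return expr, pos + 1
    if tok.kind == "OP" and tok.text == "-":
        inner, pos = _parse_atom(tokens, pos + 1)
        return ex.BinOp("-", ex.Num(0.0), inner), pos
    raise ParseError(f"expected expression, found {tok.text or 'end of input'!r}", tok.line, tok.column)


# -- statement parsing -------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.tokens = _Tokenizer(text).tokens()
        self.pos = 0
        self.parameters: dict[str, float] = {}
        self.laws: list[KineticLaw] = []
        self.behaviours: list[SpeciesBehaviour] = []
        self.initial_counts: dict[str, float] | None = None
        self.constant_species: set[str] = set()

    # token helpers
    def peek(self, ahead: int = 0) -> _Token:
        return self.tokens[min(self.pos + ahead, len(self.tokens) - 1)]

    def next(self) -> _Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise ParseError(
                f"expected {text!r}, found {tok.text or 'end of input'!r}", tok.line, tok.column
            )
        return tok

    def expect_ident(self, what: str = "identifier") -> _Token:
        tok = self.next()
        if tok.kind != "IDENT":
            raise ParseError(
                f"expected {what}, found {tok.text or 'end of input'!r}", tok.line, tok.column
            )
        return tok

    # grammar
    def parse(self) -> Model:
        while self.peek().kind != "EOF":
            self.statement()
        if self.initial_counts is None:
            tok = self.peek()
            raise ParseError("model has no composition line (species[count] <*> ...)", tok.line, tok.column)
        try:
            model = Model(
                self.parameters,
                self.behaviours,
                self.laws,
                self.initial_counts,
                self.constant_species,
            )
        except ModelError:
            raise
        return canonicalise_mass_action(model)

    def statement(self) -> None:
        tok = self.peek()
        if tok.kind != "IDENT":
            raise ParseError(
                f"expected definition, found {tok.text or 'end of input'!r}", tok.line, tok.column
            )
        if tok.text == "kineticLawOf":
            self.kinetic_law()
        elif tok.text == "constant":
            self.constant_decl()
        elif self.peek(1).text == "=":
            self.definition()
        elif self.peek(1).text == "[":
            self.composition()
        else:
            nxt = self.peek(1)
            raise ParseError(
                f"expected '=' or '[' after {tok.text!r}, found {nxt.text or 'end of input'!r}",
                nxt.line,
                nxt.column,
            )

    def kinetic_law(self) -> None:
        self.next()  # kineticLawOf
        reaction = self.expect_ident("reaction name").text
        self.expect(":")
        if self.peek().text == "fMA" and self.peek(1).text == "(":
            self.next()
            self.next()
            const = self.expect_ident("rate-constant name").text
            self.expect(")")
            law = KineticLaw(reaction, ex.Sym(const), mass_action_constant=const)
        else:
            expr, self.pos = _parse_expr_tokens(self.tokens, self.pos)
            law = KineticLaw(reaction, expr)
        self.expect(";")
        if any(l.reaction == reaction for l in self.laws):
            raise ModelError(f"duplicate kinetic law for reaction: {reaction}")
        self.laws.append(law)

    def constant_decl(self) -> None:
        self.next()  # constant
        self.constant_species.add(self.expect_ident("species name").text)
        while self.peek().text == ",":
            self.next()
            self.constant_species.add(self.expect_ident("species name").text)
        self.expect(";")

    def definition(self) -> None:
        name = self.next().text
        self.expect("=")
        saved = self.pos
        try:
            terms = self.behaviour_terms()
        except ParseError:
            self.pos = saved
            terms = None
        if terms is not None:
            self.expect(";")
            if any(b.name == name for b in self.behaviours):
                raise ModelError(f"duplicate species declaration: {name}")
            self.behaviours.append(SpeciesBehaviour(name, terms))
            return
        # parameter assignment: constant arithmetic over earlier parameters
        expr, self.pos = _parse_expr_tokens(self.tokens, self.pos)
        tok = self.expect(";")
        try:
            value = ex.evaluate(expr, self.parameters)
        except KeyError as err:
            raise ParseError(str(err.args[0]), tok.line, tok.column) from None
        self.parameters[name] = value

    def behaviour_terms(self) -> list[tuple]:
        terms = [self.behaviour_term()]
        while self.peek().text == "+" and self.peek(1).text == "(":
            self.next()
            terms.append(self.behaviour_term())
        return terms

    def behaviour_term(self) -> tuple:
        self.expect("(")
        reaction = self.expect_ident("reaction name").text
        coeff = 1
        if self.peek().text == ",":
            self.next()
            tok = self.next()
            if tok.kind != "NUMBER" or not float(tok.text).is_integer():
                raise ParseError(
                    f"expected integer stoichiometry, found {tok.text!r}", tok.line, tok.column
                )
            coeff = int(float(tok.text))
        self.expect(")")
        tok = self.next()
        if tok.text in ("<<", ">>"):
            role = Role.from_symbol(tok.text)
        elif tok.text == "(" and self.peek().text in ("+", "-") and self.peek(1).text == ")":
            role = Role.ACTIVATOR if self.next().text == "+" else Role.INHIBITOR
            self.next()  # )
        else:
            raise ParseError(
                f"expected role operator (>>, <<, (+) or (-)), found {tok.text!r}",
                tok.line,
                tok.column,
            )
        return (reaction, coeff, role)

    def composition(self) -> None:
        if self.initial_counts is not None:
            tok = self.peek()
            raise ParseError("duplicate composition line", tok.line, tok.column)
        counts: dict[str, float] = {}
        while True:
            name = self.expect_ident("species name").text
            self.expect("[")
            tok = self.next()
            if tok.kind != "NUMBER":
                raise ParseError(f"expected initial count, found {tok.text!r}", tok.line, tok.column)
            if name in counts:
                raise ParseError(f"species {name!r} composed twice", tok.line, tok.column)
            counts[name] = float(tok.text)
            self.expect("]")
            if self.peek().text != "<*>":
                break
            self.next()
        if self.peek().text == ";":
            self.next()
        self.initial_counts = counts


def parse_model(text: str) -> Model:
    """Parse model source text into a validated model."""
    return _Parser(text).parse()


def load_model(path) -> Model:
    """Parse a model file (UTF-8; conventionally ``.biopepa``)."""
    with open(path, encoding="utf-8") as fh:
        return parse_model(fh.read())


def _format_number(value: float) -> str:
    return repr(int(value)) if float(value).is_integer() and abs(value) < 1e15 else repr(value)


def pretty_print(model: Model) -> str:
    """Render a model in the canonical text form; reparses to an equal model."""
    lines: list[str] = []
    if model.parameters:
        lines.append("// parameters")
        for name, value in model.parameters.items():
            lines.append(f"{name} = {_format_number(value)};")
        lines.append("")
    lines.append("// kinetic laws")
    for law in model.laws:
        const = recognise_mass_action(model, law)
        if const is not None:
            lines.append(f"kineticLawOf {law.reaction} : fMA({const});")
        else:
            lines.append(f"kineticLawOf {law.reaction} : {ex.to_text(law.expression)};")
    lines.append("")
    lines.append("// species behaviours")
    for b in model.behaviours:
        terms = " + ".join(f"({t.reaction}, {t.coeff}) {t.role.value}" for t in b.terms)
        lines.append(f"{b.name} = {terms};")
    if model.constant_species:
        lines.append("")
        names = ", ".join(s for s in model.species if s in model.constant_species)
        lines.append(f"constant {names};")
    lines.append("")
    lines.append("// composition")
    lines.append(
        " <*> ".join(f"{s}[{_format_number(model.initial_counts[s])}]" for s in model.species)
    )
    lines.append("")
    return "\n".join(lines)
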