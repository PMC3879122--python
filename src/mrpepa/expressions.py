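"""Small arithmetic expressions for kinetic laws.

A kinetic law is an arithmetic expression over parameter names and species
names: numbers, identifiers, ``+ - * /`` and parentheses. Mass-action laws
are usually written with the ``fMA(c)`` functional-rate shorthand, which the
model layer expands to ``c * reactant1 * reactant2 * ...``; explicit product
expressions of that shape are recognised back into mass-action form so that
operations that need the rate constant (e.g. volume scaling) work on parsed
models too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Union

Expr = Union["Num", "Sym", "BinOp"]


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * /
    left: Expr
    right: Expr


def evaluate(expr: Expr, env: Mapping[str, float]) -> float:
    """Evaluate ``expr`` with identifier values taken from ``env``."""
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Sym):
        try:
            return env[expr.name]
        except KeyError:
            raise KeyError(f"undefined identifier {expr.name!r} in expression") from None
    a = evaluate(expr.left, env)
    b = evaluate(expr.right, env)
    if expr.op == "+":
        return a + b
    if expr.op == "-":
        return a - b
    if expr.op == "*":
        return a * b
    if expr.op == "/":
        return a / b
    raise ValueError(f"unknown operator {expr.op!r}")


def identifiers(expr: Expr) -> Iterator[str]:
    """Yield every identifier occurring in ``expr`` (with repeats)."""
    if isinstance(expr, Sym):
        yield expr.name
    elif isinstance(expr, BinOp):
        yield from identifiers(expr.left)
        yield from identifiers(expr.right)


_PREC = {"+": 1, "-": 1, "*": 2, "/": 2}


def to_text(expr: Expr, _parent_prec: int = 0) -> str:
    """Render an expression with minimal parentheses."""
    if isinstance(expr, Num):
        v = expr.value
        return repr(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)
    if isinstance(expr, Sym):
        return expr.name
    prec = _PREC[expr.op]
    left = to_text(expr.left, prec)
    # right operand of - and / needs parens at equal precedence
    right = to_text(expr.right, prec + (1 if expr.op in "-/" else 0))
    s = f"{left} {expr.op} {right}"
    return f"({s})" if prec < _parent_prec else s


def product_factors(expr: Expr) -> list[Expr] | None:
    """Flatten a pure product into its factors; None if not a pure product."""
    if isinstance(expr, (Num, Sym)):
        return [expr]
    if isinstance(expr, BinOp) and expr.op == "*":
        left = product_factors(expr.left)
        right = product_factors(expr.right)
        if left is not None and right is not None:
            return left + right
    return None


def build_product(factors: list[Expr]) -> Expr:
    """Left-associated product of ``factors`` (Num(1) for an empty list)."""
    if not factors:
        return Num(1.0)
    out = factors[0]
    for f in factors[1:]:
        out = BinOp("*", out, f)
    return out


# ---------------------------------------------------------------------------
# expression parsing (shared by the model-file grammar)


class ExprSyntaxError(ValueError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


def parse_expression(text: str, line: int = 1, column: int = 1) -> Expr:
    """Parse an arithmetic expression; ``line``/``column`` seed error locations."""
    from .parser import _Tokenizer, _parse_expr_tokens  # local import, no cycle at call time

    tokens = _Tokenizer(text, line=line, column=column).tokens()
    expr, pos = _parse_expr_tokens(tokens, 0)
    if pos != len(tokens) - 1:  # last token is EOF
        tok = tokens[pos]
        raise ExprSyntaxError(f"unexpected {tok.text!r} after expression", tok.line, tok.column)
    return expr
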