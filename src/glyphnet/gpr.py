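"""Gene-protein-reaction (GPR) boolean expression parsing.

A GPR rule is a boolean expression over gene identifiers stating which
genes enable a reaction, e.g. ``(b0001 and b0002) or b0003``:  AND groups
form enzyme complexes, OR branches are isoenzymes.  The boolean semantics
are recorded but never evaluated here; downstream code only needs the
gene leaf set and the tree shape.

Grammar (recursive descent, parentheses > AND > OR):

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := GENE | "(" expr ")"

Keywords are matched case-insensitively; ``&&`` / ``||`` are accepted as
synonyms.  Gene tokens keep their original case.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Tuple, Union

__all__ = ["GprError", "Gene", "BoolOp", "GprExpression", "parse_gpr", "serialize_gpr"]


class GprError(ValueError):
    """Raised on malformed GPR expressions; message includes the position."""


@dataclass(frozen=True)
class Gene:
    """A leaf: one gene identifier token."""

    name: str

    def leaves(self) -> List[str]:
        return [self.name]


@dataclass(frozen=True)
class BoolOp:
    """An internal node: AND (complex) or OR (isoenzymes) over >=2 children."""

    op: str  # "AND" | "OR"
    children: Tuple["GprExpression", ...]

    def leaves(self) -> List[str]:
        out: List[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


GprExpression = Union[Gene, BoolOp]

_TOKEN_RE = re.compile(r"\(|\)|&&|\|\||[^\s()]+")


def _tokenize(expr: str) -> List[Tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(expr):
        tok = m.group(0)
        if tok == "&&":
            tok = "and"
        elif tok == "||":
            tok = "or"
        tokens.append((tok, m.start()))
    return tokens


class _Parser:
    def __init__(self, expr: str) -> None:
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self) -> Union[Tuple[str, int], None]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> Tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GprError(
                f"unexpected end of expression at position {len(self.expr)}"
            )
        self.pos += 1
        return tok

    def parse(self) -> GprExpression:
        if not self.tokens:
            raise GprError("empty GPR expression")
        tree = self.expr_()
        rest = self.peek()
        if rest is not None:
            raise GprError(
                f"unexpected token {rest[0]!r} at position {rest[1]}"
            )
        return tree

    def expr_(self) -> GprExpression:
        children = [self.term()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0].lower() == "or":
                self.next()
                children.append(self.term())
            else:
                break
        return children[0] if len(children) == 1 else BoolOp("OR", tuple(children))

    def term(self) -> GprExpression:
        children = [self.factor()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0].lower() == "and":
                self.next()
                children.append(self.factor())
            else:
                break
        return children[0] if len(children) == 1 else BoolOp("AND", tuple(children))

    def factor(self) -> GprExpression:
        tok, pos = self.next()
        low = tok.lower()
        if tok == "(":
            inner = self.expr_()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise GprError(f"unbalanced parenthesis opened at position {pos}")
            self.next()
            return inner
        if tok == ")":
            raise GprError(f"unmatched ')' at position {pos}")
        if low in ("and", "or"):
            raise GprError(f"dangling operator {tok!r} at position {pos}")
        return Gene(tok)


def parse_gpr(expr: str) -> GprExpression:
    """Parse a GPR string into a boolean tree.

    Raises :class:`GprError` on empty input, unbalanced parentheses or
    dangling operators, reporting the offending position.
    """
    if expr is None or not expr.strip():
        raise GprError("empty GPR expression")
    return _Parser(expr).parse()


def serialize_gpr(tree: GprExpression) -> str:
    """Render a GPR tree as a canonical string that re-parses identically."""
    if isinstance(tree, Gene):
        return tree.name
    word = " and " if tree.op == "AND" else " or "
    parts = []
    for child in tree.children:
        text = serialize_gpr(child)
        if isinstance(child, BoolOp):
            # parenthesise any nested operator: unambiguous regardless of precedence
            text = f"({text})"
        parts.append(text)
    return word.join(parts)
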