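"""Boolean gene-protein-reaction (GPR) associations.

A GPR is a boolean expression tree over gene identifiers: AND nodes model
enzyme complexes (every subunit required), OR nodes model isoenzymes (any
one suffices).  The same tree structure doubles as the reduction skeleton
for mapping gene-level expression onto reactions (AND -> min, OR -> sum).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator


class GprParseError(ValueError):
    """Raised for malformed GPR expression strings."""


@dataclass(frozen=True)
class GprNode:
    """One node of a GPR tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the
    gene id in ``gene``; internal nodes carry ``children``.
    """

    kind: str
    gene: str | None = None
    children: tuple["GprNode", ...] = ()

    def genes(self) -> set[str]:
        if self.kind == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, deleted_genes: set[str] | frozenset[str]) -> bool:
        """Reaction activity after deleting ``deleted_genes``."""
        if self.kind == "gene":
            return self.gene not in deleted_genes
        if self.kind == "and":
            return all(c.evaluate(deleted_genes) for c in self.children)
        if self.kind == "or":
            return any(c.evaluate(deleted_genes) for c in self.children)
        raise GprParseError(f"unknown GPR node kind {self.kind!r}")

    def reduce(
        self,
        leaf: Callable[[str], float | None],
        and_op: Callable[[list[float]], float],
        or_op: Callable[[list[float]], float],
    ) -> float | None:
        """Fold the tree with per-node operators.

        ``leaf`` may return None for an unmeasured gene; such children are
        dropped (AND of one child is that child).  Returns None when no
        leaf in the subtree is measured.
        """
        if self.kind == "gene":
            return leaf(self.gene)
        vals = [v for v in (c.reduce(leaf, and_op, or_op) for c in self.children) if v is not None]
        if not vals:
            return None
        return and_op(vals) if self.kind == "and" else or_op(vals)

    def to_string(self) -> str:
        if self.kind == "gene":
            return self.gene
        sep = " and " if self.kind == "and" else " or "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.kind != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(expr: str) -> Iterator[str]:
    for m in _TOKEN.finditer(expr):
        yield m.group(0)


class _Parser:
    # grammar:  or_expr := and_expr ('or' and_expr)*
    #           and_expr := atom ('and' atom)*
    #           atom := gene | '(' or_expr ')'
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprParseError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def parse(self) -> GprNode:
        node = self.or_expr()
        if self.peek() is not None:
            raise GprParseError(f"trailing token {self.peek()!r} in GPR expression")
        return node

    def or_expr(self) -> GprNode:
        terms = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            terms.append(self.and_expr())
        if len(terms) == 1:
            return terms[0]
        return GprNode("or", children=tuple(terms))

    def and_expr(self) -> GprNode:
        terms = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            terms.append(self.atom())
        if len(terms) == 1:
            return terms[0]
        return GprNode("and", children=tuple(terms))

    def atom(self) -> GprNode:
        tok = self.take()
        if tok == "(":
            node = self.or_expr()
            if self.take() != ")":
                raise GprParseError("unbalanced parentheses in GPR expression")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR expression")
        return GprNode("gene", gene=tok)


def parse_gpr(expr: str | None) -> GprNode | None:
    """Parse a GPR string like ``"g1 and (g2 or g3)"``; empty -> None.

    AND/OR keywords are case-insensitive; gene ids are any
    whitespace/parenthesis-free tokens.
    """
    if expr is None:
        return None
    expr = expr.strip()
    if not expr:
        return None
    return _Parser(list(_tokenize(expr))).parse()


def evaluate_gpr(gpr: GprNode | str | None, deleted_genes: set[str]) -> bool:
    """Is the reaction still catalysable after ``deleted_genes`` are removed?

    A reaction with no GPR (spontaneous / non-gene-associated) is always
    active.
    """
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    if gpr is None:
        return True
    return gpr.evaluate(set(deleted_genes))
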