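"""Gene-protein-reaction (GPR) boolean expressions.

A GPR rule links a reaction to the genes whose products catalyse it, as an
AND/OR tree over gene identifiers: ``(gA and gB) or gC`` means the reaction
is available if either the gA+gB complex or the gC isozyme is intact.
Deleting a gene sets its leaf to False; a reaction whose rule evaluates
False is closed (bounds 0,0) in knockout simulations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class GPRExpression:
    """Boolean AND/OR tree whose leaves are gene identifiers.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``. For ``"gene"`` nodes
    ``gene`` holds the identifier and ``children`` is empty.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise ValueError("gene node must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if self.gene is not None or len(self.children) < 2:
                raise ValueError(f"{self.op!r} node needs >= 2 children and no gene id")
        else:
            raise ValueError(f"unknown GPR node op {self.op!r}")

    def genes(self) -> set[str]:
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        if self.op == "gene":
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child._iter_genes()

    def evaluate(self, deleted: set[str]) -> bool:
        """True if the reaction remains catalysed after deleting ``deleted``."""
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def to_string(self) -> str:
        return self._fmt(top=True)

    def _fmt(self, top: bool = False) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c._fmt()
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        body = sep.join(parts)
        return body if top else body

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN = re.compile(r"\s*(\(|\)|and\b|AND\b|or\b|OR\b|[^\s()]+)")


def parse_gpr(text: str) -> GPRExpression | None:
    """Parse a GPR rule string like ``"(gA and gB) or gC"``.

    Returns None for an empty rule (reaction always available). ``and``
    binds tighter than ``or``, parentheses group.
    """
    tokens = _tokenize(text)
    if not tokens:
        return None
    expr, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule {text!r}")
    return expr


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            break
        tokens.append(m.group(1))
        pos = m.end()
    if text[pos:].strip():
        raise ValueError(f"cannot tokenize GPR rule {text!r}")
    return tokens


def _parse_or(tokens: list[str], pos: int) -> tuple[GPRExpression, int]:
    node, pos = _parse_and(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return GPRExpression("or", children=tuple(children)), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[GPRExpression, int]:
    node, pos = _parse_atom(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return GPRExpression("and", children=tuple(children)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GPRExpression, int]:
    if pos >= len(tokens):
        raise ValueError("unexpected end of GPR rule")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parentheses in GPR rule")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise ValueError(f"unexpected token {tok!r} in GPR rule")
    return GPRExpression("gene", gene=tok), pos + 1
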