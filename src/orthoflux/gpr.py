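"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which combinations of genes enable a reaction: ``or``
joins isozymes (any one suffices), ``and`` joins subunits of a complex
(all are required). Rules are parsed from the usual reconstruction
dialect — gene identifiers, parentheses and the case-insensitive words
``and`` / ``or``, with ``and`` binding tighter than ``or``. An empty
rule marks a non-gene-associated reaction and always evaluates true.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping


class GPRParseError(ValueError):
    """Raised for malformed rule strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneRef:
    """Leaf node: a single gene identifier."""

    gene: str

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    """Internal node: AND/OR over two or more children."""

    op: str  # "and" | "or"
    children: tuple

    def __post_init__(self):
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown connective {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs >= 2 children")

    def __str__(self) -> str:
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            if isinstance(c, BoolOp) and not (self.op == "or" and c.op == "and"):
                parts.append(f"({c})")
            elif isinstance(c, BoolOp) and self.op == "or" and c.op == "and":
                # "and" binds tighter; parentheses optional but kept for clarity
                parts.append(f"({c})")
            else:
                parts.append(str(c))
        return sep.join(parts)


# A GPR expression is GeneRef | BoolOp | None (None = empty rule).
GPRNode = GeneRef | BoolOp | None


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids; ``root is None`` for an empty rule."""

    root: GPRNode = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        """The set of gene ids appearing in the rule."""
        out: set[str] = set()
        _collect(self.root, out)
        return frozenset(out)

    def evaluate(self, present: Iterable[str]) -> bool:
        """Standard boolean semantics; an empty rule is always true."""
        present = set(present)
        return _eval(self.root, present)

    def to_string(self) -> str:
        return "" if self.root is None else str(self.root)

    def __str__(self) -> str:
        return self.to_string()


def _collect(node: GPRNode, out: set[str]) -> None:
    if node is None:
        return
    if isinstance(node, GeneRef):
        out.add(node.gene)
    else:
        for c in node.children:
            _collect(c, out)


def _eval(node: GPRNode, present: set[str]) -> bool:
    if node is None:
        return True
    if isinstance(node, GeneRef):
        return node.gene in present
    if node.op == "and":
        return all(_eval(c, present) for c in node.children)
    return any(_eval(c, present) for c in node.children)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRExpression:
    """Parse a rule string into a :class:`GPRExpression`.

    Grammar: ``or_expr := and_expr ('or' and_expr)*``,
    ``and_expr := atom ('and' atom)*``, ``atom := gene | '(' or_expr ')'``.
    Raises :class:`GPRParseError` on unbalanced parentheses or empty
    operands, naming the character position of the offence.
    """
    if text is None or not text.strip():
        return GPRExpression(None)

    tokens: list[tuple[str, int]] = [
        (m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)
    ]
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def or_expr() -> GPRNode:
        nonlocal pos
        terms = [and_expr()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "or":
                pos += 1
                terms.append(and_expr())
            else:
                break
        return terms[0] if len(terms) == 1 else BoolOp("or", tuple(terms))

    def and_expr() -> GPRNode:
        nonlocal pos
        terms = [atom()]
        while True:
            tok, _ = peek()
            if tok is not None and tok.lower() == "and":
                pos += 1
                terms.append(atom())
            else:
                break
        return terms[0] if len(terms) == 1 else BoolOp("and", tuple(terms))

    def atom() -> GPRNode:
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GPRParseError("missing operand", at)
        if tok == "(":
            pos += 1
            inner = or_expr()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GPRParseError("unbalanced parenthesis", at2)
            pos += 1
            return inner
        if tok == ")":
            raise GPRParseError("unexpected ')'", at)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"connective {tok!r} used as operand", at)
        pos += 1
        return GeneRef(tok)

    root = or_expr()
    tok, at = peek()
    if tok is not None:
        raise GPRParseError(f"unexpected token {tok!r}", at)
    return GPRExpression(root)


# Sentinels for constant-folding during translation.
_TRUE = object()
_FALSE = object()


def translate_gpr(
    gpr: GPRExpression, mapping: Mapping[str, Iterable[str]]
) -> GPRExpression | None:
    """Rewrite a rule into a target gene namespace via a homology mapping.

    Each leaf becomes an OR over the source gene's target homologs; a
    leaf with no homolog becomes constant false and is simplified away.
    Returns ``None`` when the whole rule folds to false (the reaction
    cannot be catalysed by any mapped gene); the empty rule stays empty.
    """
    if gpr.is_empty:
        return GPRExpression(None)
    node = _translate(gpr.root, mapping)
    if node is _FALSE:
        return None
    if node is _TRUE:  # cannot occur from leaves, kept for totality
        return GPRExpression(None)
    return GPRExpression(node)


def _translate(node: GPRNode, mapping: Mapping[str, Iterable[str]]):
    if isinstance(node, GeneRef):
        targets = sorted(set(mapping.get(node.gene, ())))
        if not targets:
            return _FALSE
        if len(targets) == 1:
            return GeneRef(targets[0])
        return BoolOp("or", tuple(GeneRef(t) for t in targets))
    assert isinstance(node, BoolOp)
    children = [_translate(c, mapping) for c in node.children]
    if node.op == "and":
        if any(c is _FALSE for c in children):
            return _FALSE
        kept = [c for c in children if c is not _TRUE]
    else:
        if any(c is _TRUE for c in children):
            return _TRUE
        kept = [c for c in children if c is not _FALSE]
        if not kept:
            return _FALSE
    if not kept:
        return _TRUE
    if len(kept) == 1:
        return kept[0]
    return BoolOp(node.op, tuple(kept))


def evaluate_gpr(gpr: GPRExpression, present: Iterable[str]) -> bool:
    """Module-level convenience mirror of :meth:`GPRExpression.evaluate`."""
    return gpr.evaluate(present)
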