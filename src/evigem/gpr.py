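"""Gene-protein-reaction (GPR) boolean expressions.

A GPR states which combinations of genes enable a reaction, as a boolean
tree with AND/OR internal nodes and gene identifiers at the leaves.
Knockout simulation evaluates the tree with deleted genes set to False;
a reaction whose GPR evaluates False is disabled.

Gene identifiers are opaque strings stored verbatim (JGI transcript ids
such as ``1178899`` are legal leaves), so the string syntax tokenizes any
run of characters that is not whitespace, a parenthesis, or the keywords
``and`` / ``or`` (case-insensitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterator, Optional, Set, Tuple, Union

__all__ = ["GPR", "GPRNode", "GeneRef", "BoolOp", "parse_gpr", "GPRSyntaxError"]


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GeneRef:
    """Leaf node: a single gene identifier."""

    gene: str

    def evaluate(self, deleted: FrozenSet[str]) -> bool:
        return self.gene not in deleted

    def genes(self) -> Iterator[str]:
        yield self.gene

    def to_string(self, _parent_op: Optional[str] = None) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    """Internal node: AND (conjunction) or OR (disjunction) over children."""

    op: str  # "and" | "or"
    children: Tuple["GPRNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"invalid GPR operator: {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("BoolOp needs at least two children")

    def evaluate(self, deleted: FrozenSet[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> Iterator[str]:
        for c in self.children:
            yield from c.genes()

    def to_string(self, parent_op: Optional[str] = None) -> str:
        sep = f" {self.op} "
        body = sep.join(c.to_string(self.op) for c in self.children)
        # parenthesize when nested under a different operator, for clarity
        # and to round-trip unambiguously ("a and (b or c)")
        if parent_op is not None and parent_op != self.op:
            return f"({body})"
        return body


GPRNode = Union[GeneRef, BoolOp]


@dataclass(frozen=True)
class GPR:
    """A possibly-empty gene association.

    The empty GPR (``root is None``) means the reaction has no gene
    requirement: it is never disabled by gene deletion.
    """

    root: Optional[GPRNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, deleted: Set[str]) -> bool:
        """True iff the reaction remains active with `deleted` genes removed."""
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(deleted))

    def genes(self) -> Set[str]:
        if self.root is None:
            return set()
        return set(self.root.genes())

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    @classmethod
    def from_string(cls, text: str) -> "GPR":
        return parse_gpr(text)


# ---------------------------------------------------------------------------
# parsing

_SPECIAL = {"(", ")"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch in _SPECIAL:
            if buf:
                tokens.append("".join(buf))
                buf = []
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


class _Parser:
    """Recursive-descent parser; OR binds looser than AND."""

    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR: {self.text!r}")
        self.pos += 1
        return tok

    def parse(self) -> GPRNode:
        node = self.parse_or()
        if self.peek() is not None:
            raise GPRSyntaxError(
                f"trailing tokens at position {self.pos} in GPR: {self.text!r}"
            )
        return node

    def parse_or(self) -> GPRNode:
        parts = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else BoolOp("or", tuple(parts))

    def parse_and(self) -> GPRNode:
        parts = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            parts.append(self.parse_atom())
        return parts[0] if len(parts) == 1 else BoolOp("and", tuple(parts))

    def parse_atom(self) -> GPRNode:
        tok = self.take()
        if tok == "(":
            node = self.parse_or()
            closing = self.take()
            if closing != ")":
                raise GPRSyntaxError(f"expected ')' in GPR: {self.text!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR: {self.text!r}")
        return GeneRef(tok)


def parse_gpr(text: str) -> GPR:
    """Parse a GPR string like ``"(g1 and g2) or g3"``.

    An empty or whitespace-only string yields the empty GPR.
    """
    tokens = _tokenize(text)
    if not tokens:
        return GPR(None)
    return GPR(_Parser(tokens, text).parse())
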