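"""Gene-protein-reaction (GPR) boolean rules.

A GPR links a reaction to the genes whose products catalyse it.  ``and``
joins obligate complex subunits (all required), ``or`` joins isozymes
(any suffices).  Example from carbamoyl-phosphate synthase, a two-chain
complex with two candidate genes per chain::

    (Cthe_1867 or Cthe_0950) and (Cthe_1868 or Cthe_0949)

The expression tree is immutable; evaluation against a set of deleted
genes answers "is the reaction still catalysable?".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import FrozenSet, Iterator, Tuple

logger = logging.getLogger(__name__)

__all__ = ["Gpr", "GprLeaf", "GprAnd", "GprOr", "GprParseError", "parse_gpr"]


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class Gpr:
    """Base class for GPR expression nodes."""

    def evaluate(self, deleted: frozenset | set = frozenset()) -> bool:
        raise NotImplementedError

    @property
    def genes(self) -> FrozenSet[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self.to_string()


@dataclass(frozen=True)
class GprLeaf(Gpr):
    gene: str

    def evaluate(self, deleted=frozenset()):
        return self.gene not in deleted

    @property
    def genes(self):
        return frozenset({self.gene})

    def to_string(self):
        return self.gene


def _paren(child: Gpr) -> str:
    return f"({child.to_string()})" if isinstance(child, (GprAnd, GprOr)) else child.to_string()


@dataclass(frozen=True)
class GprAnd(Gpr):
    children: Tuple[Gpr, ...]

    def evaluate(self, deleted=frozenset()):
        return all(c.evaluate(deleted) for c in self.children)

    @property
    def genes(self):
        return frozenset().union(*(c.genes for c in self.children))

    def to_string(self):
        return " and ".join(_paren(c) for c in self.children)


@dataclass(frozen=True)
class GprOr(Gpr):
    children: Tuple[Gpr, ...]

    def evaluate(self, deleted=frozenset()):
        return any(c.evaluate(deleted) for c in self.children)

    @property
    def genes(self):
        return frozenset().union(*(c.genes for c in self.children))

    def to_string(self):
        return " or ".join(_paren(c) for c in self.children)


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        yield m.group(1), m.start(1)
        pos = m.end()


def parse_gpr(text: str) -> Gpr:
    """Parse a boolean GPR string into an expression tree.

    ``and`` binds tighter than ``or`` (complex membership before isozyme
    choice); parentheses override.  Operators are case-insensitive.  A
    warning is logged when both operators appear unparenthesized, since
    supplementary files are inconsistent about implied grouping.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise GprParseError("empty GPR expression", 0)

    ops_seen = {t.lower() for t, _ in tokens if t.lower() in ("and", "or")}
    if len(ops_seen) == 2 and "(" not in {t for t, _ in tokens}:
        logger.warning(
            "GPR %r mixes 'and'/'or' without parentheses; "
            "'and' is taken to bind tighter", text
        )

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else (None, len(text))

    def parse_or() -> Gpr:
        nonlocal idx
        terms = [parse_and()]
        while peek()[0] is not None and peek()[0].lower() == "or":
            idx += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprOr(tuple(terms))

    def parse_and() -> Gpr:
        nonlocal idx
        factors = [parse_atom()]
        while peek()[0] is not None and peek()[0].lower() == "and":
            idx += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GprAnd(tuple(factors))

    def parse_atom() -> Gpr:
        nonlocal idx
        tok, pos = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression: missing operand", pos)
        if tok == "(":
            idx += 1
            inner = parse_or()
            tok2, pos2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parentheses: expected ')'", pos2)
            idx += 1
            return inner
        if tok == ")":
            raise GprParseError("unbalanced parentheses: unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GprParseError(f"empty operand before {tok!r}", pos)
        idx += 1
        return GprLeaf(tok)

    tree = parse_or()
    tok, pos = peek()
    if tok is not None:
        raise GprParseError(f"unexpected token {tok!r}", pos)
    return tree
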