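"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``AND`` encodes subunits of a protein complex (all required), ``OR``
encodes isoenzymes (any suffices).  Rules are parsed into a small
expression tree; for expression-weight mapping the tree is evaluated
with AND -> min of child weights (a complex is as available as its
scarcest subunit) and OR -> sum of child weights (isoenzyme capacities
add up).

Grammar (keywords case-insensitive, AND binds tighter than OR):

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := GENE | "(" expr ")"
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Union


class GPRParseError(ValueError):
    """Raised for malformed GPR rule strings."""


@dataclass(frozen=True)
class Gene:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class And:
    children: tuple["GPRNode", ...]

    def __str__(self) -> str:
        return " and ".join(
            f"({c})" if isinstance(c, Or) else str(c) for c in self.children
        )


@dataclass(frozen=True)
class Or:
    children: tuple["GPRNode", ...]

    def __str__(self) -> str:
        return " or ".join(str(c) for c in self.children)


GPRNode = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _Parser:
    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of rule: {self.rule!r}")
        self.pos += 1
        return tok

    def parse_expr(self) -> GPRNode:
        terms = [self.parse_term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term(self) -> GPRNode:
        factors = [self.parse_factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.parse_factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor(self) -> GPRNode:
        tok = self.next()
        if tok == "(":
            node = self.parse_expr()
            if self.peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {self.rule!r}")
            self.next()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"empty operand near {tok!r} in {self.rule!r}")
        return Gene(tok)


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR rule string into an expression tree.

    AND binds tighter than OR when unparenthesized, the usual convention
    in metabolic reconstructions.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or empty operands.
    """
    tokens = _tokenize(rule)
    if not tokens:
        raise GPRParseError("empty GPR rule")
    parser = _Parser(tokens, rule)
    node = parser.parse_expr()
    if parser.peek() is not None:
        raise GPRParseError(
            f"trailing tokens {parser.tokens[parser.pos:]} in {rule!r}"
        )
    return node


def gpr_genes(node: GPRNode) -> set[str]:
    """All gene ids appearing in the rule."""
    if isinstance(node, Gene):
        return {node.name}
    out: set[str] = set()
    for child in node.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(node: GPRNode, weights: Mapping[str, float] | Callable[[str], float]) -> float:
    """Evaluate a GPR tree over gene weights: AND -> min, OR -> sum."""
    lookup = weights.__getitem__ if isinstance(weights, Mapping) else weights
    return _eval(node, lookup)


def _eval(node: GPRNode, lookup: Callable[[str], float]) -> float:
    if isinstance(node, Gene):
        return float(lookup(node.name))
    values = [_eval(c, lookup) for c in node.children]
    if isinstance(node, And):
        return min(values)
    return sum(values)


def serialize_gpr(node: GPRNode) -> str:
    """Canonical string form; ``parse_gpr(serialize_gpr(t))`` reproduces ``t``."""
    return str(node)
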