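"""Gene-protein-reaction (GPR) rule parsing and numeric evaluation.

A GPR rule is a boolean expression over gene identifiers in which AND
denotes an enzyme complex (every subunit required) and OR denotes
isozymes (any one suffices).  For activity scoring the boolean
semantics are replaced by numeric min/max propagation: an AND node
takes the *minimum* score of its children, an OR node the *maximum*.
The single gene whose score survives propagation to the root is the
reaction's *determinant* gene; downstream weighting (gene significance)
counts how often each gene is a determinant, so determinant selection
must be deterministic — ties are broken toward the lexicographically
smallest gene id.

Grammar (case-insensitive operators, AND binds tighter than OR)::

    expr   := term ( OR term )*
    term   := factor ( AND factor )*
    factor := '(' expr ')' | GENE

Adjacent same-operator nodes are flattened, so ``A and B and C`` is a
single three-child AND node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

__all__ = [
    "GPRLeaf",
    "GPRNode",
    "GPRRule",
    "GPREvaluation",
    "GPRParseError",
    "parse_gpr",
    "format_gpr",
    "evaluate_gpr",
    "gpr_genes",
]


@dataclass(frozen=True)
class GPRLeaf:
    """A single gene reference."""

    gene: str


@dataclass(frozen=True)
class GPRNode:
    """An operator node: ``op`` is ``"and"`` or ``"or"``."""

    op: str
    children: tuple

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("operator node requires at least two children")


GPRRule = Union[GPRLeaf, GPRNode]


class GPRParseError(ValueError):
    """Raised for malformed rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRRule:
        node = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[0]!r}", tok[1])
        return node

    def _expr(self) -> GPRRule:
        children = [self._term()]
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() == "or":
                self._next()
                children.append(self._term())
            else:
                break
        return _combine("or", children)

    def _term(self) -> GPRRule:
        children = [self._factor()]
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() == "and":
                self._next()
                children.append(self._factor())
            else:
                break
        return _combine("and", children)

    def _factor(self) -> GPRRule:
        tok = self._next()
        text, start = tok
        if text == "(":
            inner = self._expr()
            close = self._peek()
            if close is None or close[0] != ")":
                raise GPRParseError("unbalanced parenthesis", start)
            self._next()
            return inner
        if text == ")":
            raise GPRParseError("unbalanced parenthesis", start)
        if text.lower() in ("and", "or"):
            raise GPRParseError(f"dangling operator {text!r}", start)
        return GPRLeaf(text)


def _combine(op: str, children: list[GPRRule]) -> GPRRule:
    if len(children) == 1:
        return children[0]
    flat: list[GPRRule] = []
    for child in children:
        if isinstance(child, GPRNode) and child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    return GPRNode(op, tuple(flat))


def parse_gpr(rule_text: str) -> Optional[GPRRule]:
    """Parse rule text into an expression tree.

    Returns ``None`` for empty/whitespace-only text (a reaction with no
    gene association).  Raises :class:`GPRParseError` for malformed
    rules, reporting the character position of the problem.
    """
    if rule_text is None or not rule_text.strip():
        return None
    return _Parser(rule_text).parse()


def format_gpr(rule: Optional[GPRRule]) -> str:
    """Render a rule tree back to canonical text (round-trips parse)."""
    if rule is None:
        return ""
    return _format(rule, parent_op=None)


def _format(rule: GPRRule, parent_op: Optional[str]) -> str:
    if isinstance(rule, GPRLeaf):
        return rule.gene
    sep = f" {rule.op} "
    body = sep.join(_format(c, rule.op) for c in rule.children)
    # OR inside AND needs parentheses under AND-over-OR precedence
    if parent_op == "and" and rule.op == "or":
        return f"({body})"
    return body


def gpr_genes(rule: Optional[GPRRule]) -> frozenset[str]:
    """All gene ids appearing anywhere in the rule."""
    if rule is None:
        return frozenset()
    if isinstance(rule, GPRLeaf):
        return frozenset((rule.gene,))
    out: set[str] = set()
    for child in rule.children:
        out.update(gpr_genes(child))
    return frozenset(out)


@dataclass
class GPREvaluation:
    """Result of numeric GPR evaluation.

    ``value`` is ``None`` (undefined) when every gene in the rule is
    missing from the score map — distinct from a zero score.
    """

    value: Optional[float]
    determinant: Optional[str]
    missing_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def defined(self) -> bool:
        return self.value is not None


def evaluate_gpr(
    rule: GPRRule,
    scores: Mapping[str, float],
    missing: str = "drop",
) -> GPREvaluation:
    """Evaluate a rule over non-negative gene scores.

    AND propagates the minimum child value, OR the maximum; the leaf
    whose score reaches the root is the determinant.  Ties break toward
    the lexicographically smallest determinant gene id.

    Parameters
    ----------
    missing:
        ``"drop"`` (default) removes unmeasured leaves from their parent
        operator, treating them as uninformative; a node whose children
        are all missing is dropped recursively, and a fully missing rule
        yields an undefined evaluation.  ``"zero"`` scores unmeasured
        genes as 0 (they then dominate AND nodes).
    """
    if missing not in ("drop", "zero"):
        raise ValueError("missing must be 'drop' or 'zero'")
    missing_set: set[str] = set()
    result = _evaluate(rule, scores, missing, missing_set)
    if result is None:
        return GPREvaluation(None, None, frozenset(missing_set))
    value, determinant = result
    return GPREvaluation(value, determinant, frozenset(missing_set))


def _evaluate(
    rule: GPRRule,
    scores: Mapping[str, float],
    missing: str,
    missing_set: set,
) -> Optional[tuple[float, str]]:
    if isinstance(rule, GPRLeaf):
        if rule.gene in scores:
            return float(scores[rule.gene]), rule.gene
        missing_set.add(rule.gene)
        if missing == "zero":
            return 0.0, rule.gene
        return None
    evaluated = [
        r
        for r in (_evaluate(c, scores, missing, missing_set) for c in rule.children)
        if r is not None
    ]
    if not evaluated:
        return None
    pick = min if rule.op == "and" else max
    best_value = pick(v for v, _ in evaluated)
    # lexicographic tie-break on determinant among value-tied children
    candidates = [d for v, d in evaluated if v == best_value]
    return best_value, min(candidates)
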