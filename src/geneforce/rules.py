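"""Boolean regulatory-rule language: parsing, evaluation, MILP linearization.

Integrated metabolic/regulatory models describe gene expression and
transcription-factor (TF) activity with Boolean rules such as::

    (NOT ArgR) OR (arg-L(e)>0)
    (Crp AND (NOT Lrp OR (leu-L(e)>0)))
    NOT (Growth>0) AND RpoS

Leaves of a rule are either plain identifiers (genes or TFs — which of the
two is resolved against the model, not by the grammar), environmental
predicates ``met(e)>tau`` that test whether an extracellular metabolite is
available, or flux predicates ``RXN>tau`` that test whether a reaction
carries flux above a threshold (``Growth>0`` refers to the biomass flux).
``met(e)`` with no comparison is shorthand for ``met(e)>0``.

Operator precedence is NOT > AND > OR; unparenthesized mixed chains
associate left and trigger :class:`AmbiguousPrecedenceWarning`, since
published rule sets are fully parenthesized and only user-authored rules can
hit the ambiguity.

The same grammar also parses gene-protein-reaction (GPR) association
strings (``b0001 and b0002``): AND/OR/NOT are case-insensitive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterator, Mapping

from lark import Lark, Token, Transformer, v_args
from lark.exceptions import UnexpectedInput


class RuleSyntaxError(ValueError):
    """Malformed rule text; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class UnresolvedSymbolError(KeyError):
    """A rule leaf had no entry in the evaluation assignment."""


class AmbiguousPrecedenceWarning(UserWarning):
    """Mixed NOT/AND/OR at the same parenthesis depth without grouping."""


class SymbolKind(str, Enum):
    IDENTIFIER = "identifier"  # gene or TF; resolved against the model
    GENE = "gene"
    TF = "tf"
    ENV = "env"                # extracellular-metabolite presence predicate
    FLUX = "flux"              # reaction-flux predicate


@dataclass(frozen=True)
class SymbolRef:
    """A rule leaf: an identifier or a thresholded predicate.

    ``threshold`` is only meaningful for predicates; its units are
    mmol/gDW/hr for flux predicates and a presence indicator (always 0 in
    the shipped rule sets) for environmental ones.
    """

    name: str
    kind: SymbolKind = SymbolKind.IDENTIFIER
    threshold: float | None = None

    @property
    def key(self) -> str:
        """Canonical text form, used as the assignment/variable key."""
        if self.kind is SymbolKind.ENV:
            return f"{self.name}(e)>{_fmt_num(self.threshold or 0.0)}"
        if self.kind is SymbolKind.FLUX:
            return f"{self.name}>{_fmt_num(self.threshold or 0.0)}"
        return self.name

    def with_kind(self, kind: SymbolKind) -> "SymbolRef":
        return SymbolRef(self.name, kind, self.threshold)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


class BoolExpr:
    """Abstract syntax tree node. Subclasses: Const, Ref, Not, And, Or."""

    def to_text(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


@dataclass(frozen=True)
class Const(BoolExpr):
    value: bool

    def to_text(self) -> str:
        return "ON" if self.value else "OFF"


@dataclass(frozen=True)
class Ref(BoolExpr):
    symbol: SymbolRef

    def to_text(self) -> str:
        name = self.symbol.name
        if any(c.isspace() for c in name):
            name = f'"{name}"'
        if self.symbol.kind is SymbolKind.ENV:
            return f"{name}(e)>{_fmt_num(self.symbol.threshold or 0.0)}"
        if self.symbol.kind is SymbolKind.FLUX:
            return f"{name}>{_fmt_num(self.symbol.threshold or 0.0)}"
        return name


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def to_text(self) -> str:
        return f"NOT {_child_text(self.child, wrap_binary=True)}"


@dataclass(frozen=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least two operands")

    def to_text(self) -> str:
        return " AND ".join(_child_text(c, wrap_binary=True) for c in self.children)


@dataclass(frozen=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least two operands")

    def to_text(self) -> str:
        return " OR ".join(_child_text(c, wrap_binary=True) for c in self.children)


def _child_text(node: BoolExpr, wrap_binary: bool) -> str:
    text = node.to_text()
    if wrap_binary and isinstance(node, (And, Or, Not)):
        return f"({text})"
    return text


_GRAMMAR = r"""
?start: expr
?expr: or_expr
?or_expr: and_expr (_OR and_expr)*
?and_expr: unary (_AND unary)*
?unary: _NOT unary -> negation
      | atom
?atom: "(" expr ")"
     | on | off
     | env_pred
     | flux_pred
     | name_ref

on: "ON"
off: "OFF"
env_pred: ENVNAME (">" NUMBER)?
flux_pred: (NAME | QNAME) ">" NUMBER
name_ref: NAME | QNAME

_OR: "OR"i
_AND: "AND"i
_NOT: "NOT"i
ENVNAME.3: /[A-Za-z0-9_][A-Za-z0-9_\-'.,]*\(e\)/
NAME: /[A-Za-z0-9_][A-Za-z0-9_\-'.,]*/
QNAME: /"[^"]+"/
NUMBER: /\d+(\.\d+)?([eE][+-]?\d+)?/

%import common.WS
%ignore WS
"""


@v_args(inline=True)
class _AstBuilder(Transformer):
    def on(self):
        return Const(True)

    def off(self):
        return Const(False)

    def env_pred(self, name: Token, number: Token | None = None):
        met = str(name)[: -len("(e)")]
        thr = float(number) if number is not None else 0.0
        return Ref(SymbolRef(met, SymbolKind.ENV, thr))

    def flux_pred(self, name: Token, number: Token):
        return Ref(SymbolRef(_unquote(name), SymbolKind.FLUX, float(number)))

    def name_ref(self, name: Token):
        return Ref(SymbolRef(_unquote(name)))

    def negation(self, child: BoolExpr):
        return Not(child)

    def or_expr(self, *children: BoolExpr):
        return Or(tuple(children))

    def and_expr(self, *children: BoolExpr):
        return And(tuple(children))


def _unquote(tok: Token) -> str:
    s = str(tok)
    return s[1:-1] if s.startswith('"') else s


_PARSER = Lark(_GRAMMAR, parser="lalr", transformer=_AstBuilder())


def parse_rule(text: str) -> BoolExpr:
    """Parse a rule string into a :class:`BoolExpr`.

    Raises :class:`RuleSyntaxError` (with character offset) for unbalanced
    parentheses, dangling operators, or empty operands. Warns with
    :class:`AmbiguousPrecedenceWarning` when NOT/AND/OR of different kinds
    appear unparenthesized at the same nesting depth.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty rule", 0)
    _warn_if_mixed_precedence(text)
    try:
        return _PARSER.parse(text)
    except UnexpectedInput as exc:
        offset = getattr(exc, "pos_in_stream", None)
        raise RuleSyntaxError(f"invalid rule syntax in {text!r}", offset) from exc


def _warn_if_mixed_precedence(text: str) -> None:
    # Track operator kinds per parenthesis group; quoted names are opaque.
    depth = 0
    group = [0]
    counter = itertools.count(1)
    kinds: dict[int, set[str]] = {}
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == '"':
            j = text.find('"', i + 1)
            i = n if j < 0 else j + 1
            continue
        if c == "(":
            depth += 1
            group.append(next(counter))
        elif c == ")":
            if depth == 0:
                return  # unbalanced; the parser reports it
            depth -= 1
            group.pop()
        elif c.isalpha():
            j = i
            while j < n and (text[j].isalnum() or text[j] in "_-'.,"):
                j += 1
            word = text[i:j].upper()
            if word in ("AND", "OR", "NOT"):
                kinds.setdefault(group[-1], set()).add(word)
            i = j
            continue
        i += 1
    for ops in kinds.values():
        if len(ops - {"NOT"}) > 1 or (ops == {"NOT", "OR"}):
            warnings.warn(
                "rule mixes NOT/AND/OR without parentheses; "
                "precedence NOT > AND > OR applies",
                AmbiguousPrecedenceWarning,
                stacklevel=3,
            )
            return


def evaluate(expr: BoolExpr, assignment: Mapping[str, bool]) -> bool:
    """Evaluate under a truth assignment keyed by :attr:`SymbolRef.key`."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Ref):
        key = expr.symbol.key
        if key not in assignment:
            raise UnresolvedSymbolError(key)
        return bool(assignment[key])
    if isinstance(expr, Not):
        return not evaluate(expr.child, assignment)
    if isinstance(expr, And):
        return all(evaluate(c, assignment) for c in expr.children)
    if isinstance(expr, Or):
        return any(evaluate(c, assignment) for c in expr.children)
    raise TypeError(f"not a BoolExpr: {expr!r}")


def free_symbols(expr: BoolExpr) -> set[SymbolRef]:
    """The distinct leaf references of ``expr`` (kind-preserving)."""
    out: set[SymbolRef] = set()

    def walk(node: BoolExpr) -> None:
        if isinstance(node, Ref):
            out.add(node.symbol)
        elif isinstance(node, Not):
            walk(node.child)
        elif isinstance(node, (And, Or)):
            for c in node.children:
                walk(c)

    walk(expr)
    return out


def iter_nodes(expr: BoolExpr) -> Iterator[BoolExpr]:
    yield expr
    if isinstance(expr, Not):
        yield from iter_nodes(expr.child)
    elif isinstance(expr, (And, Or)):
        for c in expr.children:
            yield from iter_nodes(c)


def rename_symbols(expr: BoolExpr, rename: Callable[[SymbolRef], SymbolRef]) -> BoolExpr:
    """Structure-preserving leaf substitution (used for rule transfer)."""
    if isinstance(expr, Ref):
        return Ref(rename(expr.symbol))
    if isinstance(expr, Not):
        return Not(rename_symbols(expr.child, rename))
    if isinstance(expr, And):
        return And(tuple(rename_symbols(c, rename) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(rename_symbols(c, rename) for c in expr.children))
    return expr


@dataclass(frozen=True)
class LinearRow:
    """``lb <= sum(coeffs[var] * var) <= ub`` over binary variables."""

    coeffs: Mapping[str, float]
    lb: float
    ub: float


def linearize(
    expr: BoolExpr,
    output_var: str,
    leaf_var: Callable[[SymbolRef], str],
    fresh_var: Callable[[], str],
) -> list[LinearRow]:
    """Exact 0/1 linear encoding of ``output_var == expr``.

    Every internal AND/OR node gets one auxiliary binary (allocated with
    ``fresh_var``); NOT is encoded as the complement ``z + x = 1``; AND/OR
    use the standard min/max inequalities. For each 0/1 assignment of the
    leaves the only feasible value of ``output_var`` equals
    :func:`evaluate` — the suite checks this exhaustively.

    The caller owns variable creation: ``leaf_var`` maps each leaf symbol
    to an existing binary variable name, and the returned rows reference
    variable names only.
    """
    rows: list[LinearRow] = []

    def emit(node: BoolExpr, z: str) -> None:
        if isinstance(node, Const):
            val = 1.0 if node.value else 0.0
            rows.append(LinearRow({z: 1.0}, val, val))
        elif isinstance(node, Ref):
            x = leaf_var(node.symbol)
            rows.append(LinearRow({z: 1.0, x: -1.0}, 0.0, 0.0))
        elif isinstance(node, Not):
            x = operand_var(node.child)
            rows.append(LinearRow({z: 1.0, x: 1.0}, 1.0, 1.0))
        elif isinstance(node, (And, Or)):
            xs = [operand_var(c) for c in node.children]
            n = len(xs)
            # Repeated operands (e.g. "RhaR OR (RhaR AND Crp)" shapes)
            # accumulate coefficients instead of overwriting.
            total: dict[str, float] = {z: 1.0}
            for x in xs:
                total[x] = total.get(x, 0.0) - 1.0
            if isinstance(node, And):
                for x in xs:
                    rows.append(LinearRow({z: 1.0, x: -1.0}, -1.0, 0.0))
                rows.append(LinearRow(total, 1.0 - n, float("inf")))
            else:
                for x in xs:
                    rows.append(LinearRow({z: 1.0, x: -1.0}, 0.0, 1.0))
                rows.append(LinearRow(total, -float("inf"), 0.0))
        else:  # pragma: no cover
            raise TypeError(f"not a BoolExpr: {node!r}")

    def operand_var(node: BoolExpr) -> str:
        if isinstance(node, Ref):
            return leaf_var(node.symbol)
        aux = fresh_var()
        emit(node, aux)
        return aux

    emit(expr, output_var)
    return rows
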