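"""Gene-protein-reaction (GPR) boolean rules.

Grammar follows genome-scale-model convention: gene identifiers combined
with case-insensitive ``and`` / ``or`` and parentheses; no negation.  ``or``
joins isozymes (any one suffices), ``and`` joins complex subunits (all
required).  The empty rule denotes a spontaneous / unannotated reaction and
is always active.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, FrozenSet, Iterable, Mapping, Set, Union

__all__ = ["GprError", "parse_gpr", "evaluate_gpr", "gpr_genes", "aggregate_gpr"]


class GprError(ValueError):
    """Malformed GPR expression."""


@dataclass(frozen=True)
class Gene:
    id: str


@dataclass(frozen=True)
class And:
    operands: tuple


@dataclass(frozen=True)
class Or:
    operands: tuple


Node = Union[Gene, And, Or, None]

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-:]+)")


def _tokenize(expr: str) -> list:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise GprError(f"unexpected character at {expr[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(expr: str) -> Node:
    """Parse a GPR string into an AST; empty/whitespace rules give None."""
    if expr is None or not expr.strip():
        return None
    tokens = _tokenize(expr)
    node, rest = _parse_or(tokens, 0)
    if rest != len(tokens):
        raise GprError(f"trailing tokens in GPR {expr!r}")
    return node


def _parse_or(tokens, i):
    node, i = _parse_and(tokens, i)
    parts = [node]
    while i < len(tokens) and tokens[i].lower() == "or":
        nxt, i = _parse_and(tokens, i + 1)
        parts.append(nxt)
    return (Or(tuple(parts)) if len(parts) > 1 else parts[0]), i


def _parse_and(tokens, i):
    node, i = _parse_atom(tokens, i)
    parts = [node]
    while i < len(tokens) and tokens[i].lower() == "and":
        nxt, i = _parse_atom(tokens, i + 1)
        parts.append(nxt)
    return (And(tuple(parts)) if len(parts) > 1 else parts[0]), i


def _parse_atom(tokens, i):
    if i >= len(tokens):
        raise GprError("unexpected end of GPR expression")
    tok = tokens[i]
    if tok == "(":
        node, i = _parse_or(tokens, i + 1)
        if i >= len(tokens) or tokens[i] != ")":
            raise GprError("unbalanced parentheses in GPR")
        return node, i + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprError(f"unexpected token {tok!r} in GPR")
    return Gene(tok), i + 1


def _fold(node: Node, on_gene: Callable, on_and: Callable, on_or: Callable):
    if isinstance(node, Gene):
        return on_gene(node.id)
    if isinstance(node, And):
        return on_and([_fold(n, on_gene, on_and, on_or) for n in node.operands])
    if isinstance(node, Or):
        return on_or([_fold(n, on_gene, on_and, on_or) for n in node.operands])
    raise GprError(f"cannot fold node {node!r}")


def evaluate_gpr(gpr: Union[str, Node], deleted: Iterable[str] = ()) -> bool:
    """True if the reaction stays catalysable after deleting ``deleted``."""
    node = parse_gpr(gpr) if isinstance(gpr, str) or gpr is None else gpr
    if node is None:
        return True
    dset: FrozenSet[str] = frozenset(deleted)
    return _fold(node, lambda g: g not in dset, all, any)


def gpr_genes(gpr: Union[str, Node]) -> Set[str]:
    """All gene ids referenced by a rule."""
    node = parse_gpr(gpr) if isinstance(gpr, str) or gpr is None else gpr
    if node is None:
        return set()
    return _fold(node, lambda g: {g}, lambda xs: set().union(*xs), lambda xs: set().union(*xs))


def aggregate_gpr(gpr: Union[str, Node], values: Mapping[str, float]) -> float:
    """Aggregate per-gene values over a rule: OR -> max, AND -> min.

    Isozymes (OR) are as capable as their best-expressed member; complexes
    (AND) are limited by their least-expressed subunit.  Raises KeyError if
    a referenced gene has no value, and GprError for empty rules (which have
    no expression value by convention).
    """
    node = parse_gpr(gpr) if isinstance(gpr, str) or gpr is None else gpr
    if node is None:
        raise GprError("empty GPR has no expression value")
    return _fold(node, lambda g: values[g], min, max)
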