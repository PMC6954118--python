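"""Boolean expression trees.

Expressions are immutable trees over named references, used both for
contingency effectors (where references are elemental-state or input
names) and for compiled update rules (where references are model target
symbols).  Construction helpers (:func:`and_all`, :func:`or_all`,
:func:`not_`) perform constant folding only -- no other simplification,
so compiled rules stay structurally close to the defining equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class BoolExpr:
    """Base class for all expression nodes."""

    __slots__ = ()

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def refs(self) -> Iterator[str]:
        """Yield every reference name in the tree (with repeats)."""
        return iter(())

    def __and__(self, other: "BoolExpr") -> "BoolExpr":
        return and_all([self, other])

    def __or__(self, other: "BoolExpr") -> "BoolExpr":
        return or_all([self, other])

    def __invert__(self) -> "BoolExpr":
        return not_(self)


@dataclass(frozen=True)
class _Const(BoolExpr):
    value: bool

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        return self.value

    def __repr__(self) -> str:
        return "TRUE" if self.value else "FALSE"


TRUE = _Const(True)
FALSE = _Const(False)


@dataclass(frozen=True)
class Ref(BoolExpr):
    """Reference to a named target / state / input."""

    name: str

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        try:
            return env[self.name]
        except KeyError:
            raise KeyError(f"unresolved reference {self.name!r}") from None

    def refs(self) -> Iterator[str]:
        yield self.name

    def __repr__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Not(BoolExpr):
    child: BoolExpr

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        return not self.child.evaluate(env)

    def refs(self) -> Iterator[str]:
        return self.child.refs()

    def __repr__(self) -> str:
        return f"!{self.child!r}"


@dataclass(frozen=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        return all(c.evaluate(env) for c in self.children)

    def refs(self) -> Iterator[str]:
        for c in self.children:
            yield from c.refs()

    def __repr__(self) -> str:
        return "(" + " & ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    def evaluate(self, env: Mapping[str, bool]) -> bool:
        return any(c.evaluate(env) for c in self.children)

    def refs(self) -> Iterator[str]:
        for c in self.children:
            yield from c.refs()

    def __repr__(self) -> str:
        return "(" + " | ".join(map(repr, self.children)) + ")"


def and_all(exprs: Iterable[BoolExpr]) -> BoolExpr:
    """Conjunction with constant folding; the empty conjunction is TRUE."""
    flat: list[BoolExpr] = []
    for e in exprs:
        if e is TRUE or e == TRUE:
            continue
        if e is FALSE or e == FALSE:
            return FALSE
        flat.append(e)
    if not flat:
        return TRUE
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def or_all(exprs: Iterable[BoolExpr]) -> BoolExpr:
    """Disjunction with constant folding; the empty disjunction is FALSE."""
    flat: list[BoolExpr] = []
    for e in exprs:
        if e is FALSE or e == FALSE:
            continue
        if e is TRUE or e == TRUE:
            return TRUE
        flat.append(e)
    if not flat:
        return FALSE
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


def not_(expr: BoolExpr) -> BoolExpr:
    if expr is TRUE or expr == TRUE:
        return FALSE
    if expr is FALSE or expr == FALSE:
        return TRUE
    return Not(expr)


def substitute(expr: BoolExpr, mapping: Mapping[str, BoolExpr]) -> BoolExpr:
    """Replace every reference found in ``mapping`` by its expression."""
    if isinstance(expr, Ref):
        return mapping.get(expr.name, expr)
    if isinstance(expr, Not):
        return not_(substitute(expr.child, mapping))
    if isinstance(expr, And):
        return and_all(substitute(c, mapping) for c in expr.children)
    if isinstance(expr, Or):
        return or_all(substitute(c, mapping) for c in expr.children)
    return expr


def rename(expr: BoolExpr, mapping: Mapping[str, str]) -> BoolExpr:
    """Rename references; names absent from the mapping are kept."""
    return substitute(expr, {k: Ref(v) for k, v in mapping.items()})
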