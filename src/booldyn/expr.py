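"""Boolean rule expressions.

A rule is a finite expression tree over node names built from the logical
operators AND, OR and NOT plus the constants TRUE/FALSE.  Trees are immutable;
``And``/``Or`` keep ordered children (>= 2) and ``Not`` exactly one, so arity
invariants hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping


class Expr:
    """Base class for rule expression nodes."""

    __slots__ = ()

    def variables(self) -> set[str]:
        """Distinct node names referenced by this expression."""
        return {v for v in self._iter_vars()}

    def _iter_vars(self) -> Iterator[str]:
        raise NotImplementedError

    def evaluate(self, state: Mapping[str, int]) -> bool:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({to_native(self)!r})"


@dataclass(frozen=True, slots=True, repr=False)
class Var(Expr):
    name: str

    def _iter_vars(self) -> Iterator[str]:
        yield self.name

    def evaluate(self, state: Mapping[str, int]) -> bool:
        return bool(state[self.name])


@dataclass(frozen=True, slots=True, repr=False)
class Const(Expr):
    value: bool

    def _iter_vars(self) -> Iterator[str]:
        return iter(())

    def evaluate(self, state: Mapping[str, int]) -> bool:
        return self.value


TRUE = Const(True)
FALSE = Const(False)


@dataclass(frozen=True, slots=True, repr=False)
class Not(Expr):
    child: Expr

    def _iter_vars(self) -> Iterator[str]:
        return self.child._iter_vars()

    def evaluate(self, state: Mapping[str, int]) -> bool:
        return not self.child.evaluate(state)


class _Nary(Expr):
    __slots__ = ()
    children: tuple[Expr, ...]

    def _iter_vars(self) -> Iterator[str]:
        for c in self.children:
            yield from c._iter_vars()


@dataclass(frozen=True, slots=True, repr=False)
class And(_Nary):
    children: tuple[Expr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("And requires at least two children")

    def evaluate(self, state: Mapping[str, int]) -> bool:
        return all(c.evaluate(state) for c in self.children)


@dataclass(frozen=True, slots=True, repr=False)
class Or(_Nary):
    children: tuple[Expr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("Or requires at least two children")

    def evaluate(self, state: Mapping[str, int]) -> bool:
        return any(c.evaluate(state) for c in self.children)


def conj(children: list[Expr]) -> Expr:
    """n-ary conjunction that collapses trivial arities."""
    if not children:
        return TRUE
    if len(children) == 1:
        return children[0]
    return And(tuple(children))


def disj(children: list[Expr]) -> Expr:
    if not children:
        return FALSE
    if len(children) == 1:
        return children[0]
    return Or(tuple(children))


def substitute(expr: Expr, mapping: Mapping[str, Expr]) -> Expr:
    """Replace variable references according to ``mapping`` (missing names kept)."""
    if isinstance(expr, Var):
        return mapping.get(expr.name, expr)
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(substitute(expr.child, mapping))
    if isinstance(expr, And):
        return And(tuple(substitute(c, mapping) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(substitute(c, mapping) for c in expr.children))
    raise TypeError(type(expr))


def simplify(expr: Expr) -> Expr:
    """Simplify under the standard Boolean identities.

    Applies constant absorption (x AND TRUE = x, x OR TRUE = TRUE, ...),
    double-negation elimination, flattening of nested conjunctions and
    disjunctions, idempotence (x AND x = x) and complement cancellation on
    identical-variable literals (x AND NOT x = FALSE, x OR NOT x = TRUE).
    Purely syntactic: no truth-table minimisation is attempted.
    """
    if isinstance(expr, (Var, Const)):
        return expr
    if isinstance(expr, Not):
        c = simplify(expr.child)
        if isinstance(c, Const):
            return Const(not c.value)
        if isinstance(c, Not):
            return c.child
        return Not(c)
    if isinstance(expr, (And, Or)):
        is_and = isinstance(expr, And)
        absorber = FALSE if is_and else TRUE
        neutral = TRUE if is_and else FALSE
        flat: list[Expr] = []
        for child in expr.children:
            s = simplify(child)
            if isinstance(s, Const):
                if s == absorber:
                    return absorber
                continue  # neutral element dropped
            if type(s) is type(expr):
                flat.extend(s.children)  # type: ignore[attr-defined]
            else:
                flat.append(s)
        seen: list[Expr] = []
        for s in flat:
            if s not in seen:
                seen.append(s)
        literals = {(c.child.name, True) if isinstance(c, Not) and isinstance(c.child, Var)
                    else (c.name, False)
                    for c in seen if isinstance(c, Var)
                    or (isinstance(c, Not) and isinstance(c.child, Var))}
        names = {n for n, _ in literals}
        if len(literals) > len(names):  # some x and NOT x both present
            return absorber
        if not seen:
            return neutral
        return (conj if is_and else disj)(seen)
    raise TypeError(type(expr))


def truth_table(expr: Expr, order: list[str]) -> list[bool]:
    """Evaluate ``expr`` on every assignment of ``order`` (row i = bits of i)."""
    rows = []
    for i in range(1 << len(order)):
        state = {name: (i >> b) & 1 for b, name in enumerate(order)}
        rows.append(expr.evaluate(state))
    return rows


def signed_regulators(expr: Expr) -> dict[str, set[str]]:
    """Map regulator name -> set of parities ('+'/'-') of its occurrences.

    A regulator occurring only under an even number of negations is positive,
    only odd is negative; both makes it dual.
    """
    out: dict[str, set[str]] = {}

    def walk(e: Expr, parity: bool) -> None:
        if isinstance(e, Var):
            out.setdefault(e.name, set()).add("-" if parity else "+")
        elif isinstance(e, Not):
            walk(e.child, not parity)
        elif isinstance(e, (And, Or)):
            for c in e.children:
                walk(c, parity)

    walk(expr, False)
    return out


def to_native(expr: Expr, parent: str = "or") -> str:
    """Render in the native rule syntax (lowercase and/or/not, minimal parens)."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return "TRUE" if expr.value else "FALSE"
    if isinstance(expr, Not):
        inner = to_native(expr.child, "not")
        if isinstance(expr.child, (And, Or)):
            inner = f"({inner})"
        return f"not {inner}"
    if isinstance(expr, And):
        parts = [f"({to_native(c, 'and')})" if isinstance(c, Or) else to_native(c, "and")
                 for c in expr.children]
        return " and ".join(parts)
    if isinstance(expr, Or):
        return " or ".join(to_native(c, "or") for c in expr.children)
    raise TypeError(type(expr))


def to_bnet(expr: Expr) -> str:
    """Render with BoolNet-style operators (&, |, !)."""
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Const):
        return "1" if expr.value else "0"
    if isinstance(expr, Not):
        inner = to_bnet(expr.child)
        if isinstance(expr.child, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(expr, And):
        parts = [f"({to_bnet(c)})" if isinstance(c, Or) else to_bnet(c)
                 for c in expr.children]
        return " & ".join(parts)
    if isinstance(expr, Or):
        return " | ".join(to_bnet(c) for c in expr.children)
    raise TypeError(type(expr))


def equivalent(a: Expr, b: Expr) -> bool:
    """Truth-table equality over the union of referenced variables."""
    order = sorted(a.variables() | b.variables())
    if len(order) > 20:
        raise ValueError("too many variables for exhaustive comparison")
    return truth_table(a, order) == truth_table(b, order)
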