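"""Expression trees for constraint right/left-hand sides and guards.

Expressions are built with ordinary Python operators over :func:`ref`
(attribute references), constants, the built-in tick counter :data:`TIME`
and the grid scale factor :data:`DT`.  A reference carries a signed tick
offset: ``prev(v)`` is the value one tick in the past (the ``‵v`` operator of
the series-variable notation) and ``nxt(v)`` the value one tick ahead
(``v‵``).  Offsets may reach arbitrarily far into the past but at most one
tick into the future.

Equality between two expressions is expressed with :func:`eq` (a constraint),
while guard relations for conditional constraints are built with the
comparison operators ``< <= > >=`` or the methods ``.eq()`` / ``.ne()``
(``==`` is left untouched so expressions behave normally in containers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Iterator

from .errors import CobDefinitionError

Number = float | int

__all__ = [
    "Expr", "Const", "Ref", "TimeRef", "DtRef", "BinOp", "Neg", "Call",
    "Rel", "BoolOp", "ref", "prev", "nxt", "const", "call",
    "TIME", "DT", "Unknown", "EvalContext", "eval_expr", "eval_guard",
    "iter_refs", "substitute_refs",
]


class Unknown(Exception):
    """Raised during evaluation when a referenced value is not yet known."""

    def __init__(self, key: tuple[str, int]):
        super().__init__(f"unknown value {key[0]} at tick {key[1]}")
        self.key = key


class Expr:
    """Base expression node; subclasses are small frozen records."""

    def __add__(self, other: Any) -> "Expr":
        return BinOp("+", self, wrap(other))

    def __radd__(self, other: Any) -> "Expr":
        return BinOp("+", wrap(other), self)

    def __sub__(self, other: Any) -> "Expr":
        return BinOp("-", self, wrap(other))

    def __rsub__(self, other: Any) -> "Expr":
        return BinOp("-", wrap(other), self)

    def __mul__(self, other: Any) -> "Expr":
        return BinOp("*", self, wrap(other))

    def __rmul__(self, other: Any) -> "Expr":
        return BinOp("*", wrap(other), self)

    def __truediv__(self, other: Any) -> "Expr":
        return BinOp("/", self, wrap(other))

    def __rtruediv__(self, other: Any) -> "Expr":
        return BinOp("/", wrap(other), self)

    def __pow__(self, other: Any) -> "Expr":
        return BinOp("**", self, wrap(other))

    def __neg__(self) -> "Expr":
        return Neg(self)

    # Comparison operators build guard relations (not booleans).
    def __lt__(self, other: Any) -> "Rel":
        return Rel("<", self, wrap(other))

    def __le__(self, other: Any) -> "Rel":
        return Rel("<=", self, wrap(other))

    def __gt__(self, other: Any) -> "Rel":
        return Rel(">", self, wrap(other))

    def __ge__(self, other: Any) -> "Rel":
        return Rel(">=", self, wrap(other))

    def eq(self, other: Any) -> "Rel":
        return Rel("==", self, wrap(other))

    def ne(self, other: Any) -> "Rel":
        return Rel("!=", self, wrap(other))


@dataclass(frozen=True)
class Const(Expr):
    value: Number | str


@dataclass(frozen=True)
class Ref(Expr):
    """Reference to an attribute, optionally shifted in time.

    ``name`` is a (possibly dotted) attribute path, relative to the owning
    class until instantiation resolves it to an absolute store path.  The
    placeholder prefix ``"$."`` denotes the running element of a quantified
    constraint's component array.
    """

    name: str
    offset: int = 0

    def __post_init__(self) -> None:
        if self.offset > 1:
            raise CobDefinitionError(
                f"reference {self.name!r} looks more than one tick into the "
                f"future (offset {self.offset}); only the next tick may be bound")


@dataclass(frozen=True)
class TimeRef(Expr):
    """The built-in tick counter (starts at 1 by default)."""


@dataclass(frozen=True)
class DtRef(Expr):
    """The grid scale factor converting ticks to model time (ms per tick)."""


@dataclass(frozen=True)
class BinOp(Expr):
    op: str
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Neg(Expr):
    operand: Expr


class Call(Expr):
    """Application of a registered pure Python function to sub-expressions."""

    __slots__ = ("fn", "args", "name")

    def __init__(self, fn: Callable[..., Any], args: tuple, name: str | None = None):
        self.fn = fn
        self.args = tuple(wrap(a) for a in args)
        self.name = name or getattr(fn, "__name__", "fn")


@dataclass(frozen=True)
class Rel:
    """A relational guard; evaluates to a bool."""

    op: str
    left: Expr
    right: Expr

    def __and__(self, other: "Rel | BoolOp") -> "BoolOp":
        return BoolOp("and", (self, other))

    def __or__(self, other: "Rel | BoolOp") -> "BoolOp":
        return BoolOp("or", (self, other))

    def __invert__(self) -> "BoolOp":
        return BoolOp("not", (self,))


@dataclass(frozen=True)
class BoolOp:
    op: str
    operands: tuple

    def __and__(self, other: "Rel | BoolOp") -> "BoolOp":
        return BoolOp("and", (self, other))

    def __or__(self, other: "Rel | BoolOp") -> "BoolOp":
        return BoolOp("or", (self, other))

    def __invert__(self) -> "BoolOp":
        return BoolOp("not", (self,))


TIME = TimeRef()
DT = DtRef()


def wrap(x: Any) -> Expr:
    if isinstance(x, Expr):
        return x
    if isinstance(x, (int, float, str)):
        return Const(x)
    raise TypeError(f"cannot use {type(x).__name__} in a constraint expression")


def ref(name: str, offset: int = 0) -> Ref:
    return Ref(name, offset)


def const(value: Number | str) -> Const:
    return Const(value)


def call(fn: Callable[..., Any], *args: Any, name: str | None = None) -> Call:
    return Call(fn, args, name)


def prev(r: Ref, by: int = 1) -> Ref:
    """Shift a reference ``by`` ticks into the past (the back-quote operator)."""
    if not isinstance(r, Ref):
        raise CobDefinitionError("prev()/nxt() apply to attribute references only")
    return Ref(r.name, r.offset - by)


def nxt(r: Ref) -> Ref:
    """Shift a reference one tick into the future (the forward-quote operator)."""
    if not isinstance(r, Ref):
        raise CobDefinitionError("prev()/nxt() apply to attribute references only")
    return Ref(r.name, r.offset + 1)


@dataclass
class EvalContext:
    """Evaluation environment: a value lookup plus the current tick and dt.

    ``lookup(path, tick)`` returns the stored value or raises
    :class:`Unknown`; an ``overlay`` maps ``(path, tick)`` keys to trial
    values during solving and takes precedence.
    """

    lookup: Callable[[str, int], Any]
    k: int
    dt: float
    overlay: dict | None = None

    def value(self, name: str, offset: int) -> Any:
        tick = self.k + offset
        if self.overlay is not None:
            key = (name, tick)
            if key in self.overlay:
                return self.overlay[key]
        return self.lookup(name, tick)


def eval_expr(e: Expr, ctx: EvalContext) -> Any:
    if type(e) is Const:
        return e.value
    if type(e) is Ref:
        return ctx.value(e.name, e.offset)
    if type(e) is BinOp:
        a = eval_expr(e.left, ctx)
        b = eval_expr(e.right, ctx)
        op = e.op
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return a / b
        if op == "**":
            return a ** b
        raise CobDefinitionError(f"unknown operator {op!r}")
    if type(e) is Neg:
        return -eval_expr(e.operand, ctx)
    if type(e) is Call:
        return e.fn(*(eval_expr(a, ctx) for a in e.args))
    if type(e) is TimeRef:
        return ctx.k
    if type(e) is DtRef:
        return ctx.dt
    raise CobDefinitionError(f"cannot evaluate node {type(e).__name__}")


def eval_guard(g: Rel | BoolOp, ctx: EvalContext) -> bool:
    if isinstance(g, Rel):
        a = eval_expr(g.left, ctx)
        b = eval_expr(g.right, ctx)
        op = g.op
        if op == "==":
            if isinstance(a, str) or isinstance(b, str):
                return a == b
            return math.isclose(a, b, rel_tol=0.0, abs_tol=1e-12)
        if op == "!=":
            if isinstance(a, str) or isinstance(b, str):
                return a != b
            return not math.isclose(a, b, rel_tol=0.0, abs_tol=1e-12)
        if op == "<":
            return a < b
        if op == "<=":
            return a <= b
        if op == ">":
            return a > b
        if op == ">=":
            return a >= b
        raise CobDefinitionError(f"unknown relation {op!r}")
    if isinstance(g, BoolOp):
        if g.op == "and":
            return all(eval_guard(o, ctx) for o in g.operands)
        if g.op == "or":
            return any(eval_guard(o, ctx) for o in g.operands)
        if g.op == "not":
            return not eval_guard(g.operands[0], ctx)
    raise CobDefinitionError(f"cannot evaluate guard {type(g).__name__}")


def iter_refs(node: Expr | Rel | BoolOp) -> Iterator[Ref]:
    """Yield every attribute reference in an expression or guard tree."""
    if isinstance(node, Ref):
        yield node
    elif isinstance(node, BinOp):
        yield from iter_refs(node.left)
        yield from iter_refs(node.right)
    elif isinstance(node, Neg):
        yield from iter_refs(node.operand)
    elif isinstance(node, Call):
        for a in node.args:
            yield from iter_refs(a)
    elif isinstance(node, Rel):
        yield from iter_refs(node.left)
        yield from iter_refs(node.right)
    elif isinstance(node, BoolOp):
        for o in node.operands:
            yield from iter_refs(o)


def substitute_refs(node, mapping: Callable[[Ref], Expr]):
    """Rebuild a tree with every :class:`Ref` replaced via ``mapping``."""
    if isinstance(node, Ref):
        return mapping(node)
    if isinstance(node, BinOp):
        return BinOp(node.op, substitute_refs(node.left, mapping),
                     substitute_refs(node.right, mapping))
    if isinstance(node, Neg):
        return Neg(substitute_refs(node.operand, mapping))
    if isinstance(node, Call):
        return Call(node.fn, tuple(substitute_refs(a, mapping) for a in node.args),
                    node.name)
    if isinstance(node, Rel):
        return Rel(node.op, substitute_refs(node.left, mapping),
                   substitute_refs(node.right, mapping))
    if isinstance(node, BoolOp):
        return BoolOp(node.op, tuple(substitute_refs(o, mapping) for o in node.operands))
    return node
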