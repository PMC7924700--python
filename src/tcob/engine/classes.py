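"""Constrained-object class definitions.

A class bundles typed attribute declarations, declarative constraints and an
optional constructor (parameter names plus creational constraints).  Classes
may extend a parent class; the effective attribute and constraint sets are
the union over the inheritance chain, and redeclaring an inherited attribute
is a definition error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import CobDefinitionError
from .expr import BoolOp, Expr, Rel, iter_refs, wrap

__all__ = [
    "AttrDecl", "series", "scalar", "component", "comp_array",
    "Simple", "Conditional", "ForAll", "SumEq", "Constructor",
    "CobClassDef", "define_class", "eq", "cond", "forall", "sum_eq",
]

ELEMENT = "$"  # placeholder path segment for the running array element


@dataclass(frozen=True)
class AttrDecl:
    """Declaration of one attribute of a constrained-object class."""

    name: str
    kind: str  # 'scalar' | 'series' | 'component' | 'array'
    cls: Optional["CobClassDef"] = None
    init: dict = field(default_factory=dict)  # tick -> value, series only
    doc: str = ""


def series(name: str, init: dict | None = None, doc: str = "") -> AttrDecl:
    """Declare a series variable (one value per tick)."""
    return AttrDecl(name, "series", init=dict(init or {}), doc=doc)


def scalar(name: str, doc: str = "") -> AttrDecl:
    """Declare a time-invariant attribute (a parameter or solved constant)."""
    return AttrDecl(name, "scalar", doc=doc)


def component(name: str, cls: "CobClassDef | None" = None, doc: str = "") -> AttrDecl:
    """Declare an aggregated component object."""
    return AttrDecl(name, "component", cls=cls, doc=doc)


def comp_array(name: str, cls: "CobClassDef | None" = None, doc: str = "") -> AttrDecl:
    """Declare an array of component objects (static size, fixed at creation)."""
    return AttrDecl(name, "array", cls=cls, doc=doc)


@dataclass(frozen=True)
class Simple:
    """A simple equational constraint ``lhs = rhs``."""

    lhs: Expr
    rhs: Expr
    label: str = ""


@dataclass(frozen=True)
class Conditional:
    """``guard --> consequents``: when the guard holds at a tick, every
    consequent equation is enforced (possibly binding next-tick values)."""

    guard: Rel | BoolOp
    then: tuple[Simple, ...]
    label: str = ""


@dataclass(frozen=True)
class ForAll:
    """Quantified constraint: the body holds for every element of ``array``;
    body references use the ``$.attr`` placeholder path."""

    array: str
    body: Simple
    label: str = ""


@dataclass(frozen=True)
class SumEq:
    """Aggregate constraint: ``sum(term over array elements) = total``."""

    array: str
    term: Expr
    total: Expr
    label: str = ""


Constraint = Simple | Conditional | ForAll | SumEq


@dataclass(frozen=True)
class Constructor:
    params: tuple[str, ...] = ()
    creational: tuple[Simple, ...] = ()


def eq(lhs, rhs, label: str = "") -> Simple:
    return Simple(wrap(lhs), wrap(rhs), label)


def cond(guard: Rel | BoolOp, then: Sequence[Simple], label: str = "") -> Conditional:
    return Conditional(guard, tuple(then), label)


def forall(array: str, body: Simple, label: str = "") -> ForAll:
    return ForAll(array, body, label)


def sum_eq(array: str, term, total, label: str = "") -> SumEq:
    return SumEq(array, wrap(term), wrap(total), label)


@dataclass(frozen=True)
class CobClassDef:
    name: str
    parent: Optional["CobClassDef"] = None
    attributes: tuple[AttrDecl, ...] = ()
    constraints: tuple[Constraint, ...] = ()
    constructor: Constructor = Constructor()

    def merged_attributes(self) -> dict[str, AttrDecl]:
        merged: dict[str, AttrDecl] = {}
        if self.parent is not None:
            merged.update(self.parent.merged_attributes())
        for a in self.attributes:
            if a.name in merged:
                raise CobDefinitionError(
                    f"class {self.name!r} redeclares inherited attribute {a.name!r}")
            merged[a.name] = a
        return merged

    def merged_constraints(self) -> tuple[Constraint, ...]:
        base = self.parent.merged_constraints() if self.parent is not None else ()
        return base + self.constraints


def _check_symbols(cls: CobClassDef) -> None:
    attrs = cls.merged_attributes()
    params = set(cls.constructor.params)

    def check(node, in_quantified: bool, where: str) -> None:
        for r in iter_refs(node):
            head = r.name.split(".", 1)[0]
            if head == ELEMENT:
                if not in_quantified:
                    raise CobDefinitionError(
                        f"class {cls.name!r}: element placeholder '$' used outside "
                        f"a quantified constraint ({where})")
                continue
            if head not in attrs and head not in params:
                raise CobDefinitionError(
                    f"class {cls.name!r}: unknown symbol {head!r} in {where}")

    for c in cls.merged_constraints():
        if isinstance(c, Simple):
            check(c.lhs, False, "constraint")
            check(c.rhs, False, "constraint")
        elif isinstance(c, Conditional):
            check(c.guard, False, "conditional guard")
            for s in c.then:
                check(s.lhs, False, "conditional consequent")
                check(s.rhs, False, "conditional consequent")
        elif isinstance(c, ForAll):
            if c.array not in attrs or attrs[c.array].kind != "array":
                raise CobDefinitionError(
                    f"class {cls.name!r}: forall over undeclared array {c.array!r}")
            check(c.body.lhs, True, "forall body")
            check(c.body.rhs, True, "forall body")
        elif isinstance(c, SumEq):
            if c.array not in attrs or attrs[c.array].kind != "array":
                raise CobDefinitionError(
                    f"class {cls.name!r}: sum over undeclared array {c.array!r}")
            check(c.term, True, "sum term")
            check(c.total, False, "sum total")
    for s in cls.constructor.creational:
        check(s.lhs, False, "creational constraint")
        check(s.rhs, False, "creational constraint")


def define_class(name: str,
                 parent: CobClassDef | None = None,
                 attributes: Sequence[AttrDecl] = (),
                 constraints: Sequence[Constraint] = (),
                 constructor: Constructor | None = None) -> CobClassDef:
    """Define and validate a constrained-object class.

    Raises :class:`CobDefinitionError` on duplicate attributes (after the
    inheritance merge), on constraint symbols that are not declared, and on
    references more than one tick into the future.
    """
    own_names = [a.name for a in attributes]
    dup = {n for n in own_names if own_names.count(n) > 1}
    if dup:
        raise CobDefinitionError(
            f"class {name!r} declares duplicate attribute(s): {sorted(dup)}")
    cls = CobClassDef(name=name, parent=parent, attributes=tuple(attributes),
                      constraints=tuple(constraints),
                      constructor=constructor or Constructor())
    cls.merged_attributes()  # raises on inherited redeclaration
    _check_symbols(cls)
    return cls
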