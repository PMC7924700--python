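"""The shared constraint store: instances, series values, per-tick solving.

Time advances in integer ticks (the built-in ``Time`` counter), starting at 1
by default and increasing by one per step; a grid scale factor ``dt``
converts ticks to model time in milliseconds.  Each step instantiates every
registered constraint at the current tick (substituting already-solved past
values), evaluates conditional guards on determined values, solves the
remaining unknowns and verifies that every residual is within the store
tolerance.  Solved values are immutable: a second binding must agree or the
step fails with an inconsistency error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .classes import (AttrDecl, CobClassDef, Conditional, Constructor, ForAll,
                      Simple, SumEq, ELEMENT)
from .errors import (CobDefinitionError, CobInconsistencyError,
                     CobParameterError, CobUnderdeterminedError)
from .expr import (BinOp, BoolOp, Const, EvalContext, Expr, Ref, Rel, Unknown,
                   eval_expr, eval_guard, iter_refs, substitute_refs)
from .solver import solve_block, solve_single
from .trace import TraceTable

__all__ = ["TimeGrid", "CobInstance", "ConstraintStore", "run"]


@dataclass(frozen=True)
class TimeGrid:
    """Discrete simulation clock.

    ``dt`` is the scale factor converting the tick counter to model time
    (ms per tick); ticks run from ``t_start`` (default 1) to ``t_end``
    inclusive.
    """

    t_end: int
    dt: float = 0.01
    t_start: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise CobParameterError(f"dt must be positive, got {self.dt}")
        if self.t_end < self.t_start:
            raise CobParameterError(
                f"t_end ({self.t_end}) precedes t_start ({self.t_start})")

    @property
    def n_ticks(self) -> int:
        return self.t_end - self.t_start + 1

    def ticks(self) -> range:
        return range(self.t_start, self.t_end + 1)

    def time(self, k: int) -> float:
        return k * self.dt

    def times(self) -> np.ndarray:
        return np.array([self.time(k) for k in self.ticks()])


@dataclass
class _BoundSimple:
    """A constraint with references resolved to absolute store paths."""

    lhs: Expr
    rhs: Expr
    label: str
    creational: bool = False
    refs: tuple[tuple[str, int], ...] = ()
    min_off: int = 0


@dataclass
class _BoundConditional:
    guard: Rel | BoolOp
    then: tuple[_BoundSimple, ...]
    label: str
    guard_refs: tuple[tuple[str, int], ...] = ()
    min_off: int = 0


class CobInstance:
    """A constrained object living in a shared store."""

    def __init__(self, path: str, classdef: CobClassDef, store: "ConstraintStore"):
        self.path = path
        self.classdef = classdef
        self.store = store
        self.components: dict[str, "CobInstance"] = {}
        self.component_arrays: dict[str, list["CobInstance"]] = {}

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{self.classdef.name} {self.path!r}>"

    def attr_path(self, name: str) -> str:
        """Absolute store path of a (possibly dotted) attribute name."""
        head, _, rest = name.partition(".")
        if head in self.components:
            sub = self.components[head]
            return sub.attr_path(rest) if rest else sub.path
        if rest:
            raise CobDefinitionError(
                f"{self.classdef.name}: {head!r} is not a component "
                f"(in reference {name!r})")
        return f"{self.path}.{head}"

    def set_initial(self, attr: str, tick: int, value: Any) -> None:
        """Provide an explicit series value at a tick (an initializer)."""
        self.store.set_value(self.attr_path(attr), tick, value)

    def series(self, attr: str) -> dict[int, Any]:
        return self.store.series[self.attr_path(attr)]

    def series_array(self, attr: str) -> np.ndarray:
        """Series values on the full grid as a float array (NaN where unset)."""
        d = self.series(attr)
        g = self.store.grid
        return np.array([d.get(k, math.nan) for k in g.ticks()], dtype=float)

    def scalar(self, attr: str) -> Any:
        return self.store.scalars[self.attr_path(attr)]

    def value(self, attr: str, tick: int) -> Any:
        return self.store.series[self.attr_path(attr)][tick]

    def add_constraint(self, c: Simple | Conditional, label: str = "") -> None:
        """Attach an extra constraint to this instance after creation."""
        self.store._bind_constraint(self, c, {})


class ConstraintStore:
    """Holds every instance, every solved value and every active constraint."""

    def __init__(self, grid: TimeGrid, tolerance: float = 1e-9):
        self.grid = grid
        self.tolerance = tolerance
        self.kinds: dict[str, str] = {}        # path -> 'scalar' | 'series'
        self.scalars: dict[str, Any] = {}
        self.series: dict[str, dict[int, Any]] = {}
        self.simples: list[_BoundSimple] = []
        self.conditionals: list[_BoundConditional] = []
        self.instances: dict[str, CobInstance] = {}
        self._satisfied: list[tuple[int, _BoundSimple]] = []
        self._next_tick = grid.t_start
        self._counters: dict[str, int] = {}

    # ------------------------------------------------------------------ setup

    def instantiate(self, classdef: CobClassDef, args: dict | None = None,
                    name: str | None = None) -> CobInstance:
        """Create an instance: register attributes, expand and bind constraints.

        ``args`` supplies constructor parameters, direct scalar bindings,
        pre-built component instances, and lists of instances for component
        arrays.  Quantified constraints expand over the array elements here,
        at creation time.
        """
        args = dict(args or {})
        if name is None:
            n = self._counters.get(classdef.name, 0) + 1
            self._counters[classdef.name] = n
            name = f"{classdef.name.lower()}{n}"
        if name in self.instances:
            raise CobParameterError(f"instance name {name!r} already in use")
        inst = CobInstance(name, classdef, self)
        self.instances[name] = inst

        attrs = classdef.merged_attributes()
        params = set(classdef.constructor.params)
        missing = params - set(args)
        if missing:
            raise CobParameterError(
                f"{classdef.name}: missing constructor argument(s) {sorted(missing)}")
        for key in args:
            if key not in params and key not in attrs:
                raise CobParameterError(
                    f"{classdef.name}: unexpected argument {key!r}")

        self._register_attributes(inst, attrs, args)
        param_values = {p: args[p] for p in params}
        for c in classdef.merged_constraints():
            self._bind_constraint(inst, c, {})
        for c in classdef.constructor.creational:
            self._bind_constraint(inst, c, param_values, creational=True)
        self._eager_creational_check(inst)
        return inst

    def _register_attributes(self, inst: CobInstance,
                             attrs: dict[str, AttrDecl], args: dict) -> None:
        for a in attrs.values():
            path = f"{inst.path}.{a.name}"
            if a.kind == "scalar":
                self.kinds[path] = "scalar"
                if a.name in args and not isinstance(args[a.name], (CobInstance, list)):
                    self.scalars[path] = args[a.name]
            elif a.kind == "series":
                self.kinds[path] = "series"
                self.series[path] = dict(a.init)
            elif a.kind == "component":
                if a.name in args:
                    sub = args[a.name]
                    if not isinstance(sub, CobInstance):
                        raise CobParameterError(
                            f"{inst.classdef.name}.{a.name}: expected an instance")
                else:
                    if a.cls is None:
                        raise CobDefinitionError(
                            f"{inst.classdef.name}.{a.name}: component has no class "
                            f"and no instance was supplied")
                    sub = self.instantiate(a.cls, name=f"{inst.path}.{a.name}")
                inst.components[a.name] = sub
            elif a.kind == "array":
                elems = args.get(a.name, [])
                if not all(isinstance(e, CobInstance) for e in elems):
                    raise CobParameterError(
                        f"{inst.classdef.name}.{a.name}: expected a list of instances")
                inst.component_arrays[a.name] = list(elems)

    def _resolve_ref(self, inst: CobInstance, r: Ref,
                     params: dict, element_path: str | None = None) -> Expr:
        head = r.name.split(".", 1)[0]
        if head == ELEMENT:
            if element_path is None:
                raise CobDefinitionError("'$' reference outside a quantified constraint")
            rest = r.name.partition(".")[2]
            # element_path is an absolute instance path; append the attribute
            path = self._abs_attr(element_path, rest)
            return self._mk_ref(path, r.offset)
        if head in params:
            if r.name != head:
                raise CobDefinitionError(
                    f"constructor parameter {head!r} has no attributes")
            return Const(params[head])
        path = inst.attr_path(r.name)
        return self._mk_ref(path, r.offset)

    def _abs_attr(self, inst_path: str, attr: str) -> str:
        root, _, rest = inst_path.partition(".")
        inst = self.instances[root]
        full = f"{rest}.{attr}" if rest else attr
        return inst.attr_path(full)

    def _mk_ref(self, path: str, offset: int) -> Ref:
        kind = self.kinds.get(path)
        if kind is None and path.split(".", 1)[0] in self.instances:
            raise CobDefinitionError(f"reference to whole object {path!r}; "
                                     f"name one of its attributes")
        if kind == "scalar":
            return Ref(path, 0)  # scalars carry no time index
        return Ref(path, offset)

    def _bind_constraint(self, inst: CobInstance, c, params: dict,
                         creational: bool = False) -> None:
        if isinstance(c, Simple):
            self.simples.append(self._bind_simple(inst, c, params, creational))
        elif isinstance(c, Conditional):
            guard = substitute_refs(
                c.guard, lambda r: self._resolve_ref(inst, r, params))
            then = tuple(self._bind_simple(inst, s, params, creational)
                         for s in c.then)
            grefs = tuple((r.name, r.offset) for r in iter_refs(guard))
            min_off = min([off for p, off in grefs
                           if self.kinds.get(p) == "series"] + [0])
            self.conditionals.append(_BoundConditional(
                guard, then, c.label or f"{inst.path}:cond",
                guard_refs=grefs, min_off=min_off))
        elif isinstance(c, ForAll):
            for elem in inst.component_arrays.get(c.array, []):
                body = Simple(
                    substitute_refs(c.body.lhs,
                                    lambda r: self._resolve_ref(inst, r, params, elem.path)),
                    substitute_refs(c.body.rhs,
                                    lambda r: self._resolve_ref(inst, r, params, elem.path)),
                    c.label or f"{inst.path}:forall[{elem.path}]")
                self.simples.append(self._finish_bound(body, creational))
        elif isinstance(c, SumEq):
            elems = inst.component_arrays.get(c.array, [])
            if not elems:
                raise CobParameterError(
                    f"{inst.path}: sum over empty component array {c.array!r}")
            terms = [substitute_refs(c.term,
                                     lambda r, e=e: self._resolve_ref(inst, r, params, e.path))
                     for e in elems]
            total = substitute_refs(c.total,
                                    lambda r: self._resolve_ref(inst, r, params))
            acc = terms[0]
            for t in terms[1:]:
                acc = BinOp("+", acc, t)
            body = Simple(acc, total, c.label or f"{inst.path}:sum[{c.array}]")
            self.simples.append(self._finish_bound(body, creational))
        else:
            raise CobDefinitionError(f"unsupported constraint type {type(c).__name__}")

    def _bind_simple(self, inst: CobInstance, s: Simple, params: dict,
                     creational: bool) -> _BoundSimple:
        lhs = substitute_refs(s.lhs, lambda r: self._resolve_ref(inst, r, params))
        rhs = substitute_refs(s.rhs, lambda r: self._resolve_ref(inst, r, params))
        return self._finish_bound(
            Simple(lhs, rhs, s.label or f"{inst.path}:{_brief(s)}"), creational)

    def _finish_bound(self, s: Simple, creational: bool) -> _BoundSimple:
        refs = tuple((r.name, r.offset)
                     for r in list(iter_refs(s.lhs)) + list(iter_refs(s.rhs)))
        series_offs = [off for p, off in refs if self.kinds.get(p) == "series"]
        return _BoundSimple(s.lhs, s.rhs, s.label, creational=creational,
                            refs=refs, min_off=min(series_offs, default=0))

    def _eager_creational_check(self, inst: CobInstance) -> None:
        """Solve/check creational constraints that involve no series values,
        so impossible constructors fail at creation rather than at run."""
        scalar_only = [c for c in self.simples
                       if c.creational and
                       all(self.kinds.get(p) == "scalar" for p, _ in c.refs)]
        progress = True
        while progress:
            progress = False
            for c in scalar_only:
                unk = [(p, self.grid.t_start) for p, _ in dict(c.refs).items()
                       if p not in self.scalars]
                ctx = self._ctx(self.grid.t_start)
                if not unk:
                    try:
                        l = eval_expr(c.lhs, ctx)
                        r = eval_expr(c.rhs, ctx)
                    except Unknown:
                        continue
                    self._require_equal(l, r, c.label, self.grid.t_start)
                elif len(set(unk)) == 1:
                    try:
                        self._solve_one(c, unk[0], self.grid.t_start)
                        progress = True
                    except Unknown:
                        continue

    def post(self, c: Simple | Conditional) -> None:
        """Register a constraint whose references are absolute store paths
        (wiring between already-created instances)."""
        shim = _AbsoluteNamespace(self)
        self._bind_constraint(shim, c, {})

    # ------------------------------------------------------------------ values

    def set_value(self, path: str, tick: int, value: Any) -> None:
        if self.kinds.get(path) != "series":
            raise CobParameterError(f"{path!r} is not a series variable")
        self._assign((path, tick), value, tick)

    def resolve_series(self, path: str, offset: int, k: int) -> Any:
        """Resolve a series reference ``path`` at tick ``k + offset``.

        Past references must land on a solved or initialized value; a past
        reference with no value raises the under-determined error.  A
        reference at the current or next tick with no value yet returns
        ``None`` — an unknown to be solved this step (offset 0) or posted for
        a future step (offset +1).
        """
        d = self.series[path]
        tick = k + offset
        if tick in d:
            return d[tick]
        if offset < 0:
            raise CobUnderdeterminedError(
                f"past reference {path!r} at tick {tick} precedes any "
                f"initialized value", tick=tick, unknowns=(path,))
        return None

    def _assign(self, key: tuple[str, int], value: Any, k: int) -> None:
        path, tick = key
        kind = self.kinds[path]
        container = self.scalars if kind == "scalar" else self.series[path]
        slot = path if kind == "scalar" else tick
        if slot in container:
            old = container[slot]
            if isinstance(old, str) or isinstance(value, str):
                same = old == value
            else:
                same = abs(old - value) <= self.tolerance * max(1.0, abs(old))
            if not same:
                raise CobInconsistencyError(
                    f"conflicting values for {path} at tick {tick}: "
                    f"{old!r} vs {value!r}", tick=k)
            return
        container[slot] = value

    def _lookup(self, name: str, tick: int) -> Any:
        kind = self.kinds.get(name)
        if kind == "scalar":
            if name in self.scalars:
                return self.scalars[name]
            raise Unknown((name, tick))
        if kind == "series":
            d = self.series[name]
            if tick in d:
                return d[tick]
            raise Unknown((name, tick))
        raise CobDefinitionError(f"unknown attribute path {name!r}")

    def _ctx(self, k: int, overlay: dict | None = None) -> EvalContext:
        return EvalContext(self._lookup, k=k, dt=self.grid.dt, overlay=overlay)

    # ------------------------------------------------------------------ stepping

    def _active_at(self, refs, min_off: int, k: int) -> bool:
        """A constraint is instantiable at tick ``k`` when every past series
        reference lands on an already-solved or initialized value (standard
        difference-equation warm-up: update rules only fire once one tick of
        history exists)."""
        if min_off == 0:
            return True
        for path, off in refs:
            if off < 0 and self.kinds.get(path) == "series":
                if (k + off) not in self.series[path]:
                    return False
        return True

    def _unknowns(self, c: _BoundSimple, k: int) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        for path, off in c.refs:
            kind = self.kinds[path]
            if kind == "scalar":
                if path not in self.scalars:
                    key = (path, k)
                    if key not in seen:
                        seen.add(key)
                        out.append(key)
            else:
                tick = k + off
                if tick not in self.series[path]:
                    key = (path, tick)
                    if key not in seen:
                        seen.add(key)
                        out.append(key)
        return out

    def step(self, k: int) -> None:
        """Solve tick ``k``: instantiate constraints, fire guards, solve,
        and verify every residual."""
        if k != self._next_tick:
            raise CobParameterError(
                f"steps must be consecutive: expected tick {self._next_tick}, got {k}")
        if k > self.grid.t_end:
            raise CobParameterError(f"tick {k} beyond t_end {self.grid.t_end}")

        pending: list[_BoundSimple] = []
        for c in self.simples:
            if c.creational and k != self.grid.t_start:
                continue
            if self._active_at(c.refs, c.min_off, k):
                pending.append(c)
        pending_cond: list[_BoundConditional] = []
        for cc in self.conditionals:
            if self._active_at(cc.guard_refs, cc.min_off, k):
                pending_cond.append(cc)

        satisfied: list[_BoundSimple] = []
        while True:
            progress = False
            remaining: list[_BoundSimple] = []
            for c in pending:
                unk = self._unknowns(c, k)
                if not unk:
                    ctx = self._ctx(k)
                    self._require_equal(eval_expr(c.lhs, ctx),
                                        eval_expr(c.rhs, ctx), c.label, k)
                    satisfied.append(c)
                    progress = True
                elif len(unk) == 1:
                    self._solve_one(c, unk[0], k)
                    satisfied.append(c)
                    progress = True
                else:
                    remaining.append(c)
            pending = remaining

            still: list[_BoundConditional] = []
            for cc in pending_cond:
                try:
                    fired = eval_guard(cc.guard, self._ctx(k))
                except Unknown:
                    still.append(cc)
                    continue
                progress = True
                if fired:
                    pending.extend(s for s in cc.then
                                   if self._active_at(s.refs, s.min_off, k))
            pending_cond = still

            if not progress:
                if pending:
                    solved = self._solve_simultaneous(pending, k)
                    satisfied.extend(solved)
                    pending = []
                    if pending_cond:
                        continue  # guards may now be determinable
                break

        self._satisfied.extend((k, c) for c in satisfied)
        self._next_tick = k + 1

    def _solve_one(self, c: _BoundSimple, key: tuple[str, int], k: int) -> None:
        # direct assignment when the unknown stands alone on one side
        for side, other in ((c.lhs, c.rhs), (c.rhs, c.lhs)):
            if isinstance(side, Ref):
                skey = (side.name, k if self.kinds[side.name] == "scalar"
                        else k + side.offset)
                if skey == key:
                    try:
                        value = eval_expr(other, self._ctx(k))
                    except Unknown:
                        break
                    self._assign(key, value, k)
                    return

        def f(x: float) -> float:
            ctx = self._ctx(k, overlay={key: x})
            l = eval_expr(c.lhs, ctx)
            r = eval_expr(c.rhs, ctx)
            if isinstance(l, str) or isinstance(r, str):
                raise CobDefinitionError(
                    f"{c.label}: cannot solve numerically over symbolic values")
            return l - r

        warm = self._warm_start(key, k)
        value = solve_single(f, tol=self.tolerance, x0=warm,
                             what=f"{c.label} (tick {k})")
        self._assign(key, value, k)

    def _warm_start(self, key: tuple[str, int], k: int) -> float:
        path, tick = key
        if self.kinds[path] == "series":
            prev = self.series[path].get(tick - 1)
            if isinstance(prev, (int, float)):
                return float(prev)
        return 0.0

    def _solve_simultaneous(self, pending: list[_BoundSimple], k: int
                            ) -> list[_BoundSimple]:
        keys = sorted({key for c in pending for key in self._unknowns(c, k)})
        index = {key: i for i, key in enumerate(keys)}
        if not keys:
            return []

        def residual(c: _BoundSimple) -> Callable[[np.ndarray], float]:
            def f(x: np.ndarray) -> float:
                overlay = {key: x[i] for key, i in index.items()}
                ctx = self._ctx(k, overlay=overlay)
                return eval_expr(c.lhs, ctx) - eval_expr(c.rhs, ctx)
            return f

        unknown_sets = [{index[key] for key in self._unknowns(c, k)}
                        for c in pending]
        warm = np.array([self._warm_start(key, k) for key in keys])
        try:
            sol = solve_block([residual(c) for c in pending], unknown_sets,
                              len(keys), tol=self.tolerance, warm=warm,
                              labels=[c.label for c in pending])
        except (CobUnderdeterminedError, CobInconsistencyError) as e:
            e.tick = k
            if isinstance(e, CobUnderdeterminedError) and not e.unknowns:
                e.unknowns = tuple(f"{p}@{t}" for p, t in keys)
            raise
        for key, i in index.items():
            self._assign(key, float(sol[i]), k)
        return pending

    def _require_equal(self, l: Any, r: Any, label: str, k: int) -> None:
        if isinstance(l, str) or isinstance(r, str):
            if l != r:
                raise CobInconsistencyError(
                    f"{label}: {l!r} != {r!r} at tick {k}", tick=k,
                    constraints=(label,))
            return
        if abs(l - r) > self.tolerance * max(1.0, abs(l), abs(r)):
            raise CobInconsistencyError(
                f"{label}: residual {l - r:g} at tick {k}", tick=k,
                constraints=(label,))

    # ------------------------------------------------------------------ results

    def run(self) -> TraceTable:
        """Step every tick of the grid and return the full trace table."""
        for k in self.grid.ticks():
            try:
                self.step(k)
            except (CobInconsistencyError, CobUnderdeterminedError) as e:
                if e.tick is None:
                    e.tick = k
                raise
        return self.trace()

    def trace(self) -> TraceTable:
        return TraceTable.from_store(self)

    def residual_sweep(self) -> float:
        """Re-evaluate every constraint instantiated during the run and
        return the worst absolute residual (symbolic equalities count 0 when
        they hold, infinity otherwise)."""
        worst = 0.0
        for k, c in self._satisfied:
            ctx = self._ctx(k)
            l = eval_expr(c.lhs, ctx)
            r = eval_expr(c.rhs, ctx)
            if isinstance(l, str) or isinstance(r, str):
                worst = max(worst, 0.0 if l == r else math.inf)
            else:
                worst = max(worst, abs(l - r))
        return worst

    @property
    def n_constraints_checked(self) -> int:
        return len(self._satisfied)


def run(store: ConstraintStore, grid: TimeGrid | None = None) -> TraceTable:
    """Module-level convenience mirroring ``store.run()``."""
    if grid is not None and grid != store.grid:
        raise CobParameterError("store was built on a different grid")
    return store.run()


class _AbsoluteNamespace:
    """Instance-shaped shim used by :meth:`ConstraintStore.post`: attribute
    names are taken as absolute store paths."""

    def __init__(self, store: "ConstraintStore"):
        self.store = store
        self.path = "store"

    def attr_path(self, name: str) -> str:
        if name not in self.store.kinds:
            raise CobDefinitionError(f"unknown store path {name!r}")
        return name

    @property
    def component_arrays(self):
        return {}


def _brief(s: Simple) -> str:
    def side(e: Expr) -> str:
        if isinstance(e, Ref):
            return e.name
        if isinstance(e, Const):
            return repr(e.value)
        return type(e).__name__
    return f"{side(s.lhs)}={side(s.rhs)}"
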