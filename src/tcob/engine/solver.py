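"""Numeric solving strategies behind the constraint store.

The per-timestep systems produced by difference-equation models are solved in
three escalating stages:

1. *Local propagation*: any equation with a single unknown is solved
   immediately — by direct assignment when the unknown stands alone on one
   side, otherwise by probing the residual at a few points (linear equations
   are solved exactly from two probes, nonlinear ones by a damped secant
   iteration).
2. *Simultaneous linear blocks*: remaining equations are probed for joint
   linearity in their unknowns; if linear, the block is solved with
   :func:`numpy.linalg` (least squares when over-determined), with
   singularity mapped to under-determined / inconsistent errors.
3. *Nonlinear blocks*: a damped Gauss–Seidel sweep (secant updates, damping
   0.5, tolerance 1e-9, at most 100 iterations).

All stages are order-independent for determined systems: every unknown
receives the unique value consistent with the constraints, and conflicting
assignments raise rather than overwrite.
"""

from __future__ import annotations

import math
from typing import Any, Callable, Sequence

import numpy as np

from .classes import Simple, eq  # noqa: F401  (eq re-exported for convenience)
from .errors import (CobConvergenceError, CobDefinitionError,
                     CobInconsistencyError, CobUnderdeterminedError)
from .expr import EvalContext, Unknown, eval_expr, iter_refs

__all__ = ["solve_single", "solve_block", "solve_system"]

_PROBE_SETS = ((0.0, 1.0, 2.0), (1.0, 2.0, 3.0), (0.5, 1.5, 2.5))


def _linear_from_probes(f: Callable[[float], float], probes: Sequence[float],
                        lin_tol: float = 1e-8):
    """Try to read ``f`` as an affine function from three probe points.

    Returns ``(slope, intercept_at_0)`` if the second difference vanishes to
    within ``lin_tol`` relative to the residual scale, else ``None``.
    """
    try:
        f0, f1, f2 = (f(p) for p in probes)
    except (ZeroDivisionError, OverflowError, ValueError):
        return None
    if not all(math.isfinite(v) for v in (f0, f1, f2)):
        return None
    scale = max(abs(f0), abs(f1), abs(f2), 1.0)
    # probes are equally spaced: curvature shows up in the second difference
    if abs(f0 - 2.0 * f1 + f2) > lin_tol * scale:
        return None
    slope = (f1 - f0) / (probes[1] - probes[0])
    intercept = f0 - slope * probes[0]
    return slope, intercept


def solve_single(f: Callable[[float], float], tol: float = 1e-9,
                 x0: float = 0.0, damping: float = 0.5,
                 max_iter: int = 100, what: str = "equation") -> float:
    """Solve ``f(x) = 0`` for a single unknown.

    Linear residuals are solved exactly; nonlinear ones by damped secant
    iteration started at ``x0``.
    """
    for probes in _PROBE_SETS:
        lin = _linear_from_probes(f, probes)
        if lin is None:
            continue
        slope, intercept = lin
        scale = max(abs(intercept), 1.0)
        if abs(slope) < 1e-14 * scale:
            if abs(intercept) <= tol * scale:
                raise CobUnderdeterminedError(
                    f"{what}: any value satisfies it (degenerate relation)")
            raise CobInconsistencyError(
                f"{what}: unsatisfiable (residual {intercept:g} independent of the unknown)")
        return -intercept / slope
    # nonlinear: damped secant from x0
    x_prev, x = x0, x0 + 1.0
    try:
        f_prev = f(x_prev)
    except (ZeroDivisionError, OverflowError, ValueError):
        x_prev, x = 1.0, 2.0
        f_prev = f(x_prev)
    for it in range(max_iter):
        fx = f(x)
        if abs(fx) <= tol:
            return x
        denom = fx - f_prev
        if denom == 0.0:
            x_new = x + 1.0
        else:
            x_new = x - fx * (x - x_prev) / denom
        x_prev, f_prev = x, fx
        x = x + damping * (x_new - x)
    raise CobConvergenceError(
        f"{what}: secant iteration did not converge in {max_iter} iterations",
        iterations=max_iter)


def _match_equations(unknown_sets: list[set], n_unknowns: int) -> list[int | None]:
    """Greedy bipartite matching: pair each equation with one unknown index.

    Equations left unmatched act as consistency checks; unknowns left
    unmatched mean the block is under-determined.
    """
    order = sorted(range(len(unknown_sets)), key=lambda j: len(unknown_sets[j]))
    assigned: list[int | None] = [None] * len(unknown_sets)
    taken: set[int] = set()
    for j in order:
        for i in sorted(unknown_sets[j]):
            if i not in taken:
                assigned[j] = i
                taken.add(i)
                break
    return assigned


def solve_block(residuals: list[Callable[[np.ndarray], float]],
                unknown_sets: list[set],
                n: int,
                tol: float = 1e-9,
                warm: np.ndarray | None = None,
                damping: float = 0.5,
                max_iter: int = 100,
                labels: Sequence[str] = ()) -> np.ndarray:
    """Solve a block of simultaneous equations in ``n`` unknowns.

    ``residuals[j]`` maps a full unknown vector to that equation's residual;
    ``unknown_sets[j]`` lists which unknown indices equation ``j`` touches.
    """
    m = len(residuals)
    labels = list(labels) or [f"eq{j}" for j in range(m)]
    if m < n:
        raise CobUnderdeterminedError(
            f"{n} unknowns but only {m} equations in the simultaneous block")

    # stage 2: joint linearity probe
    linear = True
    A = np.zeros((m, n))
    b = np.zeros(m)
    try:
        x0 = np.zeros(n)
        for j, f in enumerate(residuals):
            b[j] = f(x0)
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            for j, f in enumerate(residuals):
                A[j, i] = f(e) - b[j]
        # verify with an asymmetric test point
        xt = np.array([1.3 + 0.7 * i for i in range(n)])
        for j, f in enumerate(residuals):
            pred = A[j] @ xt + b[j]
            got = f(xt)
            scale = max(abs(pred), abs(got), 1.0)
            if not math.isfinite(got) or abs(got - pred) > 1e-8 * scale:
                linear = False
                break
    except (ZeroDivisionError, OverflowError, ValueError):
        linear = False

    if linear:
        x, rank = _solve_linear(A, b, n, tol, labels)
        return x

    # stage 3: damped Gauss–Seidel with secant updates
    assigned = _match_equations(unknown_sets, n)
    if len({i for i in assigned if i is not None}) < n:
        missing = n - len({i for i in assigned if i is not None})
        raise CobUnderdeterminedError(
            f"nonlinear block: {missing} unknown(s) cannot be matched to any equation")
    x = warm.copy() if warm is not None else np.zeros(n)
    for it in range(max_iter):
        worst = 0.0
        for j, f in enumerate(residuals):
            i = assigned[j]
            if i is None:
                continue
            fx = f(x)
            h = max(1e-7, 1e-7 * abs(x[i]))
            xp = x.copy()
            xp[i] += h
            slope = (f(xp) - fx) / h
            if slope != 0.0:
                x[i] += damping * (-fx / slope)
        for f in residuals:
            worst = max(worst, abs(f(x)))
        if worst <= tol:
            return x
    raise CobConvergenceError(
        f"nonlinear block did not converge in {max_iter} iterations "
        f"(worst residual {worst:g})", iterations=max_iter)


def _solve_linear(A: np.ndarray, b: np.ndarray, n: int, tol: float,
                  labels: Sequence[str]) -> tuple[np.ndarray, int]:
    m = A.shape[0]
    x, res, rank, sv = np.linalg.lstsq(A, -b, rcond=None)
    if rank < n:
        raise CobUnderdeterminedError(
            f"singular linear system: rank {rank} < {n} unknowns")
    residual = A @ x + b
    bad = [labels[j] for j in range(m)
           if abs(residual[j]) > max(tol, 1e-9 * max(1.0, abs(b[j])))]
    if bad:
        raise CobInconsistencyError(
            "inconsistent linear system; violated: " + ", ".join(bad),
            constraints=tuple(bad))
    return x, rank


def solve_system(equations: Sequence[Simple], knowns: dict[str, Any],
                 tolerance: float = 1e-9) -> dict[str, Any]:
    """Solve a set of algebraic equations over named unknowns.

    ``equations`` are :class:`~tcob.engine.classes.Simple` relations whose
    references carry plain names (no time offsets); ``knowns`` fixes some of
    them.  Returns the full assignment (knowns plus solved unknowns).  The
    result does not depend on the order the equations are given in.
    """
    env = dict(knowns)
    names: set[str] = set()
    for c in equations:
        for r in iter_refs(c.lhs):
            names.add(r.name)
        for r in iter_refs(c.rhs):
            names.add(r.name)

    def lookup(name: str, tick: int) -> Any:
        if name in env:
            return env[name]
        raise Unknown((name, tick))

    def unknown_names(c: Simple) -> set[str]:
        return {r.name for r in list(iter_refs(c.lhs)) + list(iter_refs(c.rhs))
                if r.name not in env}

    pending = list(equations)
    progress = True
    while progress and pending:
        progress = False
        remaining = []
        for c in pending:
            unk = unknown_names(c)
            ctx = EvalContext(lookup, k=0, dt=1.0)
            if not unk:
                l, r = eval_expr(c.lhs, ctx), eval_expr(c.rhs, ctx)
                _check_equal(l, r, tolerance, c.label or "equation")
                progress = True
            elif len(unk) == 1:
                target = unk.pop()

                def f(x: float, c=c, target=target) -> float:
                    ctx = EvalContext(lookup, k=0, dt=1.0,
                                      overlay={(target, 0): x})
                    return eval_expr(c.lhs, ctx) - eval_expr(c.rhs, ctx)

                env[target] = solve_single(f, tol=tolerance,
                                           what=c.label or f"equation for {target}")
                progress = True
            else:
                remaining.append(c)
        pending = remaining

    if pending:
        keys = sorted({n for c in pending for n in unknown_names(c)})
        index = {name: i for i, name in enumerate(keys)}

        def residual(c: Simple) -> Callable[[np.ndarray], float]:
            def f(x: np.ndarray) -> float:
                overlay = {(name, 0): x[i] for name, i in index.items()}
                ctx = EvalContext(lookup, k=0, dt=1.0, overlay=overlay)
                return eval_expr(c.lhs, ctx) - eval_expr(c.rhs, ctx)
            return f

        sol = solve_block([residual(c) for c in pending],
                          [{index[n] for n in unknown_names(c)} for c in pending],
                          len(keys), tol=tolerance,
                          labels=[c.label or f"eq{j}" for j, c in enumerate(pending)])
        for name, i in index.items():
            env[name] = float(sol[i])
    missing = names - set(env)
    if missing:
        raise CobUnderdeterminedError(
            "no equation determines: " + ", ".join(sorted(missing)),
            unknowns=tuple(sorted(missing)))
    return env


def _check_equal(l: Any, r: Any, tol: float, label: str) -> None:
    if isinstance(l, str) or isinstance(r, str):
        if l != r:
            raise CobInconsistencyError(f"{label}: {l!r} != {r!r}",
                                        constraints=(label,))
        return
    if abs(l - r) > tol * max(1.0, abs(l), abs(r)):
        raise CobInconsistencyError(
            f"{label}: residual {l - r:g} exceeds tolerance", constraints=(label,))
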