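"""AC-circuit component library — the engine's canonical validation example.

Every component carries two series attributes on the shared grid: voltage
``V`` (volt) and current ``I`` (ampere).  Element laws are declarative
constraints: Ohm's law ``V = I·R`` for the resistor and the backward
difference form of ``I = C·dV/dt`` for the capacitor; a sinusoidal source
fixes its own voltage each tick.  Series/parallel composition adds the
Kirchhoff relations as quantified (forall) and aggregate (sum) constraints
expanded over the component array at creation time.

A closed circuit has no external terminal, so the top-level composite also
carries ``I = 0``; without it the source branch current is under-determined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from .engine import (DT, TIME, CobInstance, ConstraintStore, Constructor,
                     TimeGrid, call, comp_array, cond, define_class, eq,
                     forall, nxt, prev, ref, scalar, series, sum_eq)
from .engine.errors import CobParameterError

__all__ = [
    "CircuitParams", "component_class", "resistor_class", "capacitor_class",
    "source_class", "make_resistor", "make_capacitor", "make_source",
    "series_comp", "parallel_comp", "close_circuit", "sample_circuit",
]


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the demonstration circuit.

    R, R2 in ohm; Cap in farad; ``amplitude`` in volt and ``freq`` in rad/ms
    (the clock runs in milliseconds).
    """

    R: float = 1.0
    Cap: float = 1.0
    amplitude: float = 1.0
    freq: float = 1.0
    R2: float = 2.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.R2 <= 0:
            raise CobParameterError("resistance must be positive")
        if self.Cap <= 0:
            raise CobParameterError("capacitance must be positive")


@lru_cache(maxsize=None)
def component_class():
    """Abstract base: series voltage and current."""
    return define_class("component", attributes=[series("V"), series("I")])


@lru_cache(maxsize=None)
def resistor_class():
    return define_class(
        "resistor", parent=component_class(),
        attributes=[scalar("R")],
        constraints=[eq(ref("V"), ref("I") * ref("R"), label="ohm")],
        constructor=Constructor(("r",), (eq(ref("R"), ref("r")),)))


@lru_cache(maxsize=None)
def capacitor_class():
    # backward difference: I(k) = Cap * (V(k) - V(k-1)) / dt
    return define_class(
        "capacitor", parent=component_class(),
        attributes=[scalar("Cap")],
        constraints=[eq(ref("I"),
                        ref("Cap") * (ref("V") - prev(ref("V"))) / DT,
                        label="ampere")],
        constructor=Constructor(("c",), (eq(ref("Cap"), ref("c")),)))


@lru_cache(maxsize=None)
def source_class():
    return define_class(
        "source", parent=component_class(),
        attributes=[scalar("A"), scalar("W")],
        constraints=[eq(ref("V"),
                        ref("A") * call(math.sin, ref("W") * TIME * DT),
                        label="sine")],
        constructor=Constructor(("a", "w"),
                                (eq(ref("A"), ref("a")), eq(ref("W"), ref("w")))))


def make_resistor(store: ConstraintStore, R: float,
                  name: str | None = None) -> CobInstance:
    if R <= 0:
        raise CobParameterError(f"resistance must be positive, got {R}")
    return store.instantiate(resistor_class(), {"r": float(R)}, name=name)


def make_capacitor(store: ConstraintStore, Cap: float, v0: float = 0.0,
                   name: str | None = None) -> CobInstance:
    """Capacitor with the membrane-style difference constraint; the initial
    voltage (default 0) seeds the first tick."""
    if Cap <= 0:
        raise CobParameterError(f"capacitance must be positive, got {Cap}")
    inst = store.instantiate(capacitor_class(), {"c": float(Cap)}, name=name)
    inst.set_initial("V", store.grid.t_start, float(v0))
    return inst


def make_source(store: ConstraintStore, amplitude: float, freq: float,
                name: str | None = None) -> CobInstance:
    """Sinusoidal voltage source V(k) = amplitude·sin(freq·k·dt)."""
    return store.instantiate(source_class(),
                             {"a": float(amplitude), "w": float(freq)},
                             name=name)


@lru_cache(maxsize=None)
def _series_comp_class():
    return define_class(
        "series_comp", parent=component_class(),
        attributes=[comp_array("comps")],
        constraints=[
            forall("comps", eq(ref("$.I"), ref("I")), label="kcl-series"),
            sum_eq("comps", ref("$.V"), ref("V"), label="kvl-series"),
        ])


@lru_cache(maxsize=None)
def _parallel_comp_class():
    return define_class(
        "parallel_comp", parent=component_class(),
        attributes=[comp_array("comps")],
        constraints=[
            forall("comps", eq(ref("$.V"), ref("V")), label="kvl-parallel"),
            sum_eq("comps", ref("$.I"), ref("I"), label="kcl-parallel"),
        ])


def series_comp(store: ConstraintStore, components: Sequence[CobInstance],
                name: str | None = None) -> CobInstance:
    """Compose components in series: equal currents, voltages sum."""
    if len(components) < 1:
        raise CobParameterError("series composition needs at least one component")
    return store.instantiate(_series_comp_class(),
                             {"comps": list(components)}, name=name)


def parallel_comp(store: ConstraintStore, components: Sequence[CobInstance],
                  name: str | None = None) -> CobInstance:
    """Compose components in parallel: equal voltages, currents sum."""
    if len(components) < 1:
        raise CobParameterError("parallel composition needs at least one component")
    return store.instantiate(_parallel_comp_class(),
                             {"comps": list(components)}, name=name)


def close_circuit(top: CobInstance) -> None:
    """Mark a composite as a closed loop (no external terminal): I = 0."""
    top.add_constraint(eq(ref("I"), 0.0, label="closed-loop"))


def sample_circuit(store: ConstraintStore, params: CircuitParams | None = None
                   ) -> dict[str, CobInstance]:
    """The demonstration circuit: a resistor–capacitor series branch in
    parallel with a sinusoidal source and a second resistor."""
    p = params or CircuitParams()
    r1 = make_resistor(store, p.R, name="r1")
    c1 = make_capacitor(store, p.Cap, name="c1")
    rc = series_comp(store, [r1, c1], name="rc")
    src = make_source(store, p.amplitude, p.freq, name="src")
    r2 = make_resistor(store, p.R2, name="r2")
    top = parallel_comp(store, [rc, src, r2], name="circuit")
    close_circuit(top)
    return {"r1": r1, "c1": c1, "rc": rc, "src": src, "r2": r2, "top": top}
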