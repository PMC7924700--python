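"""Composite neurons and the cerebellar granular-layer microcircuit.

A composite neuron aggregates an AdEx cell with conductance-based synapses;
the cell's total input current ``Iin`` is tied to the sum of the member
synaptic currents by a per-tick aggregation constraint
(``N.Iin = Am.Iampa + Ga.Igaba + Nm.Inmda``).  Synapse currents here use the
*delivered* (depolarizing-positive) sign ``I = g · (Esyn − V)`` so that the
sum feeds the neuron's input current directly; the electrophysiological
membrane-current convention ``g · (V − Esyn)`` remains available as
:func:`tcob.synapses.syn_current`.

The microcircuit wires one granule (GrC), one Golgi (GoC) and one Purkinje
(Pc) cell: mossy fibres drive both GrC and GoC (excitatory, AMPA kinetics);
GoC inhibits GrC (feed-forward inhibition, GABA kinetics); GrC output
travels along the parallel fibre (a pure relay) to excite Pc.  Connection
multiplicity — on average four excitatory and four inhibitory afferents per
granule cell — is realized as multiple synapse instances.  All routing is
expressed as per-tick interface constraints::

    GrC.MfInput  = Mf.Input        GoC.MfInput = Mf.Input
    GoC.Output   = GoC.SpikeTrain  GrC.GoCInput = GoC.Output
    GrC.Output   = GrC.SpikeTrain  Pf.Input = GrC.Output
    Pc.GrCInput  = Pf.Input        Pc.Output = Pc.SpikeTrain

Spike events propagate to downstream synapses with a one-tick axonal delay
(zero delay would create within-tick constraint cycles).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .engine import (DT, TIME, CobInstance, ConstraintStore, TimeGrid,
                     call, cond, define_class, eq, prev, ref, series)
from .engine.errors import CobParameterError
from .neurons import ADEX_PRESETS, AdExParams, SpikeTrain, detect_spikes
from .synapses import SynapseParams, conductance, receptor_preset

__all__ = [
    "SynapseSpec", "CompositeNeuron", "ConnectivityConfig", "Microcircuit",
    "MicrocircuitResult", "build_neuron", "build_microcircuit",
    "run_microcircuit",
]


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse of a composite neuron.

    ``spike_times`` drives the synapse with a fixed presynaptic train (ms);
    ``source`` instead names a store series of per-tick spike indicators
    (a presynaptic cell's output port), read with a one-tick delay.
    """

    params: SynapseParams
    spike_times: Sequence[float] | None = None
    source: str | None = None
    name: str = ""


@dataclass
class CompositeNeuron:
    cell: CobInstance
    synapses: list[CobInstance]
    store: ConstraintStore

    def spike_train(self, dt: float | None = None) -> SpikeTrain:
        dt = dt if dt is not None else self.store.grid.dt
        flags = self.cell.series("SpikeTrain")
        return SpikeTrain([k * dt for k in sorted(flags) if flags[k] >= 0.5],
                          source=self.cell.path)


@dataclass(frozen=True)
class ConnectivityConfig:
    """Afferent counts onto the granule cell.

    ``mode='fixed'`` wires exactly the stated counts; ``mode='poisson'``
    draws each count from Poisson(mean) with a mandatory seed.
    """

    n_excitatory: int = 4
    n_inhibitory: int = 4
    mode: str = "fixed"
    mean: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise CobParameterError("connection counts must be non-negative")
        if self.mode not in ("fixed", "poisson"):
            raise CobParameterError(f"unknown draw mode {self.mode!r}")
        if self.mode == "poisson" and self.seed is None:
            raise CobParameterError("poisson connectivity requires a seed")

    def draw(self) -> tuple[int, int]:
        if self.mode == "fixed":
            return self.n_excitatory, self.n_inhibitory
        rng = np.random.default_rng(self.seed)
        return int(rng.poisson(self.mean)), int(rng.poisson(self.mean))


# ------------------------------------------------------------- cell classes

def _adex_cell_class(cls_name: str, p: AdExParams, t_start: int, v0: float,
                     ports: Sequence[str]) -> "object":
    """AdEx cell whose input current ``Iin`` is left to external constraints
    (the composite posts the synaptic-sum relation).  ``ports`` adds named
    input/output series used by interface constraints."""
    V, w, flag, Iin = (ref(s) for s in ("V", "w", "flag", "Iin"))
    pV, pw = prev(V), prev(w)
    exp_term = call(lambda v: math.exp(min((v - p.Vt) / p.DeltaT, 20.0)), pV,
                    name="spike_initiation")
    attrs = [
        series("V", init={t_start: v0}),
        series("w", init={t_start: 0.0}),
        series("flag", init={t_start: 0.0}),
        series("SpikeTrain", init={t_start: 0.0}),
        series("Iin", init={t_start: 0.0}),
    ]
    attrs += [series(port) for port in ports]
    return define_class(
        cls_name,
        attributes=attrs,
        constraints=[
            cond(pV > p.Vcut,
                 [eq(V, p.Vr, label=f"{cls_name}-reset-V"),
                  eq(w, pw + p.b, label=f"{cls_name}-reset-w"),
                  eq(flag, 1.0, label=f"{cls_name}-spike")],
                 label=f"{cls_name}-spike-branch"),
            cond(pV <= p.Vcut,
                 [eq(V, pV + DT * (-p.gL * (pV - p.EL)
                                   + p.gL * p.DeltaT * exp_term
                                   - pw + Iin) / p.C,
                     label=f"{cls_name}-euler-V"),
                  eq(w, pw + DT * (p.a * (pV - p.EL) - pw) / p.tau_w,
                     label=f"{cls_name}-euler-w"),
                  eq(flag, 0.0, label=f"{cls_name}-no-spike")],
                 label=f"{cls_name}-smooth-branch"),
            eq(ref("SpikeTrain"), flag, label=f"{cls_name}-spiketrain"),
        ])


class _FlagReader:
    """Replay-safe incremental reader of a spike-indicator series.

    Accumulates the spike ticks seen so far and answers "spike times at
    ticks ≤ j" for any j already scanned (or scannable), so constraint
    re-evaluation during residual sweeps sees exactly the values it saw
    during the run.
    """

    def __init__(self, store: ConstraintStore, path: str, dt: float):
        self.store = store
        self.path = path
        self.dt = dt
        self.spike_ticks: list[int] = []
        self.scanned_to = store.grid.t_start - 1

    def times_until(self, j: int) -> list[float]:
        d = self.store.series[self.path]
        while self.scanned_to < j:
            k = self.scanned_to + 1
            v = d.get(k)
            if v is None:
                break
            if v >= 0.5:
                self.spike_ticks.append(k)
            self.scanned_to = k
        cut = bisect_right(self.spike_ticks, j)
        return [k * self.dt for k in self.spike_ticks[:cut]]


def _make_gfn(store: ConstraintStore, spec: SynapseSpec) -> Callable[[int], float]:
    dt = store.grid.dt
    p = spec.params
    if spec.spike_times is not None:
        times = sorted(float(t) for t in spec.spike_times)

        def g_fn(k: int) -> float:
            t = k * dt
            cut = bisect_right(times, t)
            return float(conductance(t, p, times[:cut]))
        return g_fn
    if spec.source is None:
        return lambda k: 0.0
    reader = _FlagReader(store, spec.source, dt)

    def g_fn(k: int) -> float:
        # one-tick axonal delay: only spikes up to tick k-1 are visible
        return float(conductance(k * dt, p, reader.times_until(k - 1)))
    return g_fn


def _make_synapse(store: ConstraintStore, name: str, spec: SynapseSpec,
                  post_v_path: str) -> CobInstance:
    g_fn = _make_gfn(store, spec)
    t0 = store.grid.t_start
    cls = define_class(
        f"synapse_{spec.params.kind}",
        attributes=[series("g"), series("I", init={t0: 0.0})],
        constraints=[eq(ref("g"), call(g_fn, TIME), label=f"{name}-kernel")])
    inst = store.instantiate(cls, name=name)
    # delivered current (depolarizing positive), from the previous-tick
    # postsynaptic voltage so each tick stays explicit
    store.post(eq(ref(f"{name}.I"),
                  ref(f"{name}.g") * (spec.params.Esyn - ref(post_v_path, -1)),
                  label=f"{name}-current"))
    return inst


def build_neuron(store: ConstraintStore, adex_params: AdExParams,
                 synapse_specs: Sequence[SynapseSpec],
                 name: str = "neuron", v0: float = -70.0,
                 ports: Sequence[str] = (),
                 i_ext: Callable[[float], float] | float | None = None
                 ) -> CompositeNeuron:
    """Aggregate an AdEx cell with synapses inside ``store``.

    Registers the per-tick summation constraint tying the cell's input
    current to its member synaptic currents (plus an optional external
    current-clamp term).
    """
    cls = _adex_cell_class(f"{name}_cell", adex_params, store.grid.t_start,
                           v0, ports)
    cell = store.instantiate(cls, name=name)
    synapses = []
    for i, spec in enumerate(synapse_specs):
        sname = spec.name or f"{name}_syn{i}"
        synapses.append(_make_synapse(store, sname, spec, f"{name}.V"))

    total = None
    for syn in synapses:
        term = ref(f"{syn.path}.I")
        total = term if total is None else total + term
    if i_ext is not None:
        stim = i_ext if callable(i_ext) else (lambda t, a=float(i_ext): a)
        term = call(stim, TIME * DT, name="i_ext")
        total = term if total is None else total + term
    store.post(eq(ref(f"{name}.Iin"), 0.0 if total is None else total,
                  label=f"{name}-input-sum"))
    return CompositeNeuron(cell=cell, synapses=synapses, store=store)


# ------------------------------------------------------------- microcircuit

@dataclass
class Microcircuit:
    store: ConstraintStore
    grid: TimeGrid
    grc: CompositeNeuron
    goc: CompositeNeuron
    pc: CompositeNeuron
    mf: CobInstance
    pf: CobInstance
    config: ConnectivityConfig
    n_exc: int
    n_inh: int
    golgi_silenced: bool = False


@dataclass
class MicrocircuitResult:
    spikes: dict[str, SpikeTrain]
    traces: dict[str, np.ndarray]
    time: np.ndarray
    store: ConstraintStore


def build_microcircuit(config: ConnectivityConfig | None = None,
                       grid: TimeGrid | None = None,
                       cell_params: dict[str, AdExParams] | None = None,
                       synapse_params: dict[str, SynapseParams] | None = None,
                       golgi_silenced: bool = False,
                       i_ext: dict[str, float | Callable] | None = None
                       ) -> Microcircuit:
    """Wire the granular-layer microcircuit into a fresh constraint store.

    ``cell_params`` may override the granule/golgi/purkinje AdEx presets;
    ``synapse_params`` the mossy→GrC AMPA ('mf_grc'), mossy→GoC AMPA
    ('mf_goc'), GoC→GrC GABA ('goc_grc') and parallel-fibre→Pc AMPA
    ('pf_pc') kernels.  ``golgi_silenced`` replaces the GoC output relay
    with silence (for paired feed-forward-inhibition comparisons).
    """
    config = config or ConnectivityConfig()
    grid = grid or TimeGrid(t_end=5000, dt=0.1)
    cells = {**{k: ADEX_PRESETS[k] for k in ("granule", "golgi", "purkinje")},
             **(cell_params or {})}
    syn = {
        "mf_grc": receptor_preset("AMPA", gmax=0.6),
        "mf_goc": receptor_preset("AMPA", gmax=0.6),
        "goc_grc": receptor_preset("GABAA", gmax=0.6),
        "pf_pc": receptor_preset("AMPA", gmax=8.0),
        **(synapse_params or {}),
    }
    n_exc, n_inh = config.draw()
    if n_exc == 0 and n_inh == 0 and config.mode == "fixed":
        raise CobParameterError("microcircuit with no granule afferents")

    store = ConstraintStore(grid)
    t0 = grid.t_start

    mf_cls = define_class("mossy_fiber", attributes=[series("Input")])
    mf = store.instantiate(mf_cls, name="Mf")
    pf_cls = define_class(
        "parallel_fiber",
        attributes=[series("Input"), series("Output")],
        constraints=[eq(ref("Output"), ref("Input"), label="pf-relay")])
    pf = store.instantiate(pf_cls, name="Pf")

    grc_specs = (
        [SynapseSpec(syn["mf_grc"], source="GrC.MfInput",
                     name=f"GrC_ampa{i}") for i in range(n_exc)]
        + [SynapseSpec(syn["goc_grc"], source="GrC.GoCInput",
                       name=f"GrC_gaba{i}") for i in range(n_inh)])
    goc_specs = [SynapseSpec(syn["mf_goc"], source="GoC.MfInput",
                             name=f"GoC_ampa{i}")
                 for i in range(config.n_excitatory)]
    pc_specs = [SynapseSpec(syn["pf_pc"], source="Pc.GrCInput",
                            name="Pc_ampa0")]
    iext = i_ext or {}
    grc = build_neuron(store, cells["granule"], grc_specs, name="GrC",
                      ports=("MfInput", "GoCInput", "Output"),
                      i_ext=iext.get("granule"))
    goc = build_neuron(store, cells["golgi"], goc_specs, name="GoC",
                      ports=("MfInput", "Output"), i_ext=iext.get("golgi"))
    pc = build_neuron(store, cells["purkinje"], pc_specs, name="Pc",
                     ports=("GrCInput", "Output"), i_ext=iext.get("purkinje"))

    # interface constraints (signal routing between the objects)
    wire = [
        ("GrC.MfInput", "Mf.Input"),
        ("GoC.MfInput", "Mf.Input"),
        ("GoC.Output", "GoC.SpikeTrain"),
        ("GrC.Output", "GrC.SpikeTrain"),
        ("Pf.Input", "GrC.Output"),
        ("Pc.GrCInput", "Pf.Input"),
        ("Pc.Output", "Pc.SpikeTrain"),
    ]
    if golgi_silenced:
        store.post(eq(ref("GrC.GoCInput"), 0.0, label="GrC.GoCInput=silenced"))
    else:
        wire.append(("GrC.GoCInput", "GoC.Output"))
    for dst, src in wire:
        store.post(eq(ref(dst), ref(src), label=f"{dst}={src}"))

    return Microcircuit(store=store, grid=grid, grc=grc, goc=goc, pc=pc,
                        mf=mf, pf=pf, config=config, n_exc=n_exc,
                        n_inh=n_inh, golgi_silenced=golgi_silenced)


def run_microcircuit(mc: Microcircuit,
                     stimulus: Sequence[float],
                     grid: TimeGrid | None = None) -> MicrocircuitResult:
    """Drive the mossy fibre with spike times (ms), step the full constraint
    store over the grid and extract spike trains and voltage traces."""
    grid = grid or mc.grid
    if grid != mc.grid:
        raise CobParameterError("microcircuit was built on a different grid")
    times = sorted(float(t) for t in stimulus)
    horizon = grid.time(grid.t_end)
    if any(t > horizon for t in times):
        raise CobParameterError(
            f"stimulus spike beyond the simulated horizon ({horizon} ms)")
    spike_ticks = {max(grid.t_start, int(math.ceil(t / grid.dt)))
                   for t in times}
    for k in grid.ticks():
        mc.mf.set_initial("Input", k, 1.0 if k in spike_ticks else 0.0)
    mc.store.run()

    dt = grid.dt
    spikes, traces = {}, {}
    for label, neuron in (("GrC", mc.grc), ("GoC", mc.goc), ("Pc", mc.pc)):
        flags = neuron.cell.series_array("flag")
        resets = np.flatnonzero(flags >= 0.5) + grid.t_start
        spikes[label] = detect_spikes(resets=resets, dt=dt, source=label)
        # display voltage: finite upswing, clamped at the spike cutoff
        traces[label] = np.minimum(neuron.cell.series_array("V"), 0.0)
    return MicrocircuitResult(spikes=spikes, traces=traces,
                              time=grid.times(), store=mc.store)
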