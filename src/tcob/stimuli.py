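"""Stimulus generators: step currents, spike bursts, sinusoids.

Single-spike input models the in-vitro protocol (one presynaptic event);
small bursts — five spikes per burst by default — model in-vivo-like mossy
fibre activity.  Step currents reproduce current-clamp protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .engine import TimeGrid
from .engine.errors import CobParameterError

__all__ = ["StimulusSpec", "gen_step_current", "gen_burst", "gen_sinusoid",
           "step_fn", "single_spike", "burst"]


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative stimulus description.

    kind: one of step_current, single_spike, burst, sinusoid, spike_file.
    amplitude in the target model's current units (or volt for sources);
    onset/offset in ms; n_spikes and isi (ms) apply to bursts; freq in
    rad/ms to sinusoids; path to spike_file.
    """

    kind: str = "step_current"
    amplitude: float = 10.0
    onset: float = 0.0
    offset: float = float("inf")
    n_spikes: int = 5
    isi: float = 10.0
    freq: float = 1.0
    path: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        kinds = ("step_current", "single_spike", "burst", "sinusoid",
                 "spike_file")
        if self.kind not in kinds:
            raise CobParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.onset >= self.offset:
            raise CobParameterError(
                f"onset ({self.onset}) must precede offset ({self.offset})")
        if self.n_spikes < 1:
            raise CobParameterError("a burst needs at least one spike")
        if self.isi <= 0:
            raise CobParameterError("inter-spike interval must be positive")


def step_fn(spec: StimulusSpec) -> Callable[[float], float]:
    """The step current as a function of time (ms): amplitude on
    [onset, offset), zero elsewhere."""
    a, on, off = spec.amplitude, spec.onset, spec.offset
    return lambda t: a if on <= t < off else 0.0


def gen_step_current(spec: StimulusSpec, grid: TimeGrid) -> np.ndarray:
    """Sample the step current on the grid (one value per tick)."""
    f = step_fn(spec)
    return np.array([f(grid.time(k)) for k in grid.ticks()])


def gen_burst(spec: StimulusSpec, grid: TimeGrid | None = None) -> list[float]:
    """Spike times of a burst: ``n_spikes`` events from ``onset`` spaced
    ``isi`` ms apart.  Events beyond the grid horizon are dropped with a
    warning."""
    times = [spec.onset + i * spec.isi for i in range(spec.n_spikes)]
    if grid is not None:
        horizon = grid.time(grid.t_end)
        kept = [t for t in times if t <= horizon]
        if len(kept) < len(times):
            warnings.warn(
                f"burst truncated: {len(times) - len(kept)} spike(s) beyond "
                f"the {horizon} ms horizon", stacklevel=2)
        times = kept
    return times


def single_spike(onset: float = 20.0) -> StimulusSpec:
    """In-vitro-like input: one presynaptic spike."""
    return StimulusSpec(kind="single_spike", onset=onset, n_spikes=1)


def burst(onset: float = 20.0, n_spikes: int = 5, isi: float = 10.0
          ) -> StimulusSpec:
    """In-vivo-like input: a small burst (default five spikes)."""
    return StimulusSpec(kind="burst", onset=onset, n_spikes=n_spikes, isi=isi)


def gen_sinusoid(spec: StimulusSpec, grid: TimeGrid) -> np.ndarray:
    """amplitude · sin(freq · t) sampled on the grid."""
    return spec.amplitude * np.sin(spec.freq * grid.times())
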