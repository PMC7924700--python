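"""Point-neuron models: Hodgkin–Huxley, Izhikevich and AdEx.

Each model exists in two forms with identical update rules:

* a *fast path* — plain forward-Euler step functions and simulation loops
  (:func:`hh_step` / :func:`simulate_hh`, ...) used by amplitude sweeps and
  the command line; and
* a *constrained-object form* — engine classes whose per-tick constraints
  encode the same difference equations declaratively
  (:func:`build_hh_store`, ...), used wherever the declarative semantics
  (residual audits, conditional resets, microcircuit wiring) matter.

A classic fourth-order Runge–Kutta integrator over the same right-hand
sides (:func:`integrate_reference`) serves as an independent accuracy
oracle; it is never part of the simulation path.

Voltages are millivolts, time milliseconds.  Currents are taken at face
value in the model's own units (the HH current scale is the classic
µA/cm²-like unit, written "pA" in the source literature for these desk-scale
cells).  The HH rate functions follow the classic squid-axon convention:
they are evaluated at the depolarization ``V - Vrest`` relative to rest,
while the integrated membrane voltage is absolute with rest at −70 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .engine import (DT, CobInstance, ConstraintStore, TimeGrid, call, cond,
                     define_class, eq, prev, ref, scalar, series, TIME)
from .engine.errors import CobDivergenceError, CobParameterError

__all__ = [
    "HHParams", "HHState", "IzhParams", "IzhState", "AdExParams", "AdExState",
    "SpikeTrain", "Rates", "hh_rates", "hh_steady_gates", "hh_step",
    "izh_step", "adex_step", "simulate_hh", "simulate_izh", "simulate_adex",
    "detect_spikes", "integrate_reference", "firing_onset",
    "IZH_PRESETS", "ADEX_PRESETS", "build_hh_store", "build_izh_store",
    "build_adex_store",
]


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class HHParams:
    """Classic squid-axon parameter set, shifted so rest sits at ``Vrest``.

    Units: Cm µF/cm²; conductances mS/cm²; potentials mV.
    """

    Cm: float = 1.0
    gNaMax: float = 120.0
    gKMax: float = 36.0
    gL: float = 0.3
    Vrest: float = -70.0
    ENa: float = field(default=None)  # type: ignore[assignment]
    EK: float = field(default=None)   # type: ignore[assignment]
    EL: float = field(default=None)   # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise CobParameterError("Cm must be positive")
        if min(self.gNaMax, self.gKMax, self.gL) < 0:
            raise CobParameterError("conductances must be non-negative")
        if self.ENa is None:
            object.__setattr__(self, "ENa", self.Vrest + 115.0)
        if self.EK is None:
            object.__setattr__(self, "EK", self.Vrest - 12.0)
        if self.EL is None:
            object.__setattr__(self, "EL", self.Vrest + 10.6)


@dataclass(frozen=True)
class HHState:
    V: float
    m: float
    h: float
    n: float
    IExt: float = 0.0


@dataclass(frozen=True)
class IzhParams:
    """Izhikevich two-variable model: a (1/ms) recovery time scale, b
    recovery sensitivity, c (mV) after-spike voltage reset, d after-spike
    recovery increment, Vpeak (mV) the finite upswing cutoff."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    Vpeak: float = 30.0

    def __post_init__(self) -> None:
        if self.Vpeak <= self.c:
            raise CobParameterError("Vpeak must exceed the reset value c")


@dataclass(frozen=True)
class IzhState:
    V: float
    u: float


@dataclass(frozen=True)
class AdExParams:
    """Adaptive exponential integrate-and-fire.

    C pF; gL, a nS; EL, DeltaT, Vt, Vr, Vcut mV; tau_w ms; b pA.
    A spike is registered when V crosses ``Vcut`` (0 mV); V then resets to
    Vr and the adaptation current w jumps by b.
    """

    C: float = 200.0
    gL: float = 10.0
    EL: float = -70.0
    DeltaT: float = 2.0
    Vt: float = -50.0
    Vr: float = -58.0
    tau_w: float = 120.0
    a: float = 2.0
    b: float = 0.0
    Vcut: float = 0.0

    def __post_init__(self) -> None:
        if self.DeltaT <= 0:
            raise CobParameterError("DeltaT must be positive")
        if self.tau_w <= 0:
            raise CobParameterError("tau_w must be positive")


@dataclass(frozen=True)
class AdExState:
    V: float
    w: float


class SpikeTrain:
    """Ordered spike times in milliseconds with a source-cell identifier."""

    def __init__(self, times: Sequence[float], source: str = ""):
        arr = np.asarray(list(times), dtype=float)
        if arr.ndim != 1:
            raise CobParameterError("spike times must form a 1-d sequence")
        if arr.size and np.any(np.diff(arr) <= 0):
            raise CobParameterError("spike times must be strictly increasing")
        self.times = arr
        self.source = source

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self):
        return iter(self.times)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpikeTrain(n={len(self)}, source={self.source!r})"

    def rate(self, window_ms: float) -> float:
        """Mean firing rate in Hz over a window of ``window_ms``."""
        return 1000.0 * len(self) / window_ms if window_ms > 0 else 0.0

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


# ----------------------------------------------------------------- HH model

class Rates(NamedTuple):
    alpha_m: float
    beta_m: float
    alpha_n: float
    beta_n: float
    alpha_h: float
    beta_h: float


def _vtrap(x: float, y: float) -> float:
    """x / (exp(x/y) - 1) with its removable singularity filled at x = 0."""
    r = x / y
    if abs(r) < 1e-7:
        return y * (1.0 - r / 2.0)
    return x / (math.exp(r) - 1.0)


def hh_rates(v_shift: float) -> Rates:
    """Voltage-dependent opening/closing rates of the Na⁺ and K⁺ gates.

    ``v_shift`` is the membrane depolarization relative to rest (mV).  The
    removable singularities of alpha_m (at 25 mV) and alpha_n (at 10 mV)
    return their analytic limits, so the function is total.
    """
    alpha_m = 0.1 * _vtrap(25.0 - v_shift, 10.0)
    beta_m = 4.0 * math.exp(-v_shift / 18.0)
    alpha_n = 0.01 * _vtrap(10.0 - v_shift, 10.0)
    beta_n = 0.125 * math.exp(-v_shift / 80.0)
    alpha_h = 0.07 * math.exp(-v_shift / 20.0)
    beta_h = 1.0 / (math.exp(3.0 - 0.1 * v_shift) + 1.0)
    return Rates(alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h)


def hh_steady_gates(v_shift: float = 0.0) -> tuple[float, float, float]:
    """Steady-state gate values x_inf = alpha/(alpha+beta) → (m, h, n)."""
    r = hh_rates(v_shift)
    return (r.alpha_m / (r.alpha_m + r.beta_m),
            r.alpha_h / (r.alpha_h + r.beta_h),
            r.alpha_n / (r.alpha_n + r.beta_n))


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def hh_step(state: HHState, params: HHParams, dt: float) -> HHState:
    """One forward-Euler step of the four coupled HH difference equations.

    Gate rates are evaluated at the previous-tick depolarization; updated
    gates are clipped to [0, 1].
    """
    p = params
    V, m, h, n = state.V, state.m, state.h, state.n
    am, bm, an, bn, ah, bh = hh_rates(V - p.Vrest)
    I_ion = (p.gNaMax * m ** 3 * h * (V - p.ENa)
             + p.gKMax * n ** 4 * (V - p.EK)
             + p.gL * (V - p.EL))
    V_new = V + dt * (state.IExt - I_ion) / p.Cm
    m_new = _clip01(m + dt * (am * (1.0 - m) - bm * m))
    h_new = _clip01(h + dt * (ah * (1.0 - h) - bh * h))
    n_new = _clip01(n + dt * (an * (1.0 - n) - bn * n))
    if not math.isfinite(V_new):
        raise CobDivergenceError("HH membrane voltage became non-finite")
    return HHState(V_new, m_new, h_new, n_new, state.IExt)


def simulate_hh(params: HHParams, stimulus: Callable[[float], float] | float,
                dt: float = 0.01, t_stop: float = 500.0,
                v0: float | None = None) -> dict[str, np.ndarray]:
    """Simulate the HH neuron; returns arrays t, V, m, h, n, I.

    ``stimulus`` is either a constant current or a function of time (ms).
    The membrane starts at rest (−70 mV by default) with gates at their
    steady-state values.  The first row is the initial condition at t = 0.
    """
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    n_steps = int(round(t_stop / dt))
    V = v0 if v0 is not None else p.Vrest
    m, h, n = hh_steady_gates(V - p.Vrest)
    t_arr = np.empty(n_steps + 1)
    out = {k: np.empty(n_steps + 1) for k in ("V", "m", "h", "n", "I")}
    gNa, gK, gL = p.gNaMax, p.gKMax, p.gL
    ENa, EK, EL, Vr, Cm = p.ENa, p.EK, p.EL, p.Vrest, p.Cm
    for i in range(n_steps + 1):
        t = i * dt
        I = stim(t)
        t_arr[i] = t
        out["V"][i] = V
        out["m"][i] = m
        out["h"][i] = h
        out["n"][i] = n
        out["I"][i] = I
        if i == n_steps:
            break
        am, bm, an, bn, ah, bh = hh_rates(V - Vr)
        I_ion = (gNa * m * m * m * h * (V - ENa) + gK * n ** 4 * (V - EK)
                 + gL * (V - EL))
        V = V + dt * (I - I_ion) / Cm
        m = _clip01(m + dt * (am * (1.0 - m) - bm * m))
        h = _clip01(h + dt * (ah * (1.0 - h) - bh * h))
        n = _clip01(n + dt * (an * (1.0 - n) - bn * n))
        if not math.isfinite(V):
            raise CobDivergenceError("HH membrane voltage became non-finite",
                                     tick=i + 1)
    out["t"] = t_arr
    return out


# ------------------------------------------------------- voltage-reset models

def izh_step(state: IzhState, params: IzhParams, I: float, dt: float) -> IzhState:
    """One step of the Izhikevich model with the after-spike reset.

    If the previous-tick voltage reached ``Vpeak`` the state resets
    discontinuously (V ← c, u ← u + d); otherwise both variables advance by
    forward Euler on dV/dt = 0.04 V² + 5 V + 140 − u + I and
    du/dt = a (bV − u).
    """
    p = params
    if state.V >= p.Vpeak:
        return IzhState(p.c, state.u + p.d)
    V, u = state.V, state.u
    V_new = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + I)
    u_new = u + dt * p.a * (p.b * V - u)
    if not math.isfinite(V_new):
        raise CobDivergenceError("Izhikevich voltage became non-finite")
    return IzhState(V_new, u_new)


def adex_step(state: AdExState, params: AdExParams, Iin: float,
              dt: float) -> AdExState:
    """One step of the AdEx model with the spike-triggered reset.

    If the previous-tick voltage exceeded ``Vcut`` (0 mV): V ← Vr,
    w ← w + b.  Otherwise forward Euler with the standard sign convention;
    the exponential argument is capped at 20 so the pre-reset upswing cannot
    overflow.
    """
    p = params
    if state.V > p.Vcut:
        return AdExState(p.Vr, state.w + p.b)
    V, w = state.V, state.w
    ex = math.exp(min((V - p.Vt) / p.DeltaT, 20.0))
    dV = (-p.gL * (V - p.EL) + p.gL * p.DeltaT * ex - w + Iin) / p.C
    V_new = V + dt * dV
    w_new = w + dt * (p.a * (V - p.EL) - w) / p.tau_w
    if not math.isfinite(V_new):
        raise CobDivergenceError("AdEx voltage became non-finite")
    return AdExState(V_new, w_new)


def simulate_izh(params: IzhParams, stimulus: Callable[[float], float] | float,
                 dt: float = 0.1, t_stop: float = 1000.0,
                 v0: float = -70.0, u0: float | None = None
                 ) -> dict[str, np.ndarray]:
    """Simulate the Izhikevich neuron; returns t, V (clamped at Vpeak for
    display), u and the reset step indices.

    The recovery variable starts at its subthreshold fixed point b·v0 unless
    given explicitly.
    """
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    state = IzhState(v0, p.b * v0 if u0 is None else u0)
    n_steps = int(round(t_stop / dt))
    t = np.arange(n_steps + 1) * dt
    V = np.empty(n_steps + 1)
    u = np.empty(n_steps + 1)
    resets = []
    for i in range(n_steps + 1):
        V[i] = min(state.V, p.Vpeak)  # finite maximum upswing for display
        u[i] = state.u
        if i == n_steps:
            break
        was_spike = state.V >= p.Vpeak
        state = izh_step(state, p, stim(i * dt), dt)
        if was_spike:
            resets.append(i + 1)
    return {"t": t, "V": V, "u": u, "resets": np.array(resets, dtype=int)}


def simulate_adex(params: AdExParams, stimulus: Callable[[float], float] | float,
                  dt: float = 0.1, t_stop: float = 1000.0,
                  v0: float = -70.0, w0: float = 0.0) -> dict[str, np.ndarray]:
    """Simulate the AdEx neuron; returns t, V (clamped at Vcut for display),
    w and the reset step indices."""
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    state = AdExState(v0, w0)
    n_steps = int(round(t_stop / dt))
    t = np.arange(n_steps + 1) * dt
    V = np.empty(n_steps + 1)
    w = np.empty(n_steps + 1)
    resets = []
    for i in range(n_steps + 1):
        V[i] = min(state.V, p.Vcut)
        w[i] = state.w
        if i == n_steps:
            break
        was_spike = state.V > p.Vcut
        state = adex_step(state, p, stim(i * dt), dt)
        if was_spike:
            resets.append(i + 1)
    return {"t": t, "V": V, "w": w, "resets": np.array(resets, dtype=int)}


IZH_PRESETS: dict[str, IzhParams] = {
    # canonical cortical firing patterns of the two-variable model
    "regular_spiking": IzhParams(a=0.02, b=0.2, c=-65.0, d=8.0),
    "chattering": IzhParams(a=0.02, b=0.2, c=-50.0, d=2.0),
    "fast_spiking": IzhParams(a=0.1, b=0.2, c=-65.0, d=2.0),
}

ADEX_PRESETS: dict[str, AdExParams] = {
    # generic cortical-scale cell, tonic vs adapting
    "tonic": AdExParams(C=200.0, gL=10.0, EL=-70.0, Vt=-50.0, DeltaT=2.0,
                        Vr=-58.0, tau_w=30.0, a=2.0, b=0.0),
    "adapting": AdExParams(C=200.0, gL=12.0, EL=-70.0, Vt=-50.0, DeltaT=2.0,
                           Vr=-58.0, tau_w=300.0, a=2.0, b=60.0),
    # desk-scale cerebellar presets (small cells, pA-scale currents)
    "granule": AdExParams(C=3.1, gL=0.43, EL=-70.0, Vt=-58.0, DeltaT=2.0,
                          Vr=-70.0, tau_w=100.0, a=0.3, b=2.0),
    "golgi": AdExParams(C=20.0, gL=1.0, EL=-70.0, Vt=-61.0, DeltaT=2.0,
                        Vr=-70.0, tau_w=120.0, a=0.5, b=4.0),
    "purkinje": AdExParams(C=75.0, gL=0.8, EL=-70.0, Vt=-60.0, DeltaT=2.0,
                           Vr=-68.0, tau_w=150.0, a=1.0, b=10.0),
}


# ------------------------------------------------------------ spike handling

def detect_spikes(trace: np.ndarray | None = None, *,
                  resets: Sequence[int] | None = None,
                  dt: float,
                  threshold: float = -20.0,
                  source: str = "") -> SpikeTrain:
    """Extract a spike train from a voltage trace or a list of reset steps.

    For threshold models the spike times are the reset step indices × dt.
    For continuous traces (HH) a spike is an upward crossing of
    ``threshold`` (default −20 mV), one spike per crossing.  An empty or
    flat trace yields an empty train.
    """
    if (trace is None) == (resets is None):
        raise CobParameterError("provide exactly one of trace= or resets=")
    if resets is not None:
        return SpikeTrain([k * dt for k in resets], source=source)
    v = np.asarray(trace, dtype=float)
    if v.size == 0:
        return SpikeTrain([], source=source)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return SpikeTrain(crossings * dt, source=source)


def firing_onset(params: HHParams, amplitudes: Sequence[float],
                 dt: float = 0.01, t_stop: float = 500.0,
                 min_spikes: int = 2) -> tuple[float | None, dict[float, int]]:
    """Scan step-current amplitudes for the onset of repetitive firing.

    Repetitive firing means more than one action potential in the window
    (``min_spikes`` ≥ 2 by default; raise it to demand sustained trains).
    Returns (smallest repetitively-firing amplitude or None, spike counts
    per amplitude).
    """
    counts: dict[float, int] = {}
    onset = None
    for amp in amplitudes:
        res = simulate_hh(params, float(amp), dt=dt, t_stop=t_stop)
        counts[amp] = len(detect_spikes(res["V"], dt=dt))
        if onset is None and counts[amp] >= min_spikes:
            onset = amp
    return onset, counts


# ----------------------------------------------------- RK4 reference oracle

def integrate_reference(model_id: str, params, stimulus, dt: float,
                        t_stop: float, v0: float | None = None
                        ) -> dict[str, np.ndarray]:
    """Classic RK4 integration of the same right-hand sides (testing oracle).

    ``model_id`` is one of ``hh``, ``izh``, ``adex``; resets of the
    threshold models are applied between smooth steps.  ``stimulus`` is a
    constant or a function of time (ms).
    """
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    if model_id == "hh":
        return _rk4_hh(params, stim, dt, t_stop, v0)
    if model_id == "izh":
        return _rk4_reset(params, stim, dt, t_stop,
                          v0 if v0 is not None else -70.0, _izh_rhs,
                          lambda s, p: s[0] >= p.Vpeak,
                          lambda s, p: (p.c, s[1] + p.d),
                          u0=lambda p, v: p.b * v, names=("V", "u"),
                          v_clamp=params.Vpeak)
    if model_id == "adex":
        return _rk4_reset(params, stim, dt, t_stop,
                          v0 if v0 is not None else params.EL, _adex_rhs,
                          lambda s, p: s[0] > p.Vcut,
                          lambda s, p: (p.Vr, s[1] + p.b),
                          u0=lambda p, v: 0.0, names=("V", "w"),
                          v_clamp=params.Vcut)
    raise CobParameterError(f"unknown model id {model_id!r}")


def _hh_rhs(y: np.ndarray, I: float, p: HHParams) -> np.ndarray:
    V, m, h, n = y
    am, bm, an, bn, ah, bh = hh_rates(V - p.Vrest)
    I_ion = (p.gNaMax * m ** 3 * h * (V - p.ENa)
             + p.gKMax * n ** 4 * (V - p.EK) + p.gL * (V - p.EL))
    return np.array([
        (I - I_ion) / p.Cm,
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    ])


def _rk4_hh(p: HHParams, stim, dt: float, t_stop: float,
            v0: float | None) -> dict[str, np.ndarray]:
    V = v0 if v0 is not None else p.Vrest
    m, h, n = hh_steady_gates(V - p.Vrest)
    y = np.array([V, m, h, n])
    n_steps = int(round(t_stop / dt))
    t = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 4))
    for i in range(n_steps + 1):
        out[i] = y
        if i == n_steps:
            break
        ti = i * dt
        k1 = _hh_rhs(y, stim(ti), p)
        k2 = _hh_rhs(y + 0.5 * dt * k1, stim(ti + 0.5 * dt), p)
        k3 = _hh_rhs(y + 0.5 * dt * k2, stim(ti + 0.5 * dt), p)
        k4 = _hh_rhs(y + dt * k3, stim(ti + dt), p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(y[0]):
            raise CobDivergenceError("RK4 HH voltage became non-finite", tick=i + 1)
    return {"t": t, "V": out[:, 0], "m": out[:, 1], "h": out[:, 2],
            "n": out[:, 3]}


def _izh_rhs(y: np.ndarray, I: float, p: IzhParams) -> np.ndarray:
    V, u = y
    return np.array([0.04 * V * V + 5.0 * V + 140.0 - u + I,
                     p.a * (p.b * V - u)])


def _adex_rhs(y: np.ndarray, I: float, p: AdExParams) -> np.ndarray:
    V, w = y
    ex = math.exp(min((V - p.Vt) / p.DeltaT, 20.0))
    return np.array([(-p.gL * (V - p.EL) + p.gL * p.DeltaT * ex - w + I) / p.C,
                     (p.a * (V - p.EL) - w) / p.tau_w])


def _rk4_reset(p, stim, dt, t_stop, v0, rhs, is_spike, do_reset, u0, names,
               v_clamp):
    y = np.array([v0, u0(p, v0)])
    n_steps = int(round(t_stop / dt))
    t = np.arange(n_steps + 1) * dt
    out = np.empty((n_steps + 1, 2))
    resets = []
    for i in range(n_steps + 1):
        out[i] = [min(y[0], v_clamp), y[1]]
        if i == n_steps:
            break
        if is_spike(y, p):
            y = np.array(do_reset(y, p))
            resets.append(i + 1)
            continue
        ti = i * dt
        k1 = rhs(y, stim(ti), p)
        k2 = rhs(y + 0.5 * dt * k1, stim(ti + 0.5 * dt), p)
        k3 = rhs(y + 0.5 * dt * k2, stim(ti + 0.5 * dt), p)
        k4 = rhs(y + dt * k3, stim(ti + dt), p)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(y[0]):
            raise CobDivergenceError("RK4 voltage became non-finite", tick=i + 1)
    return {"t": t, "V": out[:, 0], names[1]: out[:, 1],
            "resets": np.array(resets, dtype=int)}


# -------------------------------------------- constrained-object model forms

def build_hh_store(params: HHParams, stimulus: Callable[[float], float] | float,
                   grid: TimeGrid) -> tuple[ConstraintStore, CobInstance]:
    """HH neuron as a constrained-object class.

    V, m, h, n and IExt are series variables; the coupled difference
    equations are simple constraints over previous-tick values, so every
    tick solves by local propagation.  Initial values sit at tick 1 (rest,
    steady-state gates).
    """
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    m0, h0, n0 = hh_steady_gates(0.0)

    def rates_at(v: float) -> Rates:
        return hh_rates(v - p.Vrest)

    V, m, h, n, IExt = (ref(s) for s in ("V", "m", "h", "n", "IExt"))
    pV, pm, ph, pn = prev(V), prev(m), prev(h), prev(n)
    am = call(lambda v: rates_at(v).alpha_m, pV, name="alpha_m")
    bm = call(lambda v: rates_at(v).beta_m, pV, name="beta_m")
    ah = call(lambda v: rates_at(v).alpha_h, pV, name="alpha_h")
    bh = call(lambda v: rates_at(v).beta_h, pV, name="beta_h")
    an = call(lambda v: rates_at(v).alpha_n, pV, name="alpha_n")
    bn = call(lambda v: rates_at(v).beta_n, pV, name="beta_n")
    i_ion = (p.gNaMax * pm ** 3 * ph * (pV - p.ENa)
             + p.gKMax * pn ** 4 * (pV - p.EK) + p.gL * (pV - p.EL))

    cls = define_class(
        "hh_neuron",
        attributes=[
            series("V", init={grid.t_start: p.Vrest}),
            series("m", init={grid.t_start: m0}),
            series("h", init={grid.t_start: h0}),
            series("n", init={grid.t_start: n0}),
            series("IExt"),
        ],
        constraints=[
            eq(IExt, call(stim, TIME * DT), label="stimulus"),
            eq(V, pV + DT * (prev(IExt) - i_ion) / p.Cm, label="membrane"),
            eq(m, call(_clip01, pm + DT * (am * (1 - pm) - bm * pm)), label="gate-m"),
            eq(h, call(_clip01, ph + DT * (ah * (1 - ph) - bh * ph)), label="gate-h"),
            eq(n, call(_clip01, pn + DT * (an * (1 - pn) - bn * pn)), label="gate-n"),
        ])
    store = ConstraintStore(grid)
    inst = store.instantiate(cls, name="hh")
    return store, inst


def build_izh_store(params: IzhParams, stimulus: Callable[[float], float] | float,
                    grid: TimeGrid, v0: float = -70.0
                    ) -> tuple[ConstraintStore, CobInstance]:
    """Izhikevich neuron as a constrained-object class.

    The discontinuous after-spike reset is a pair of complementary
    conditional constraints on the previous-tick voltage; a ``flag`` series
    marks reset ticks and ``Varray`` stores the display voltage clamped at
    the finite upswing cutoff Vpeak.
    """
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    V, u, flag, Varr, I = (ref(s) for s in ("V", "u", "flag", "Varray", "I"))
    pV, pu = prev(V), prev(u)
    cls = define_class(
        "izh_neuron",
        attributes=[
            series("V", init={grid.t_start: v0}),
            series("u", init={grid.t_start: p.b * v0}),
            series("flag", init={grid.t_start: 0.0}),
            series("Varray", init={grid.t_start: min(v0, p.Vpeak)}),
            series("I"),
        ],
        constraints=[
            eq(I, call(stim, TIME * DT), label="stimulus"),
            cond(pV >= p.Vpeak,
                 [eq(V, p.c, label="reset-V"),
                  eq(u, pu + p.d, label="reset-u"),
                  eq(flag, 1.0, label="spike-flag")],
                 label="spike-branch"),
            cond(pV < p.Vpeak,
                 [eq(V, pV + DT * (0.04 * pV ** 2 + 5.0 * pV + 140.0 - pu
                                   + prev(I)), label="euler-V"),
                  eq(u, pu + DT * p.a * (p.b * pV - pu), label="euler-u"),
                  eq(flag, 0.0, label="no-spike")],
                 label="smooth-branch"),
            eq(Varr, call(lambda v: min(v, p.Vpeak), V), label="upswing-clamp"),
        ])
    store = ConstraintStore(grid)
    inst = store.instantiate(cls, name="izh")
    return store, inst


def build_adex_store(params: AdExParams,
                     stimulus: Callable[[float], float] | float,
                     grid: TimeGrid, v0: float = -70.0
                     ) -> tuple[ConstraintStore, CobInstance]:
    """AdEx neuron as a constrained-object class (reset via conditionals)."""
    p = params
    stim = stimulus if callable(stimulus) else (lambda t, a=float(stimulus): a)
    V, w, flag, I = (ref(s) for s in ("V", "w", "flag", "Iin"))
    pV, pw = prev(V), prev(w)
    exp_term = call(lambda v: math.exp(min((v - p.Vt) / p.DeltaT, 20.0)), pV,
                    name="spike_initiation")
    cls = define_class(
        "adex_neuron",
        attributes=[
            series("V", init={grid.t_start: v0}),
            series("w", init={grid.t_start: 0.0}),
            series("flag", init={grid.t_start: 0.0}),
            series("Iin"),
        ],
        constraints=[
            eq(I, call(stim, TIME * DT), label="input"),
            cond(pV > p.Vcut,
                 [eq(V, p.Vr, label="reset-V"),
                  eq(w, pw + p.b, label="reset-w"),
                  eq(flag, 1.0, label="spike-flag")],
                 label="spike-branch"),
            cond(pV <= p.Vcut,
                 [eq(V, pV + DT * (-p.gL * (pV - p.EL)
                                   + p.gL * p.DeltaT * exp_term
                                   - pw + prev(I)) / p.C, label="euler-V"),
                  eq(w, pw + DT * (p.a * (pV - p.EL) - pw) / p.tau_w,
                     label="euler-w"),
                  eq(flag, 0.0, label="no-spike")],
                 label="smooth-branch"),
        ])
    store = ConstraintStore(grid)
    inst = store.instantiate(cls, name="adex")
    return store, inst
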