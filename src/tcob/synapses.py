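"""Conductance-based synapse kernels and receptor presets.

Synaptic current follows I_syn(t) = g_syn(t) · (V − E_syn), with the
conductance time course g_syn(t) given by one of three stereotyped kernels
triggered at the presynaptic spike time t0:

* single exponential — instantaneous rise to g_max, decay with constant τ;
* alpha — g_max · ((t−t0)/τ) · e^{1−(t−t0)/τ}, peaking at t0+τ;
* double exponential — separate rise and decay constants, normalized so the
  peak (at the closed-form t_peak) equals g_max exactly.

Every kernel is causal: identically zero before t0.  Multiple presynaptic
spikes superpose linearly (:func:`conductance`).

Receptor presets parameterize the double-exponential kernel for the four
canonical receptor types: AMPA (fast excitatory), NMDA (slow excitatory),
GABA_A (fast inhibitory) and GABA_B (slow inhibitory).  Excitatory reversal
is 0 mV; inhibitory reversals sit below rest.  Time constants and maximal
conductances are configurable defaults, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .engine.errors import CobParameterError

__all__ = [
    "SynapseParams", "DoubleExpDerived", "g_single_exp", "g_alpha",
    "g_double_exp", "double_exp_derived", "syn_current", "conductance",
    "receptor_preset", "RECEPTOR_DEFAULTS",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kernel parameters: conductances in nS, times in ms, potentials in mV.

    ``kind`` selects the kernel ('single_exp', 'alpha' or 'double_exp');
    ``tau`` drives the first two, ``tau_rise``/``tau_decay`` the last.
    ``t0`` is the most recent presynaptic spike time.
    """

    gmax: float = 1.0
    tau: float = 3.0
    tau_rise: float = 0.5
    tau_decay: float = 2.0
    Esyn: float = 0.0
    t0: float = 0.0
    kind: str = "double_exp"

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise CobParameterError("gmax must be non-negative")
        if self.kind in ("single_exp", "alpha") and self.tau <= 0:
            raise CobParameterError("tau must be positive")
        if self.kind == "double_exp" and not (self.tau_decay > self.tau_rise > 0):
            raise CobParameterError(
                f"double-exponential kernel needs tau_decay > tau_rise > 0, "
                f"got rise={self.tau_rise}, decay={self.tau_decay}")


@dataclass(frozen=True)
class DoubleExpDerived:
    """Derived double-exponential quantities: the normalization factor and
    the time of peak conductance (g(t_peak) = gmax by construction)."""

    f_norm: float
    t_peak: float


def double_exp_derived(p: SynapseParams) -> DoubleExpDerived:
    tr, td = p.tau_rise, p.tau_decay
    if not td > tr > 0:
        raise CobParameterError("tau_decay must exceed tau_rise (both > 0)")
    t_peak = p.t0 + (td * tr) / (td - tr) * math.log(td / tr)
    rel = t_peak - p.t0
    f_norm = 1.0 / (math.exp(-rel / td) - math.exp(-rel / tr))
    return DoubleExpDerived(f_norm=f_norm, t_peak=t_peak)


def g_single_exp(t, p: SynapseParams):
    """Instantaneous rise to gmax at t0, exponential decay with tau."""
    if p.tau <= 0:
        raise CobParameterError("tau must be positive")
    t = np.asarray(t, dtype=float)
    rel = t - p.t0
    out = np.where(rel >= 0.0, p.gmax * np.exp(-np.maximum(rel, 0.0) / p.tau), 0.0)
    return float(out) if out.ndim == 0 else out


def g_alpha(t, p: SynapseParams):
    """Alpha kernel: finite rise, peak gmax at t0 + tau."""
    if p.tau <= 0:
        raise CobParameterError("tau must be positive")
    t = np.asarray(t, dtype=float)
    rel = np.maximum(t - p.t0, 0.0)
    out = np.where(t - p.t0 >= 0.0,
                   p.gmax * (rel / p.tau) * np.exp(1.0 - rel / p.tau), 0.0)
    return float(out) if out.ndim == 0 else out


def g_double_exp(t, p: SynapseParams):
    """Difference of exponentials, normalized to peak gmax at t_peak."""
    d = double_exp_derived(p)
    t = np.asarray(t, dtype=float)
    rel = np.maximum(t - p.t0, 0.0)
    out = np.where(t - p.t0 >= 0.0,
                   p.gmax * d.f_norm * (np.exp(-rel / p.tau_decay)
                                        - np.exp(-rel / p.tau_rise)), 0.0)
    return float(out) if out.ndim == 0 else out


_KERNELS = {"single_exp": g_single_exp, "alpha": g_alpha,
            "double_exp": g_double_exp}


def conductance(t, p: SynapseParams, spike_times: Sequence[float] | None = None):
    """Total conductance at ``t``: kernels superposed over a spike history.

    ``spike_times=None`` means a single kernel triggered at ``p.t0``; an
    explicit (possibly empty) history sums the kernel over those times
    (linear superposition), so an empty history gives zero conductance.
    """
    kernel = _KERNELS[p.kind]
    if spike_times is None:
        return kernel(t, p)
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t, dtype=float)
    for ts in spike_times:
        total = total + kernel(t, replace(p, t0=float(ts)))
    return float(total) if total.ndim == 0 else total


def syn_current(g, V, Esyn: float):
    """Synaptic current I = g · (V − E_syn); negative means inward
    (depolarizing) with the convention used throughout."""
    return g * (np.asarray(V, dtype=float) - Esyn)


RECEPTOR_DEFAULTS: dict[str, SynapseParams] = {
    # rise/decay ordering: AMPA fastest, NMDA slow excitatory,
    # GABA_A fast inhibitory, GABA_B slowest
    "AMPA": SynapseParams(gmax=1.0, tau_rise=0.5, tau_decay=2.0, Esyn=0.0),
    "NMDA": SynapseParams(gmax=0.5, tau_rise=2.0, tau_decay=100.0, Esyn=0.0),
    "GABAA": SynapseParams(gmax=1.0, tau_rise=0.5, tau_decay=5.0, Esyn=-75.0),
    "GABAB": SynapseParams(gmax=0.5, tau_rise=30.0, tau_decay=150.0, Esyn=-90.0),
}


def receptor_preset(name: str, **overrides) -> SynapseParams:
    """Double-exponential parameters for a named receptor type.

    ``name`` is one of AMPA, NMDA, GABAA, GABAB (case-insensitive; GABA_A /
    GABA_B accepted).  Keyword overrides replace any field.
    """
    key = name.upper().replace("_", "")
    if key not in RECEPTOR_DEFAULTS:
        raise CobParameterError(
            f"unknown receptor {name!r}; expected one of "
            f"{sorted(RECEPTOR_DEFAULTS)}")
    return replace(RECEPTOR_DEFAULTS[key], **overrides)
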