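# tcob — temporal constrained objects for neuronal dynamics

`tcob` is a declarative, time-stepped simulation framework.  Models are
written as *constrained objects*: classes whose attributes are related by
equations rather than updated by imperative code.  A *series variable* holds
one value per tick of a discrete clock (`‵v` is its previous value, `v‵` its
next), and each simulation step instantiates the constraints at the current
tick and hands them to a solver — local propagation first, simultaneous
linear blocks next, damped iteration for anything nonlinear.  Difference
equations, conditional resets and Kirchhoff-style composition rules all
become one-line relations, and the engine guarantees that after a run every
instantiated constraint holds to within 1e-9.

On top of the engine the package ships the standard building blocks of
cellular and microcircuit neuroscience:

- **Neurons** — Hodgkin–Huxley (`C dV/dt = I_ext − g_Na m³h (V−E_Na) −
  g_K n⁴ (V−E_K) − g_L (V−E_L)` with the classic squid-axon gate kinetics),
  Izhikevich (`dV/dt = 0.04V² + 5V + 140 − u + I` with after-spike reset
  `V←c, u←u+d`), and adaptive exponential integrate-and-fire (AdEx,
  exponential spike initiation plus an adaptation current `w`).
- **Synapses** — conductance-based kernels (single-exponential, alpha,
  double-exponential with exact peak normalization) and AMPA / NMDA /
  GABA_A / GABA_B receptor presets; `I_syn = g_syn(t) (V − E_syn)`.
- **Microcircuit** — a desk-scale cerebellar granular-layer circuit: mossy
  fibres excite a granule and a Golgi cell, the Golgi cell provides
  feed-forward inhibition onto the granule cell (four excitatory and four
  inhibitory afferents by default), and the granule cell's parallel fibre
  excites a Purkinje cell.  All wiring is expressed as per-tick interface
  constraints (`GrC.MfInput = Mf.Input`, `GrC.GoCInput = GoC.Output`, ...).
- **Validation tooling** — an independent fourth-order Runge–Kutta reference
  integrator, spike-train extraction, stimulus generators (step currents,
  single spikes for in-vitro-like input, five-spike bursts for in-vivo-like
  input), CSV/spike-file I/O and a CLI.

It is aimed at modellers who want the model text to *be* the specification —
close to the mathematical notation, order-independent, and automatically
checked — at the scale of single cells and small circuits.

## Worked example

Scan step-current amplitudes for the onset of repetitive firing of the
Hodgkin–Huxley neuron (classic parameter set, rest at −70 mV, dt = 0.01 ms,
500 ms window):

```text
$ tcob sweep --i-range 1:10:1
I=1: 0 spikes
I=2: 0 spikes
I=3: 1 spikes
I=4: 1 spikes
I=5: 1 spikes
I=6: 2 spikes
I=7: 30 spikes
I=8: 32 spikes
I=9: 33 spikes
I=10: 35 spikes
repetitive firing onset: 6
```

Below 6 current units the neuron fires at most one action potential; from 6
onwards it fires repeatedly (a doublet at the boundary, sustained trains
above it), and the firing rate grows with the injected current.  A single
supra-threshold run shows the spike shape — the action potential peaks near
+40 mV (35.5 mV at this dt):

```text
$ tcob simulate --model hh --i 10 --tstop 100 --out hh10.csv
7 spikes; trace -> hh10.csv, spikes -> hh10.spikes.txt
```

The same library calls are available in Python:

```python
from tcob.neurons import HHParams, firing_onset, simulate_hh

onset, counts = firing_onset(HHParams(), range(1, 11))   # -> 6
peak = simulate_hh(HHParams(), 10.0, dt=0.01, t_stop=100.0)["V"].max()
```

Running the microcircuit under an in-vivo-like five-spike mossy-fibre burst
(defaults: 300 ms, dt = 0.1 ms, burst at 20 ms, 10 ms inter-spike interval)
writes one trace and one spike file per cell:

```text
$ tcob microcircuit --outdir mc_out
spike counts: GrC=12, GoC=5, Pc=9
```

Silencing the Golgi cell (`golgi_silenced=True` in
`tcob.network.build_microcircuit`) removes the feed-forward inhibition and
the granule cell's spike count rises — the paired comparison the test suite
checks.

For the engine itself, the canonical example is an AC circuit
(`tcob.circuit`): resistors carry `V = I·R`, capacitors the difference form
of `I = C·dV/dt`, and series/parallel composition adds the Kirchhoff
constraints as quantified relations.  The same non-directional solver that
derives `I` from `V` and `R` will equally derive `R` from `V` and `I`.

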