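# Methods

## The engine: temporal constrained objects

A model is a set of classes.  Each class declares attributes — scalars
(parameters), series variables (one value per tick), components and
component arrays — plus constraints over them.  Constraints come in four
forms: simple equations, conditionals (`guard --> consequents`), and the
quantified/aggregate forms `forall` and `sum` over a component array
(expanded into plain equations when the object is created; arrays are
static).  Constructors bind parameters and add creational constraints that
hold at the creation tick; a creational contradiction that involves no
series values (e.g. `1 = 2`) is rejected at instantiation.

**Clock.**  The built-in tick counter starts at 1 and increases by one per
step; a scale factor `dt` (default 0.01 ms per tick) converts ticks to
model time, so tick `k` is time `k·dt`.  References may reach arbitrarily
far into the past but at most one tick into the future: constraints at tick
`k` may bind values at `k` and `k+1` only, and deeper future references are
rejected at class-definition time.  None of the models here need them, and
the restriction keeps each step's unknown set finite and local.

**Stepping semantics.**  At tick `k` every registered constraint is
instantiated with solved past values substituted.  A constraint whose past
reference lands before any available value is skipped at that tick — this
is the standard warm-up of a difference equation: an update rule written
against `‵v` first fires one tick after `v`'s initializer.  (The standalone
`resolve_series` query, by contrast, raises an under-determined error for
such references, since there the caller asked for a definite value.)
Conditional guards are evaluated on determined values only; if a guard's
operand is still unknown, single-unknown equations are solved first and the
guard re-examined — a two-phase loop that reproduces the on–off-controller
and voltage-reset semantics without a full constraint-logic system.  Guards
that remain undeterminable when the step ends leave their consequents
untriggered.

**Solving.**  Three stages, in order:

1. *Local propagation to fixpoint.*  Any equation with one unknown is
   solved immediately — direct assignment when the unknown stands alone on
   one side; otherwise the residual is probed at three points, solved
   exactly if affine, and by damped secant iteration if not.
2. *Simultaneous linear blocks.*  Remaining equations are probed for joint
   linearity in their unknowns (unit-vector probes plus an asymmetric
   verification point) and solved with dense linear algebra; rank
   deficiency maps to an under-determined error, inconsistent residuals to
   an inconsistency error.
3. *Nonlinear blocks.*  Damped Gauss–Seidel with secant updates (damping
   0.5, tolerance 1e-9, at most 100 iterations), warm-started from the
   previous tick.  The in-scope models never reach this stage; it exists so
   the solver is total over the constraint language.

Solved values are immutable: a second binding must agree to within the
store tolerance (1e-9) or the step fails.  Under-determined systems fail
loudly rather than picking a value, because a silent choice would not be a
model solution.  Determined systems make the result independent of
declaration order: every unknown receives the unique consistent value, and
both the property tests and the model tests permute constraint lists to
confirm traces agree to 1e-12.

After a run, `residual_sweep()` re-evaluates every constraint instance that
was active at every tick and reports the worst |lhs − rhs|; the test suite
requires ≤ 1e-9 for every model, including the full microcircuit.

## AC-circuit library

Resistors carry `V = I·R`; capacitors use the backward difference
`I(k) = C·(V(k) − V(k−1))/dt` (initial voltage 0 unless configured);
sources fix `V(k) = A·sin(ω·k·dt)` (sine convention, ω in rad/ms).  Series
composition equates currents and sums voltages; parallel composition
equates voltages and sums currents.  A closed loop has no external
terminal, so the top-level composite additionally carries `I = 0` — without
this closure the source branch current is genuinely under-determined, and
the engine would (correctly) refuse to run.  The demonstration circuit is a
resistor–capacitor series branch in parallel with a sinusoidal source and a
second resistor.

The backward-difference capacitor makes the scheme first order: the test
suite checks that the step-response error against the analytic exponential
halves when dt halves, and that the driven series-RC steady-state current
amplitude matches the impedance formula `A/√(R² + 1/(ωC)²)` within 2 % at
dt = 0.005 ms.

## Neuron models

All voltages are mV, all times ms, and every simulation starts at the
initial resting potential of −70 mV.  Currents are taken at face value in
each model's own units (the HH scale is the classic µA/cm²-like unit; the
AdEx scale is pA) without dimensional reconciliation — the sources for
these desk-scale cells mix the conventions, and nothing downstream depends
on the absolute scale.

**Hodgkin–Huxley.**  Parameters are the classic squid-axon set shifted so
rest sits at −70 mV: Cm = 1 µF/cm², gNa = 120, gK = 36, gL = 0.3 mS/cm²,
ENa = Vrest+115, EK = Vrest−12, EL = Vrest+10.6 mV.  The rate functions
α, β are evaluated at the depolarization `V − Vrest` (the classic
convention with rest at 0) while the integrated voltage is absolute; the
removable singularities of α_m (at +25 mV) and α_n (at +10 mV) return
their analytic limits so the functions are total.  Gates start at their
steady-state values α/(α+β) and are clipped to [0, 1] after each update.
Integration is forward Euler at dt = 0.01 ms by default; the EL offset
makes rest an exact equilibrium, and the suite verifies drift < 0.5 mV
over 100 ms.

*Repetitive-firing onset.*  `firing_onset` scans step-current amplitudes
and reports the smallest one whose spike count reaches `min_spikes`
(default 2: more than one action potential is repeated firing; a doublet
counts).  With the classic set the integer scan computed by the suite gives
counts 0,0,1,1,1,2,30,… for amplitudes 1…7, so the onset is 6; the
transition to indefinitely sustained trains lies between 6 and 7 (the
doublet at 6 sits at the boundary of the model's bistable window).  Callers
who want "sustained" rather than "repetitive" can pass `min_spikes=3`,
which moves the reported onset to 7 — the parameter makes the definition
explicit rather than baked in.

**Izhikevich.**  `dV/dt = 0.04V² + 5V + 140 − u + I`,
`du/dt = a(bV − u)`, with reset `V←c, u←u+d` applied when the
previous-tick voltage reaches Vpeak = 30 mV — the reset is triggered by the
*membrane voltage*, and the finite upswing is clamped at Vpeak in the
display series (`Varray` in the constrained-object form, where a `flag`
series marks reset ticks).  The recovery variable starts at its
subthreshold fixed point `b·V₀`.  Presets cover regular spiking
(a=0.02, b=0.2, c=−65, d=8), chattering (c=−50, d=2) and fast spiking
(a=0.1).  Default dt = 0.1 ms.

**AdEx.**  `C dV/dt = −gL(V−EL) + gL·ΔT·exp((V−Vt)/ΔT) − w + Iin`,
`τw dw/dt = a(V−EL) − w`, reset `V←Vr, w←w+b` when the previous-tick
voltage exceeds Vcut = 0 mV.  The exponential argument is capped at 20 so
the one-tick pre-reset upswing cannot overflow.  Presets: a generic tonic
cell (b = 0) and an adapting cell (b = 60 pA, τw = 300 ms) for the
firing-pattern galleries, plus desk-scale cerebellar cells — granule
(C = 3.1 pF, gL = 0.43 nS), Golgi (C = 20 pF) and Purkinje (C = 75 pF) —
whose rheobases sit below the 10 pA current-clamp protocol.  These presets
are configuration chosen for qualitative firing behaviour at desk scale,
not fitted reproductions of any recorded cell.

**Reference integrator.**  `integrate_reference` runs classic RK4 over the
same right-hand sides (resets applied between smooth steps).  It is a
testing oracle only: the suite checks it against a closed-form exponential
relaxation to 1e-8, and checks that the Euler-vs-RK4 sup-norm voltage
discrepancy shrinks monotonically as dt halves 0.04 → 0.02 → 0.01 ms.  The
discrepancy at spiking amplitudes is dominated by spike-time shifts and is
therefore large in absolute terms; the criterion is its monotone decrease,
consistent with the first-order Euler scheme.

**Spike detection.**  For reset models, spike times are the reset ticks ×
dt.  For continuous traces, spikes are upward crossings of a threshold
(default −20 mV), one spike per crossing.

## Synapses

`I_syn = g_syn(t)·(V − E_syn)`.  Kernels: single exponential (instant rise
to gmax, e-folding decay), alpha (`gmax·((t−t0)/τ)·e^{1−(t−t0)/τ}`, peak
gmax at t0+τ), and double exponential with normalization
`f_norm = 1/(e^{−Δ/τd} − e^{−Δ/τr})` at
`t_peak = t0 + (τd·τr/(τd−τr))·ln(τd/τr)`, which makes `g(t_peak) = gmax`
exact — the suite enforces both peak identities to 1e-9, and the
double-exponential degenerates to the alpha shape as τr → τd (checked at
ratio 1.001, < 1 % relative L2).  All kernels are identically zero before
t0, and multiple presynaptic spikes superpose linearly.

Receptor presets (double-exponential; rise/decay in ms): AMPA 0.5/2,
NMDA 2/100, GABA_A 0.5/5, GABA_B 30/150; excitatory reversal 0 mV,
GABA_A −75 mV, GABA_B −90 mV; gmax of order 1 nS.  The values are
configurable defaults that honour the qualitative ordering (AMPA fastest,
NMDA slow excitatory, GABA_A fast / GABA_B slow inhibitory), not
measurements.  No NMDA magnesium-block voltage dependence is modelled —
the formulation used here defines none; the kernel interface accepts a
replacement if one is needed.

## Composite neurons and the microcircuit

A composite neuron aggregates an AdEx cell with synapse objects and posts
the per-tick aggregation constraint `Iin = Σ I_synapse (+ I_ext)`.  Inside
the network module a synapse's current series uses the *delivered* sign
`I = g·(E_syn − V)` (depolarizing positive) so the sum feeds the cell's
input current directly; the electrophysiological membrane-current
convention `g·(V − E_syn)` remains the standalone `syn_current`.  The
postsynaptic voltage in the current law is the previous-tick value, keeping
every tick explicit.

Wiring follows the granular-layer pathway with one cell per population:
mossy fibre → granule and Golgi (AMPA), Golgi → granule (GABA_A by
default; feed-forward inhibition), granule → parallel fibre (a pure relay)
→ Purkinje (AMPA).  Connection multiplicity is realized as synapse
instances: exactly 4 excitatory and 4 inhibitory afferents onto the granule
cell by default, or Poisson(4) counts under a mandatory seed.  Spikes
propagate to downstream synapses with a one-tick axonal delay — zero delay
would create within-tick constraint cycles, and the sources are silent on
the value.  Golgi inhibition uses GABA_A (configurable); one granule cell
feeds the Purkinje cell (configurable gmax lumps the parallel-fibre
population).  All interface constraints (`GrC.MfInput = Mf.Input`,
`GoC.Output = GoC.SpikeTrain`, `Pf.Input = GrC.Output`, ...) are ordinary
per-tick equalities in the store, so the routing audit is just a series
comparison and the residual sweep covers the wiring.

Silencing the Golgi cell for paired comparisons replaces the
`GrC.GoCInput = GoC.Output` wire with `GrC.GoCInput = 0`, leaving
everything else identical.  The modelled cells are not spontaneously
active (real Golgi cells are pacemakers; this one only fires on input), so
zero mossy input leaves the whole circuit quiescent.

## Stimuli and I/O

Step currents hold an amplitude on [onset, offset); bursts are `n` spikes
(default 5, the in-vivo-like input; `n = 1` is the in-vitro-like single
spike) spaced by a default 10 ms inter-spike interval — the count is
specified by the protocol, the spacing is a package default.  Bursts
extending beyond the simulated horizon are truncated with a warning.
Traces serialize to CSV with a fixed `time,...` header (time in ms, 6
decimals); spike files are plain text, one ms value per line, and all
writers/readers are mutual inverses on valid data.  Configuration is JSON
(YAML accepted), and each CLI run echoes its fully resolved parameters and
seed into a manifest JSON.

## Problem sizes and determinism

Everything here is desk scale and deterministic (the only randomness is
the optional Poisson connectivity draw, which requires a seed).  The test
suite runs the HH model for up to 500 ms at dt = 0.01 ms on the fast path,
and the constrained-object forms for 20–150 ms windows where the
declarative semantics are what is under test; the microcircuit runs 100–150
ms at dt = 0.1 ms.  These windows are chosen so each behaviour of interest
(onset scan, adaptation, feed-forward inhibition) is fully expressed.

## Known limitations

- Units are taken at face value from the model definitions; no dimensional
  analysis reconciles the HH current scale with the pA scale of the
  reset models.
- Forward Euler throughout the simulation path (first order); the RK4
  integrator is an oracle, not an alternative backend.
- Single-compartment cells, one cell per microcircuit population, static
  connectivity, no plasticity, no receptor saturation, no synaptic noise
  or jitter — the synthetic stimuli are deterministic, so passing tests
  say nothing about robustness to biological variability.
- The engine's per-step future horizon is one tick; models needing deeper
  look-ahead are out of scope by design.
- Non-series-parallel circuit topologies are not expressible in the
  composition vocabulary of the circuit library.
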