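# Methods

This note records the models, conventions and numerical choices behind
`spikering`, in the spirit of a simulator methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and design stance

The package re-expresses the spike-propagation and effect-application
algorithms of data-parallel (GPU) network backends as deterministic sequential
semantics.  Parallel-hardware behaviour itself — thread blocks, occupancy,
atomic-operation scheduling, reallocation cost — is explicitly out of scope;
what is preserved is the *observable contract* of each structure: which
synapses are due on which step, and what the accumulated effect on each target
is.  Three substitutions follow from this stance:

* The atomic-counter construction of the spiking-neuron array has
  nondeterministic order on parallel hardware; here the canonical order is
  ascending neuron id, making runs bit-reproducible.
* Atomic adds during effect application become a fixed reduction: due synapse
  ids are sorted ascending and accumulated per target with one weighted
  bincount.  Any permutation of delivery order therefore produces a bitwise
  identical state.
* The per-partition critical section that serialises queue pushes becomes
  plain sequential iteration; queue contents are treated as sets by their
  consumer.

Because of these choices, the simulator is invariant — bit for bit — under
the number of connectivity partitions and under bundle mode (bundles vs
per-synapse queueing).  The test suite asserts this at N = 2000 over 5 s.

## Clock and schedule

Time advances in fixed steps Δt (default 0.1 ms).  Every step executes, in
order: (1) state updates and Poisson generation; (2) spike detection;
(3) per synapse population, delay-structure advance and effect application
(pre-triggered pathway, then the undelayed post-triggered plasticity
pathway); (4) resets and refractory bookkeeping; (5) monitor sampling;
(6) clock increment.  This mirrors the reference ordering
`state update → threshold → synapses → reset`.  Two consequences are
documented contracts:

* an effect delivered at step *n + k* modifies its target *after* that step's
  detection, so it can first influence spiking at step *n + k + 1*;
* monitors sample after resets, so a spiking neuron's recorded voltage is the
  reset value.

## LIF model

`dV = (μ_ext − V)·dt/τ + σ_ext·√(2·dt/τ)·η`, `η ~ N(0,1)` per neuron per step
(Euler–Maruyama).  The `√(2·dt/τ)` scaling pins `σ_ext` as the *stationary*
standard deviation of the free process, whose stationary law is
N(μ_ext, σ_ext²); the suite verifies both moments within 3 standard errors
over 10⁷ samples, using the Ornstein–Uhlenbeck integrated autocorrelation time
(≈ 2τ/dt steps) for the effective sample count.

Conventions, pinned and tested:

* **Strict threshold**: a neuron spikes when `V > Θ`, not `≥`.
* **Refractoriness**: a spike at step *n* clamps `V = V_r` and suspends
  integration while `step < n + round(τ_ref/dt)`; bookkeeping is in integer
  steps, so the earliest next spike is exactly τ_ref later (minimum
  inter-spike interval equals τ_ref).  The clamp is re-applied in the reset
  kernel, so synaptic effects landing on a refractory neuron cannot move its
  observable voltage.  (Whether the membrane is clamped during refractoriness
  is a convention; this package clamps.)
* The noise stream draws one normal per neuron per step regardless of
  refractory state, keeping stream consumption independent of the dynamics.

## Conductance-based HH model

Six ODEs per neuron (v; gates m, h, n; conductances g_e, g_i) with the
classic Traub–Miles-derived rate functions, using the widely circulated
benchmark constants for a 20,000 µm² patch (C_m = 200 pF, g_l = 10 nS,
E_l = −60 mV, ḡ_Na = 20 µS, E_Na = 50 mV, ḡ_K = 6 µS, E_K = −90 mV,
V_T = −63 mV, τ_e = 5 ms, τ_i = 10 ms, E_e = 0, E_i = −80 mV).  All constants
are package conventions and fully overridable; none is treated as a quantity
to reproduce.

Integration is exponential Euler: each variable is advanced with the others
frozen at their start-of-step values using the exact exponential solution of
the resulting linear ODE.  Gates therefore remain in [0, 1] for any dt.  The
rational rate functions are evaluated through `exprel`, removing their
removable singularities.

Spike detection is a strict crossing `v > −20 mV` with a 3 ms detection
lockout and *no reset* — the dynamics produce the action potential.  Note that
with the default constants the model is intrinsically rhythmic: the sodium
window current outweighs the leak at subthreshold voltages, so there is no
stable subthreshold rest (the only membrane equilibrium is depolarised and
unstable).  `hh.equilibrium_state` finds that fixed point for verification;
`hh.leak_state` (v = E_l, gates at steady state) is the default population
initialisation, and the HH benchmark uses Gaussian-randomised initial
conditions (v ~ E_l + (5·randn − 5) mV, g_e ~ (1.5·randn + 4)·10 nS,
g_i ~ (12·randn + 20)·10 nS, clipped at 0, gates at x_∞(v)).

At dt = 0.1 ms the exponential-Euler firing period carries an O(dt) error of a
few percent relative to a dt/100 reference; the self-convergence test
therefore compares spike counts over a window spanning a few periods.

## Connectivity and delays

Bernoulli sampling: every ordered pair (self-pairs included by default) is an
independent trial with p = min(C/n_pre, 1), so populations smaller than C
become complete graphs.  Edges are generated in (pre, post) row-major order;
synapse ids are assigned in that input order before any sorting, and all sorts
are stable, so rebuilds are identical.

Delays are stored as integer steps only.  Discretisation is round-to-nearest
with **ties to even**: under this rule a U(0, 4) ms delay distribution at
dt = 0.1 ms occupies all 41 step values {0, …, 40}, whereas floor rounding
would occupy 40 — the tie rule is pinned by that distinct-value count.

Partitions are contiguous blocks of target ids of size ceil(n/P) (the
original leaves the mapping unspecified; contiguous-ceil is this package's
choice).  Bundles group each (neuron, partition) synapse group by delay; in
per-synapse mode every synapse is its own singleton bundle.

## Delay structures

Within a step the order is **push, then pop, then rotate**.  This makes a
k = 0 structure reduce exactly to direct same-step application, unifying the
no-delay, homogeneous and heterogeneous paths under one schedule (the
original does not state the within-step order; this one is pinned by the
k = 0 consistency argument).

Queue capacities only grow (Python lists give amortised doubling; high-water
marks are tracked so the monotone-capacity contract is observable).  A bundle
id never appears twice in the same queue, but it *can* legitimately sit in two
different queues of one partition at once — a neuron may spike twice within
the maximum delay window (τ_ref = 2 ms < 4 ms max delay) — and delivery
conservation (each spike × synapse delivered exactly once, exactly
delay_steps later) is the authoritative contract, verified against a naive
event-list oracle.

## Plasticity

All-to-all additive pair-based STDP with per-synapse traces and event-driven
decay (`a ← a·exp(−Δt_elapsed/τ)` evaluated only at events; elapsed time kept
in integer steps).  On a presynaptic arrival (spike time + axonal delay):
decay both traces → depress `w += a_post` → clip to [0, w_max] → `a_pre +=
A_pre` → increment the postsynaptic conductance with the **updated** weight →
stamp the event time.  On a postsynaptic spike (undelayed, dispatched through
the post-sorted dual matrix): decay → facilitate `w += a_pre` → clip →
`a_post += A_post`.  Coincident pre and post events at one synapse process the
pre pathway first (engine tie-break).  Whether the conductance kick uses the
pre- or post-depression weight is a convention; the post-update choice is
pinned here because the depression itself is defined to use the *current*
(decayed) trace.

Constants default to the canonical pair-based example set — τ_pre = τ_post =
20 ms, A_pre = 0.01·w_max, A_post = −1.05·A_pre, w_max = 0.01 — labelled
conventions, all overridable.  Isolated pairings reproduce
±A·e^(−Δ/τ) to 1e-10 relative tolerance, and the event-driven update matches
a clock-driven per-step reference to the same tolerance.

The conductance-based LIF target of the plasticity benchmark is likewise the
canonical example configuration (τ_m = 10 ms, E_l = −74 mV, E_e = 0,
v_th = −54 mV, v_r = −60 mV, τ_e = 5 ms, dimensionless g_e), integrated by
exponential Euler with g_e frozen over the step.

## Randomness

One master seed fans out into named Philox (counter-based) streams per
(purpose, population): membrane noise, Poisson trials, connectivity, delays,
weights, initial conditions.  Structural randomness is therefore independent
of dynamical randomness, and partition count/bundle mode consume no
randomness at all.  Stream names are hashed with CRC-32 into SeedSequence
spawn keys.

## Benchmark generators and what they do not emulate

The three builders construct networks purely from their stated parameters and
echo the resolved parameter set into the run manifest.  They emulate the
*structure and drive* of the reference models — not biological realism beyond
it: no conduction-velocity geometry behind the delay distributions, no
synaptic failure or short-term plasticity, stationary Poisson input, and the
HH benchmark's weights are deliberately too small to couple the dynamics (its
purpose is to exercise propagation machinery, and coupled vs uncoupled runs
are verified to spike identically over the test window).  Passing tests
establish the correctness of the propagation/plasticity semantics at these
study conditions; they are not evidence about fitted biological data.

## Problem sizes used by the shipped checks

The suite runs the structural-equivalence check at N = 2000 for 5 s, the
qualitative-dynamics check at N = 5000 for 10 s (heterogeneous delays), the
stationarity check on 10⁷ samples, and conservation oracles on networks of
≤ 50 neurons; `scripts/acceptance.py` uses 1,000 generators × 10 s for the
Poisson rate and N = 10,000 for the degree statistic.  These sizes are the
package's chosen desk-scale study conditions.

## Degenerate inputs and faults

Empty spike lists, empty edge lists and zero-duration runs are valid no-ops.
Non-finite state aborts with step context (`SimulationError`); undersampled
Poisson rates (rate·dt > 1), invalid partition counts, negative delays,
mis-sized queue structures and unknown target variables raise
`ConfigurationError`-family faults.  Causality violations in event-driven
updates (event before the synapse's last update) fault rather than silently
decay by a negative time.

## Known limitations

* Arbitrary user-defined equations (a DSL/code generation) are out of scope;
  the implemented pathways are the static-increment and pair-based STDP ones
  the benchmarks exercise.
* Only the postsynaptically partitioned pre-sorted matrix and its post-sorted
  dual exist; effects onto presynaptic neurons or synapse-variable expressions
  beyond the STDP state are not supported.
* One clock per network; no customisable scheduling slots.
* The heterogeneous queue push loop is pure Python per spiking neuron; it is
  sized for desk-scale networks (≲ 10⁴ neurons, ≲ 10⁷ synapses), not for
  maximum-throughput simulation.
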