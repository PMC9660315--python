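# spikering

A deterministic, desk-scale simulator for clock-driven spiking neural
networks, built around the data-parallel propagation algorithms used by
GPU network simulators — re-expressed as exact, bit-reproducible sequential
semantics:

* **Compressed partitioned connectivity** — synapses stored YALE/CSR-style as
  one concatenated array of synapse ids sorted by (presynaptic neuron,
  postsynaptic partition, synapse id), plus per-synapse pre/post/delay/weight
  lookups.  A dual matrix sorted by postsynaptic neuron dispatches
  postsynaptically triggered plasticity updates.
* **Circular spike buffers** for homogeneous transmission delays *d = kΔt*:
  a ring of *k + 1* spiking-neuron arrays whose labels rotate once per step,
  making delayed propagation an index rotation.
* **Bundle-based spike queues** for heterogeneous delays: synapses sharing
  (presynaptic neuron, partition, delay) form a *synapse bundle*; when a
  neuron spikes, its bundles are pushed into per-partition rings of *k + 1*
  queues keyed by delay, and the *0Δt* queues are consumed each step.
* **Order-independent effect application** — synaptic increments are
  accumulated per target in a fixed ascending-synapse-id reduction, so results
  are bitwise identical across partition counts, bundle modes, and delivery
  permutations (the deterministic stand-in for atomic adds).
* **Event-driven pair-based STDP** — per-synapse weight and two exponentially
  decaying traces, updated analytically only at spike events; axonal delays
  apply to the presynaptic pathway only, the postsynaptic pathway is
  undelayed; weights hard-clipped to [0, w_max].

## Who this is for

Anyone who needs small-to-medium spiking network simulations whose *semantics*
match the parallel-backend algorithms — e.g. for validating propagation
machinery, studying delay structures, or producing exactly reproducible
reference spike trains — without a GPU.

## Models

* Noise-driven **LIF** neurons, Euler–Maruyama:
  `dV = (μ_ext − V) dt/τ + σ_ext √(2dt/τ) η`, strict threshold `V > Θ`,
  reset to `V_r`, refractory clamp for `τ_ref`.  The built-in `lif` benchmark
  is the classic sparse recurrent-inhibition network (Θ = 20 mV, V_r = 10 mV,
  τ = 20 ms, J = 0.1 mV, τ_ref = 2 ms, C = 1000 synapses/neuron; d = 2 ms with
  μ/σ = 25/1 mV, or d ~ U(0, 4) ms with μ/σ = 27/0.33 mV) which exhibits fast
  global oscillations with low single-neuron rates.
* Conductance-based **Hodgkin–Huxley** neurons (six ODEs, exponential-Euler),
  80/20 excitatory/inhibitory benchmark with Bernoulli connectivity and
  vanishing weights U(0, 10⁻¹⁸ S).
* **Poisson generators** (one Bernoulli trial per step) driving plastic
  feedforward synapses onto conductance-based LIF targets (the `stdp`
  benchmark: N generators at 15 s⁻¹, N/1000 targets, mean in-degree 1000).

## Worked example

```bash
spikering run --model lif --n 2000 --delay-mode heterogeneous \
    --duration 1.0 --seed 1 --partitions 4 --out out/
```

prints

```
simulated 10000 steps of 1.0 s at dt=0.0001 s
recorded 8272 spikes (mean rate 4.136 /s over 2000 neurons)
wrote: out/spikes.tsv, out/rate.tsv, out/run.json
```

Each of the 2000 neurons fires ~4 times per second, yet the population rate
(`rate.tsv`, fraction of neurons spiking per 0.1 ms step) oscillates globally —
its spectrum peaks near 155 Hz for this seed — the hallmark regime of sparse
strong inhibition with delays: individual neurons fire rarely and
irregularly while the population rhythm is fast.  Rerunning with
`--partitions 1` or `--bundles off` reproduces the identical spike train
byte for byte.

The same networks are available from Python:

```python
from spikering import BenchmarkConfig, SpikeMonitor, build_benchmark

net = build_benchmark(BenchmarkConfig(name="lif", N=2000,
                                      delay_mode="heterogeneous", seed=1))
net.add_monitor(SpikeMonitor("lif"))
result = net.run(1.0)
print(result.spikes.n_spikes)   # 8272
```

`spikering validate` runs quick structural self-checks (ring periodicity,
zero-delay reduction, delivery conservation against a naive event-list oracle,
and the two-neuron delay/amplitude probe).

## On-disk formats

Edge lists are tab-separated text (`pre  post  delay_steps  weight`, `#`
header); adjacency can be exported/imported as MatrixMarket coordinate files.
Monitors write `spikes.tsv`, `rate.tsv`, `state.tsv` and a `run.json` manifest
(resolved configuration, seed, versions); times are seconds at full precision.

See `docs/methods.md` for the model conventions, numerical choices, and known
limitations.
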