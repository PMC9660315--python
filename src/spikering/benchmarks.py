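"""Builders for the reference benchmark networks.

Three network families, constructed purely from printed parameters:

* **lif** — N noise-driven LIF neurons with sparse random recurrent inhibition
  (the classic sparse-inhibition fast-oscillation network): threshold 20 mV,
  reset 10 mV, tau 20 ms, refractory 2 ms, coupling J = 0.1 mV, Bernoulli
  connectivity p = C/N with C = 1000 (complete graph for N < 1000,
  self-connections included).  Homogeneous variant: d = 2 ms for every
  synapse, drive mu = 25 mV / sigma = 1 mV; heterogeneous variant:
  d ~ U(0, 4) ms, drive mu = 27 mV / sigma = 0.33 mV.

* **stdp** — N Poisson generators at 15 s^-1 with plastic feedforward synapses
  onto N/1000 conductance-based LIF neurons; mean in-degree C = 1000 per
  target (so each generator has on average one outgoing synapse).  Delays are
  axonal: they apply to the pre-triggered pathway only.

* **hh** — N conductance-based HH neurons (80% excitatory / 20% inhibitory)
  with Gaussian-randomised initial conditions; when coupled, Bernoulli
  recurrent connectivity p = C/N with weights ~ U(0, 1e-18 S) (deliberately
  too small to alter the dynamics) and no delays.

Every builder is a pure function of (config, seed) and echoes its resolved
parameters into ``network.meta`` for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import connectivity as cn
from . import core_state as cs
from . import effects as fx
from . import hh as hhmod
from .engine import CondLIFParams, Network
from .errors import ConfigurationError
from .monitors import RateMonitor, SpikeMonitor, StateMonitor
from .rng import stream

__all__ = [
    "BenchmarkConfig",
    "build_lif_benchmark",
    "build_stdp_benchmark",
    "build_hh_benchmark",
    "build_benchmark",
    "two_neuron_probe",
    "run_validation_suite",
]

# external drive (mu_ext, sigma_ext) per delay variant, volts
_LIF_DRIVE = {
    "homogeneous": (25e-3, 1e-3),
    "heterogeneous": (27e-3, 0.33e-3),
    "none": (25e-3, 1e-3),
}
_HOMOGENEOUS_DELAY = 2e-3  # s
_HETEROGENEOUS_RANGE = (0.0, 4e-3)  # s, uniform
_POISSON_RATE = 15.0  # s^-1


@dataclass
class BenchmarkConfig:
    """Which benchmark to build and under which structural options."""

    name: str  # "lif" | "stdp" | "hh"
    N: int
    delay_mode: str = "homogeneous"  # "none" | "homogeneous" | "heterogeneous"
    coupled: bool = True  # hh only
    seed: int = 0
    partitions: int = 1
    bundle_mode: bool = True
    C: float = 1000.0
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ConfigurationError("N must be >= 1")
        if self.name not in ("lif", "stdp", "hh"):
            raise ConfigurationError(f"unknown benchmark {self.name!r}")
        if self.delay_mode not in ("none", "homogeneous", "heterogeneous"):
            raise ConfigurationError(f"unknown delay mode {self.delay_mode!r}")
        if self.name == "hh" and self.delay_mode != "none":
            raise ConfigurationError("the HH benchmark has no synaptic delays")


def _attach_delays(edges: cn.EdgeList, mode: str, seed: int, name: str,
                   clock: cs.SimClock) -> None:
    if mode == "homogeneous":
        edges.delay_steps[:] = cn.discretize_delays(
            np.full(len(edges), _HOMOGENEOUS_DELAY), clock
        )
    elif mode == "heterogeneous":
        lo, hi = _HETEROGENEOUS_RANGE
        seconds = stream(seed, "delays", name).uniform(lo, hi, len(edges))
        edges.delay_steps[:] = cn.discretize_delays(seconds, clock)


def build_lif_benchmark(cfg: BenchmarkConfig) -> Network:
    """Sparse recurrent-inhibition LIF network, homogeneous or heterogeneous delays."""
    if cfg.name != "lif":
        raise ConfigurationError("config is not a lif benchmark")
    mu, sigma = _LIF_DRIVE[cfg.delay_mode]
    params = cs.LIFParams(mu_ext=mu, sigma_ext=sigma)
    net = Network(dt=cfg.dt, seed=cfg.seed)
    pop = net.add_lif("lif", cfg.N, params)
    # start uniformly between reset and threshold to avoid artificial synchrony
    pop.state.v = stream(cfg.seed, "init", "lif").uniform(
        params.v_reset, params.theta, cfg.N
    )
    spec = cn.ConnectivitySpec(cfg.N, cfg.N, cfg.C, allow_self=True)
    edges = cn.sample_bernoulli(spec, stream(cfg.seed, "connectivity", "lif"))
    edges.weight[:] = params.J
    _attach_delays(edges, cfg.delay_mode, cfg.seed, "lif", net.clock)
    net.connect(
        "inhibition", "lif", "lif", edges,
        delay_mode=cfg.delay_mode, partitions=cfg.partitions,
        bundle_mode=cfg.bundle_mode,
        effect=fx.StaticEffect(target="v", sign=-1.0),
    )
    net.meta = {"benchmark": asdict(cfg), "lif_params": vars(params),
                "n_synapses": len(edges)}
    return net


def build_stdp_benchmark(cfg: BenchmarkConfig) -> Network:
    """Poisson generators with plastic feedforward synapses onto LIF targets."""
    if cfg.name != "stdp":
        raise ConfigurationError("config is not a stdp benchmark")
    n_targets = cfg.N // 1000
    if n_targets < 1:
        warnings.warn(
            f"N={cfg.N} < 1000: falling back to a single target neuron",
            stacklevel=2,
        )
        n_targets = 1
    net = Network(dt=cfg.dt, seed=cfg.seed)
    net.add_poisson("gen", cfg.N, _POISSON_RATE)
    target_params = CondLIFParams()
    net.add_cond_lif("lif", n_targets, target_params)
    spec = cn.ConnectivitySpec(cfg.N, n_targets, cfg.C, allow_self=True)
    edges = cn.sample_bernoulli(spec, stream(cfg.seed, "connectivity", "ff"))
    _attach_delays(edges, cfg.delay_mode, cfg.seed, "ff", net.clock)
    stdp = fx.STDPParams()
    w_init = stream(cfg.seed, "weights", "ff").uniform(0.0, stdp.w_max, len(edges))
    net.connect(
        "plastic", "gen", "lif", edges,
        delay_mode=cfg.delay_mode, partitions=cfg.partitions,
        bundle_mode=cfg.bundle_mode, stdp=stdp, w_init=w_init,
    )
    net.meta = {"benchmark": asdict(cfg), "stdp_params": vars(stdp),
                "target_params": vars(target_params),
                "poisson_rate": _POISSON_RATE,
                "n_targets": n_targets, "n_synapses": len(edges)}
    return net


def build_hh_benchmark(cfg: BenchmarkConfig) -> Network:
    """Conductance-based HH population, optionally with tiny-weight recurrence."""
    if cfg.name != "hh":
        raise ConfigurationError("config is not an hh benchmark")
    params = hhmod.HHParams()
    n_exc = int(round(0.8 * cfg.N))
    rng = stream(cfg.seed, "init", "hh")
    v = params.e_leak + (rng.standard_normal(cfg.N) * 5.0 - 5.0) * 1e-3
    g_e = np.clip((rng.standard_normal(cfg.N) * 1.5 + 4.0) * 10e-9, 0.0, None)
    g_i = np.clip((rng.standard_normal(cfg.N) * 12.0 + 20.0) * 10e-9, 0.0, None)
    m, h, n_gate = hhmod.gating_steady_state(v, params)
    state = hhmod.HHState(
        v=v, m=m, h=h, n_gate=n_gate, g_e=g_e, g_i=g_i,
        refractory_until_step=np.zeros(cfg.N, dtype=np.int64),
    )
    net = Network(dt=cfg.dt, seed=cfg.seed)
    net.add_hh("hh", cfg.N, params, state)
    n_synapses = 0
    if cfg.coupled:
        w_max = 1e-18  # siemens; deliberately without substantial effect
        spec = cn.ConnectivitySpec(cfg.N, cfg.N, cfg.C, allow_self=True)
        edges = cn.sample_bernoulli(spec, stream(cfg.seed, "connectivity", "hh"))
        edges.weight[:] = stream(cfg.seed, "weights", "hh").uniform(
            0.0, w_max, len(edges)
        )
        n_synapses = len(edges)
        is_exc = edges.pre < n_exc
        for label, mask, target in (
            ("exc", is_exc, "g_e"),
            ("inh", ~is_exc, "g_i"),
        ):
            sub = cn.EdgeList(
                edges.pre[mask], edges.post[mask],
                edges.delay_steps[mask], edges.weight[mask],
                cfg.N, cfg.N,
            )
            net.connect(
                f"recurrent_{label}", "hh", "hh", sub,
                delay_mode="none", partitions=cfg.partitions,
                effect=fx.StaticEffect(target=target, sign=1.0),
            )
    net.meta = {"benchmark": asdict(cfg), "hh_params": vars(params),
                "n_exc": n_exc, "n_inh": cfg.N - n_exc,
                "n_synapses": n_synapses}
    return net


_BUILDERS = {
    "lif": build_lif_benchmark,
    "stdp": build_stdp_benchmark,
    "hh": build_hh_benchmark,
}


def build_benchmark(cfg: BenchmarkConfig) -> Network:
    return _BUILDERS[cfg.name](cfg)


def attach_monitors(net: Network, population: str, kinds=("spikes", "rate")) -> None:
    for kind in kinds:
        if kind == "spikes":
            net.add_monitor(SpikeMonitor(population))
        elif kind == "rate":
            net.add_monitor(RateMonitor(population))
        elif kind == "state":
            net.add_monitor(StateMonitor(population, variables=("v",), neurons=(0,)))
        else:
            raise ConfigurationError(f"unknown monitor kind {kind!r}")


def two_neuron_probe(dt: float = 1e-4, n_steps: int = 60) -> dict:
    """Two-neuron delay/amplitude probe using the homogeneous benchmark synapse.

    Neuron 0 is forced to spike at step 0 (noise silenced, supra-threshold
    initial voltage); neuron 1 is silent and records its membrane potential
    every step.  Returns the measured lag between the presynaptic spike and
    the postsynaptic deflection (ms) and the deflection magnitude (mV).
    """
    params = cs.LIFParams(mu_ext=0.0, sigma_ext=0.0)
    net = Network(dt=dt, seed=0)
    pop = net.add_lif("pair", 2, params)
    pop.state.v = np.array([25e-3, 0.0])
    edges = cn.EdgeList(
        pre=[0], post=[1], delay_steps=[0], weight=[params.J], n_pre=2, n_post=2
    )
    clock_probe = cs.SimClock(dt=dt)
    edges.delay_steps[:] = cn.discretize_delays(
        np.full(1, _HOMOGENEOUS_DELAY), clock_probe
    )
    net.connect("probe", "pair", "pair", edges, delay_mode="homogeneous",
                effect=fx.StaticEffect(target="v", sign=-1.0))
    spikes = SpikeMonitor("pair")
    state = StateMonitor("pair", variables=("v",), neurons=(1,))
    net.add_monitor(spikes)
    net.add_monitor(state)
    net.run(n_steps * dt)

    spike_steps = spikes.spike_array()
    pre_spike_step = int(spike_steps[0, 0])
    trace = state.values("v", 1)
    jumps = np.flatnonzero(np.abs(np.diff(np.concatenate(([0.0], trace)))) > 0)
    deflection_step = int(jumps[0])
    amplitude = abs(
        trace[deflection_step] - (trace[deflection_step - 1] if deflection_step else 0.0)
    )
    return {
        "lag_ms": (deflection_step - pre_spike_step) * dt * 1e3,
        "amplitude_mv": amplitude * 1e3,
        "delay_steps": int(edges.delay_steps[0]),
    }


# ---------------------------------------------------------------------------
# Self-validation (CLI `validate`): quick structural property checks.

def _naive_deliveries(spike_log, edges: cn.EdgeList):
    """Event-list oracle: every (spike, synapse) delivered delay_steps later."""
    expected = []
    for step, ids in spike_log:
        for i in ids:
            for s in np.flatnonzero(edges.pre == i):
                expected.append((step + int(edges.delay_steps[s]), int(s)))
    return sorted(expected)


def run_validation_suite(seed: int = 0) -> list[tuple[str, bool, str]]:
    """Fast self-checks of the propagation machinery; returns (name, ok, detail)."""
    from .delay_propagation import CircularSpikeBuffer

    results = []

    buf = CircularSpikeBuffer(3)
    initial = buf.state()
    ok = all(buf.advance(np.empty(0, np.int64)).size == 0 for _ in range(4))
    ok = ok and buf.state() == initial
    results.append(("ring periodicity (k+1 empty advances)", ok, "k=3"))

    buf0 = CircularSpikeBuffer(0)
    probe = np.array([1, 4])
    ok = np.array_equal(buf0.advance(probe), probe)
    results.append(("k=0 direct application", ok, ""))

    # conservation on a small random network with heterogeneous delays
    rng = np.random.default_rng(seed)
    n = 20
    mask = rng.random((n, n)) < 0.3
    pre, post = np.nonzero(mask)
    edges = cn.EdgeList(pre, post, rng.integers(0, 6, pre.size),
                        np.ones(pre.size), n, n)
    net = Network(dt=1e-4, seed=seed)
    pop = net.add_lif("p", n, cs.LIFParams(mu_ext=22e-3, sigma_ext=2e-3))
    pop.state.v = stream(seed, "init", "p").uniform(10e-3, 20e-3, n)
    syn = net.connect("s", "p", "p", edges, delay_mode="heterogeneous",
                      partitions=2, effect=fx.StaticEffect("v", -1.0))
    net.record_deliveries()
    mon = SpikeMonitor("p")
    net.add_monitor(mon)
    net.run(0.05)
    n_steps = net.clock.step
    spike_log = [(int(s), [int(i)]) for s, i in mon.spike_array()]
    expected = [d for d in _naive_deliveries(spike_log, edges) if d[0] < n_steps]
    got = sorted(
        (int(step), int(s)) for step, due in syn.deliveries for s in due
    )
    ok = got == expected
    results.append(("delivery conservation vs event-list oracle", ok,
                    f"{len(expected)} deliveries"))

    pair = two_neuron_probe()
    ok = pair["lag_ms"] == 2.0 and abs(pair["amplitude_mv"] - 0.1) < 1e-12
    results.append(("two-neuron delay/amplitude probe", ok,
                    f"lag={pair['lag_ms']} ms amp={pair['amplitude_mv']} mV"))
    return results
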