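"""The clock-driven simulation loop.

Every step executes the same fixed kernel schedule:

1. state updates / Poisson generation for all populations;
2. spike detection (strict threshold, ascending-id order);
3. per synapse population: advance the delay structure with the new spikes and
   apply the effects due this step (pre-triggered pathway first, then the
   undelayed post-triggered STDP pathway);
4. resets and refractory bookkeeping;
5. monitor sampling;
6. clock increment.

Effects delivered at step ``n + k`` therefore modify their targets *after*
that step's integration and spike detection: the earliest step at which a
delivered effect can influence spiking is ``n + k + 1``.

Determinism: a master seed fans out into named child streams (membrane noise,
Poisson, connectivity, delays, weights, initial conditions), and every
reduction runs in a fixed ascending-id order, so identical configurations and
seeds produce bitwise-identical results — across runs, partition counts and
bundle modes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import connectivity as cn
from . import core_state as cs
from . import effects as fx
from . import hh as hhmod
from .delay_propagation import CircularSpikeBuffer, SpikeQueueSet
from .errors import ConfigurationError, SimulationError
from .monitors import RateMonitor, SpikeMonitor, StateMonitor
from .rng import stream

__all__ = [
    "Network",
    "RunResult",
    "LIFPopulation",
    "CondLIFParams",
    "CondLIFPopulation",
    "HHPopulation",
    "PoissonPopulation",
    "SynapsePopulation",
    "build_network",
]

logger = logging.getLogger("spikering")

_EMPTY = np.empty(0, dtype=np.int64)


class LIFPopulation:
    """Noise-driven LIF population."""

    def __init__(self, name: str, n: int, params: cs.LIFParams,
                 noise_stream: np.random.Generator):
        self.name = name
        self.n = n
        self.params = params
        self.state = cs.LIFState.zeros(n)
        self._rng = noise_stream

    def state_array(self, var: str) -> np.ndarray:
        if var != "v":
            raise ConfigurationError(f"LIF population has no variable {var!r}")
        return self.state.v

    def integrate(self, clock: cs.SimClock) -> None:
        cs.lif_step(self.state, self.params, clock, self._rng)

    def detect(self, clock: cs.SimClock) -> np.ndarray:
        return cs.detect_spikes(self.state, self.params.theta, clock)

    def reset(self, spikes: np.ndarray, clock: cs.SimClock) -> None:
        cs.apply_reset(self.state, spikes, self.params, clock)


@dataclass
class CondLIFParams:
    """Conductance-based LIF used as the plasticity-benchmark target.

    Two ODEs: ``dv/dt = (g_e*(e_e - v) + e_leak - v)/tau_m`` and
    ``dg_e/dt = -g_e/tau_e`` with dimensionless ``g_e``.  Defaults follow the
    canonical pair-based plasticity example set (a convention, overridable).
    """

    tau_m: float = 10e-3
    e_leak: float = -74e-3
    e_e: float = 0.0
    v_thresh: float = -54e-3
    v_reset: float = -60e-3
    tau_e: float = 5e-3
    tau_ref: float = 0.0

    def ref_steps(self, dt: float) -> int:
        return int(round(self.tau_ref / dt))


class CondLIFPopulation:
    """Deterministic conductance-based LIF population (exponential Euler)."""

    def __init__(self, name: str, n: int, params: CondLIFParams | None = None):
        self.name = name
        self.n = n
        self.params = params or CondLIFParams()
        self.v = np.full(n, self.params.e_leak)
        self.g_e = np.zeros(n)
        self.refractory_until_step = np.zeros(n, dtype=np.int64)

    # detect_spikes duck-typing
    @property
    def state(self):
        return self

    def state_array(self, var: str) -> np.ndarray:
        try:
            return {"v": self.v, "g_e": self.g_e}[var]
        except KeyError:
            raise ConfigurationError(
                f"conductance LIF population has no variable {var!r}"
            ) from None

    def integrate(self, clock: cs.SimClock) -> None:
        p = self.params
        # dv/dt = ((e_leak + g_e*e_e) - (1 + g_e) * v) / tau_m, g_e frozen
        g_tot = 1.0 + self.g_e
        v_inf = (p.e_leak + self.g_e * p.e_e) / g_tot
        decay = np.exp(-g_tot * clock.dt / p.tau_m)
        v_new = v_inf + (self.v - v_inf) * decay
        refractory = self.refractory_until_step > clock.step
        self.v = np.where(refractory, p.v_reset, v_new)
        self.g_e = self.g_e * np.exp(-clock.dt / p.tau_e)
        if not np.all(np.isfinite(self.v)):
            raise SimulationError(f"non-finite potential at step {clock.step}")

    def detect(self, clock: cs.SimClock) -> np.ndarray:
        return cs.detect_spikes(self, self.params.v_thresh, clock)

    def reset(self, spikes: np.ndarray, clock: cs.SimClock) -> None:
        if spikes.size:
            self.v[spikes] = self.params.v_reset
            self.refractory_until_step[spikes] = (
                clock.step + self.params.ref_steps(clock.dt)
            )
        self.v[self.refractory_until_step > clock.step] = self.params.v_reset


class HHPopulation:
    """Conductance-based HH population with crossing detection and lockout."""

    def __init__(self, name: str, n: int, params: hhmod.HHParams,
                 state: hhmod.HHState | None = None):
        self.name = name
        self.n = n
        self.params = params
        self.state = state if state is not None else hhmod.leak_state(n, params)

    def state_array(self, var: str) -> np.ndarray:
        mapping = {
            "v": self.state.v, "m": self.state.m, "h": self.state.h,
            "n": self.state.n_gate, "g_e": self.state.g_e, "g_i": self.state.g_i,
        }
        try:
            return mapping[var]
        except KeyError:
            raise ConfigurationError(f"HH population has no variable {var!r}") from None

    def integrate(self, clock: cs.SimClock) -> None:
        hhmod.hh_step(self.state, self.params, clock)

    def detect(self, clock: cs.SimClock) -> np.ndarray:
        return cs.detect_spikes(self.state, self.params.theta, clock)

    def reset(self, spikes: np.ndarray, clock: cs.SimClock) -> None:
        # no voltage reset: the dynamics produce the action potential;
        # spiking neurons only enter a detection lockout.
        if spikes.size:
            self.state.refractory_until_step[spikes] = (
                clock.step + self.params.lockout_steps(clock.dt)
            )


class PoissonPopulation:
    """Generators performing one Bernoulli trial per step (no internal state)."""

    def __init__(self, name: str, n: int, params: cs.PoissonParams,
                 rng_stream: np.random.Generator):
        self.name = name
        self.n = n
        self.params = params
        self._rng = rng_stream
        self._pending = _EMPTY

    def state_array(self, var: str) -> np.ndarray:
        raise ConfigurationError("Poisson generators carry no state variables")

    def integrate(self, clock: cs.SimClock) -> None:
        self._pending = cs.poisson_step(self.params, self.n, clock, self._rng)

    def detect(self, clock: cs.SimClock) -> np.ndarray:
        return self._pending

    def reset(self, spikes: np.ndarray, clock: cs.SimClock) -> None:
        self._pending = _EMPTY


class SynapsePopulation:
    """Connectivity + delay structure + effect pathway between two populations.

    ``delay_mode`` is "none", "homogeneous" or "heterogeneous".  The no-delay
    case runs through a k = 0 ring buffer, which reduces to direct same-step
    application.  With ``stdp`` set, the pre-triggered pathway carries the
    axonal delay and drives conductance + depression updates, while the
    post-triggered pathway (dispatched through the dual post-sorted matrix)
    is undelayed.
    """

    def __init__(
        self,
        name: str,
        pre,
        post,
        edges: cn.EdgeList,
        delay_mode: str = "none",
        partitions: int = 1,
        bundle_mode: bool = True,
        effect: fx.StaticEffect | None = None,
        stdp: fx.STDPParams | None = None,
        w_init: np.ndarray | None = None,
    ):
        if delay_mode not in ("none", "homogeneous", "heterogeneous"):
            raise ConfigurationError(f"unknown delay mode {delay_mode!r}")
        if (effect is None) == (stdp is None):
            raise ConfigurationError("exactly one of effect/stdp must be given")
        self.name = name
        self.pre = pre
        self.post = post
        self.edges = edges
        self.delay_mode = delay_mode
        self.conn = cn.build_compressed(edges, partitions, direction="pre")
        self.effect = effect
        self.stdp_params = stdp
        self.deliveries: list[tuple[int, np.ndarray]] | None = None

        if delay_mode == "heterogeneous":
            self.bundles = cn.build_bundles(self.conn, per_synapse=not bundle_mode)
            self.queues = SpikeQueueSet(partitions, self.bundles.max_delay)
            self.buffer = None
        else:
            if delay_mode == "none":
                k = 0
            else:
                uniq = np.unique(edges.delay_steps)
                if uniq.size > 1:
                    raise ConfigurationError(
                        "homogeneous delay mode requires a single delay value"
                    )
                k = int(uniq[0]) if uniq.size else 0
            self.buffer = CircularSpikeBuffer(k)
            self.bundles = None
            self.queues = None

        if stdp is not None:
            if w_init is None:
                raise ConfigurationError("STDP synapses require initial weights")
            self.stdp_state = fx.STDPSynapseState.init(w_init)
            post_partitions = min(partitions, edges.n_pre)
            self.post_conn = cn.build_compressed(
                edges, post_partitions, direction="post"
            )
        else:
            self.stdp_state = None
            self.post_conn = None

    def _due_synapses(self, pre_spikes: np.ndarray) -> np.ndarray:
        if self.buffer is not None:
            due_neurons = self.buffer.advance(pre_spikes)
            return self.conn.gather(due_neurons)
        due_bundles = self.queues.advance(pre_spikes, self.bundles)
        chunks = [
            self.bundles.bundle_synapses(b)
            for per_part in due_bundles
            for b in per_part
        ]
        if not chunks:
            return _EMPTY
        out = np.concatenate(chunks)
        out.sort()
        return out

    def propagate(self, pre_spikes: np.ndarray, post_spikes: np.ndarray,
                  clock: cs.SimClock) -> None:
        due = self._due_synapses(pre_spikes)
        if self.deliveries is not None and due.size:
            self.deliveries.append((clock.step, due.copy()))
        if self.effect is not None:
            target = self.post.state_array(self.effect.target)
            fx.apply_static_effects(due, self.conn, target, self.effect.sign)
        else:
            g_target = self.post.state_array("g_e")
            fx.stdp_on_pre(self.stdp_state, due, self.stdp_params,
                           clock.step, clock.dt, self.conn, g_target)
            post_syn = self.post_conn.gather(post_spikes)
            fx.stdp_on_post(self.stdp_state, post_syn, self.stdp_params,
                            clock.step, clock.dt)


@dataclass
class RunResult:
    """Outcome of a run: monitor records, final network, step count."""

    monitors: list
    step_count: int
    dt: float
    seed: int
    meta: dict = field(default_factory=dict)
    network: "Network | None" = None

    def monitor(self, kind: str):
        for m in self.monitors:
            if m.kind == kind:
                return m
        raise KeyError(f"no {kind!r} monitor attached")

    @property
    def spikes(self) -> SpikeMonitor:
        return self.monitor("spikes")

    @property
    def rate(self) -> RateMonitor:
        return self.monitor("rate")

    def flush(self, out_dir, config: dict | None = None):
        from .monitors import flush_results

        return flush_results(self, out_dir, config=config)


def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class Network:
    """A simulated network: populations, synapse populations, monitors, clock."""

    def __init__(self, dt: float = 1e-4, seed: int = 0):
        self.clock = cs.SimClock(dt=dt)
        self.seed = int(seed)
        self.populations: dict[str, object] = {}
        self.synapses: list[SynapsePopulation] = []
        self.monitors: list = []
        self.meta: dict = {"dt": dt, "seed": self.seed}

    # -- construction -------------------------------------------------------
    def _check_name(self, name: str) -> None:
        if name in self.populations:
            raise ConfigurationError(f"duplicate population name {name!r}")

    def add_lif(self, name: str, n: int, params: cs.LIFParams | None = None
                ) -> LIFPopulation:
        self._check_name(name)
        pop = LIFPopulation(name, n, params or cs.LIFParams(),
                            stream(self.seed, "noise", name))
        self.populations[name] = pop
        return pop

    def add_cond_lif(self, name: str, n: int,
                     params: CondLIFParams | None = None) -> CondLIFPopulation:
        self._check_name(name)
        pop = CondLIFPopulation(name, n, params)
        self.populations[name] = pop
        return pop

    def add_hh(self, name: str, n: int, params: hhmod.HHParams | None = None,
               state: hhmod.HHState | None = None) -> HHPopulation:
        self._check_name(name)
        pop = HHPopulation(name, n, params or hhmod.HHParams(), state)
        self.populations[name] = pop
        return pop

    def add_poisson(self, name: str, n: int, rate: float) -> PoissonPopulation:
        self._check_name(name)
        pop = PoissonPopulation(name, n, cs.PoissonParams(rate),
                                stream(self.seed, "poisson", name))
        self.populations[name] = pop
        return pop

    def connect(self, name: str, pre: str, post: str, edges: cn.EdgeList,
                **kwargs) -> SynapsePopulation:
        if pre not in self.populations or post not in self.populations:
            raise ConfigurationError("synapse population references unknown population")
        syn = SynapsePopulation(
            name, self.populations[pre], self.populations[post], edges, **kwargs
        )
        self.synapses.append(syn)
        return syn

    def add_monitor(self, monitor) -> None:
        if monitor.population not in self.populations:
            raise ConfigurationError(
                f"monitor references unknown population {monitor.population!r}"
            )
        self.monitors.append(monitor)

    def record_deliveries(self) -> None:
        """Enable per-step (step, synapse id) delivery logging on all synapses."""
        for syn in self.synapses:
            syn.deliveries = []

    # -- simulation ---------------------------------------------------------
    def step(self) -> dict[str, np.ndarray]:
        clock = self.clock
        pops = self.populations
        for pop in pops.values():
            pop.integrate(clock)
        spikes = {name: pop.detect(clock) for name, pop in pops.items()}
        for syn in self.synapses:
            syn.propagate(spikes[syn.pre.name], spikes[syn.post.name], clock)
        for name, pop in pops.items():
            pop.reset(spikes[name], clock)
        for mon in self.monitors:
            mon.sample(spikes, pops, clock)
        clock.advance()
        return spikes

    def run(self, duration: float) -> RunResult:
        if duration < 0:
            raise ConfigurationError("duration must be nonnegative")
        n_steps = cs.steps_of(duration, self.clock.dt)
        t0 = time.perf_counter()
        for _ in range(n_steps):
            self.step()
        wall = time.perf_counter() - t0
        logger.info(
            "run: config=%s seed=%d steps=%d wall=%.3fs (%.1f us/step)",
            _config_hash(self.meta), self.seed, n_steps, wall,
            1e6 * wall / max(n_steps, 1),
        )
        return RunResult(
            monitors=list(self.monitors),
            step_count=self.clock.step,
            dt=self.clock.dt,
            seed=self.seed,
            meta=dict(self.meta),
            network=self,
        )


# ---------------------------------------------------------------------------
# Structured-config (JSON) construction


def _resolve_values(spec, n, rng_name, seed):
    """A scalar, or {"uniform": [lo, hi]} drawn from a named stream."""
    if isinstance(spec, dict):
        lo, hi = spec["uniform"]
        return stream(seed, *rng_name).uniform(lo, hi, n)
    return np.full(n, float(spec))


def build_network(cfg: dict) -> tuple[Network, dict]:
    """Build a :class:`Network` from a structured config document.

    Sections: ``populations``, ``synapses``, ``monitors``, ``run`` (duration,
    dt, seed, partitions, bundle_mode).  Returns (network, run section).
    """
    run_cfg = dict(cfg.get("run", {}))
    dt = float(run_cfg.get("dt", 1e-4))
    seed = int(run_cfg.get("seed", 0))
    partitions = int(run_cfg.get("partitions", 1))
    bundle_mode = bool(run_cfg.get("bundle_mode", True))
    net = Network(dt=dt, seed=seed)
    net.meta = {"config": cfg}
    clock = cs.SimClock(dt=dt)

    for pop_cfg in cfg.get("populations", []):
        name, model, n = pop_cfg["name"], pop_cfg["model"], int(pop_cfg["n"])
        params = pop_cfg.get("params", {})
        if model == "lif":
            pop = net.add_lif(name, n, cs.LIFParams(**params))
            v_init = pop_cfg.get("v_init")
            if v_init is not None:
                pop.state.v = _resolve_values(v_init, n, ("init", name), seed)
        elif model == "cond_lif":
            net.add_cond_lif(name, n, CondLIFParams(**params))
        elif model == "hh":
            net.add_hh(name, n, hhmod.HHParams.from_dict(params))
        elif model == "poisson":
            net.add_poisson(name, n, float(pop_cfg["rate"]))
        else:
            raise ConfigurationError(f"unknown population model {model!r}")

    for syn_cfg in cfg.get("synapses", []):
        name = syn_cfg["name"]
        pre, post = syn_cfg["pre"], syn_cfg["post"]
        n_pre, n_post = net.populations[pre].n, net.populations[post].n
        conn_cfg = syn_cfg["connectivity"]
        if "edges_tsv" in conn_cfg:
            edges = cn.read_edges_tsv(conn_cfg["edges_tsv"], n_pre, n_post)
        else:
            spec = cn.ConnectivitySpec(
                n_pre, n_post, float(conn_cfg["C"]),
                allow_self=bool(conn_cfg.get("allow_self", True)),
            )
            edges = cn.sample_bernoulli(spec, stream(seed, "connectivity", name))
        if "weight" in syn_cfg:
            edges.weight[:] = _resolve_values(
                syn_cfg["weight"], len(edges), ("weights", name), seed
            )
        delay_cfg = syn_cfg.get("delay", {"mode": "none"})
        mode = delay_cfg["mode"]
        if mode == "homogeneous":
            edges.delay_steps[:] = cn.discretize_delays(
                np.full(len(edges), float(delay_cfg["value"])), clock
            )
        elif mode == "heterogeneous":
            lo, hi = float(delay_cfg.get("low", 0.0)), float(delay_cfg["high"])
            seconds = stream(seed, "delays", name).uniform(lo, hi, len(edges))
            edges.delay_steps[:] = cn.discretize_delays(seconds, clock)
        kwargs: dict = dict(delay_mode=mode, partitions=partitions,
                            bundle_mode=bundle_mode)
        if "stdp" in syn_cfg:
            stdp_cfg = dict(syn_cfg["stdp"])
            w_init_spec = stdp_cfg.pop("w_init", 0.0)
            params = fx.STDPParams(**stdp_cfg)
            kwargs["stdp"] = params
            kwargs["w_init"] = _resolve_values(
                w_init_spec, len(edges), ("weights", name), seed
            )
        else:
            kwargs["effect"] = fx.StaticEffect(
                target=syn_cfg.get("target", "v"),
                sign=float(syn_cfg.get("sign", 1.0)),
            )
        net.connect(name, pre, post, edges, **kwargs)

    for mon_cfg in cfg.get("monitors", []):
        kind = mon_cfg["kind"]
        popname = mon_cfg["population"]
        if kind == "spikes":
            net.add_monitor(SpikeMonitor(popname))
        elif kind == "rate":
            net.add_monitor(RateMonitor(popname))
        elif kind == "state":
            net.add_monitor(StateMonitor(
                popname,
                variables=mon_cfg.get("variables", ("v",)),
                neurons=mon_cfg.get("neurons", (0,)),
            ))
        else:
            raise ConfigurationError(f"unknown monitor kind {kind!r}")

    return net, run_cfg
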