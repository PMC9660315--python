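"""Synaptic effect application and the event-driven pair-based STDP pathway.

Static effects are additive increments to one target state variable of the
postsynaptic population (membrane potential for the inhibitory LIF benchmark,
conductances for HH-type networks).  On parallel hardware these are atomic
adds whose order is nondeterministic; here the reduction order is fixed —
due synapses are processed in ascending synapse-id order and accumulated
per-target with a single weighted bincount — so results are bit-reproducible
and independent of delivery-order permutations.

The plasticity rule is all-to-all, additive, pair-based STDP.  Each synapse
carries a weight ``w``, two exponentially decaying trace variables ``a_pre``
and ``a_post``, and the step of its last event; traces decay analytically
between events (event-driven update), so no per-step work is done on silent
synapses.

* On a presynaptic spike *arrival* (spike time + axonal delay): decay both
  traces to the arrival time, depress ``w += a_post`` (``a_post < 0``), clip
  to ``[0, w_max]``, increment ``a_pre += A_pre``, then increase the
  postsynaptic excitatory conductance by the *updated* weight.
* On a postsynaptic spike (undelayed): decay both traces, facilitate
  ``w += a_pre``, clip, increment ``a_post += A_post``.

For an isolated pre-before-post pairing at lag D this yields
``dw = A_pre * exp(-D/tau_pre) > 0`` (facilitation); the inverted order gives
``dw = A_post * exp(-D/tau_post) < 0`` (depression).  When a pre arrival and a
post spike coincide on one step, the pre pathway is processed first (engine
schedule tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import CompressedConnectivity
from .errors import ConfigurationError, SimulationError

__all__ = [
    "StaticEffect",
    "STDPParams",
    "STDPSynapseState",
    "apply_static_effects",
    "decay_trace",
    "stdp_on_pre",
    "stdp_on_post",
]


@dataclass
class StaticEffect:
    """Additive increment of one postsynaptic state variable.

    ``target`` names the variable on the post population ("v", "g_e", "g_i");
    the applied increment is ``sign * weight`` per due synapse.
    """

    target: str
    sign: float = 1.0


def apply_static_effects(
    due_synapses: np.ndarray,
    conn: CompressedConnectivity,
    target_state: np.ndarray,
    sign: float = 1.0,
) -> np.ndarray:
    """Accumulate ``sign * weight`` onto each due synapse's target (in place).

    The due set is re-sorted ascending and the per-target sum is taken in that
    order, so any permutation of the delivery order produces a bitwise-identical
    result (fixed reduction order).
    """
    due = np.sort(np.asarray(due_synapses, dtype=np.int64))
    if due.size == 0:
        return target_state
    posts = conn.post_of[due]
    delta = sign * conn.weight_of[due]
    target_state += np.bincount(posts, weights=delta, minlength=target_state.size)
    return target_state


def decay_trace(value, t_last, t_now, tau: float):
    """Exponential event-driven decay: value * exp(-(t_now - t_last)/tau)."""
    elapsed = np.asarray(t_now, dtype=np.float64) - np.asarray(t_last, dtype=np.float64)
    if np.any(elapsed < 0):
        raise SimulationError("causality violation: t_now < t_last in trace decay")
    return value * np.exp(-elapsed / tau)


@dataclass
class STDPParams:
    """Pair-based additive STDP constants.

    Defaults follow the canonical pair-based example set (a package
    convention, not a measured quantity): equal 20 ms trace time constants,
    ``A_pre = 0.01 * w_max`` and ``A_post = -1.05 * A_pre``.  Weights are
    hard-clipped to ``[0, w_max]``.
    """

    w_max: float = 0.01
    tau_pre: float = 20e-3
    tau_post: float = 20e-3
    A_pre: float = None  # type: ignore[assignment]
    A_post: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.w_max > 0:
            raise ConfigurationError("w_max must be positive")
        if not (self.tau_pre > 0 and self.tau_post > 0):
            raise ConfigurationError("trace time constants must be positive")
        if self.A_pre is None:
            self.A_pre = 0.01 * self.w_max
        if self.A_post is None:
            self.A_post = -1.05 * self.A_pre
        if not self.A_pre > 0:
            raise ConfigurationError("A_pre must be positive (facilitation)")
        if not self.A_post < 0:
            raise ConfigurationError("A_post must be negative (depression)")


@dataclass
class STDPSynapseState:
    """Per-synapse weight, traces and last-event step for event-driven decay."""

    w: np.ndarray
    a_pre: np.ndarray
    a_post: np.ndarray
    t_last_step: np.ndarray

    @classmethod
    def init(cls, w_init: np.ndarray) -> "STDPSynapseState":
        w = np.asarray(w_init, dtype=np.float64).copy()
        n = w.size
        return cls(w, np.zeros(n), np.zeros(n), np.zeros(n, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.w.size


def _decay_to(state: STDPSynapseState, idx: np.ndarray, step_now: int,
              dt: float, params: STDPParams) -> None:
    elapsed_steps = step_now - state.t_last_step[idx]
    if np.any(elapsed_steps < 0):
        raise SimulationError("causality violation: event before last synapse update")
    elapsed = elapsed_steps * dt
    state.a_pre[idx] *= np.exp(-elapsed / params.tau_pre)
    state.a_post[idx] *= np.exp(-elapsed / params.tau_post)


def stdp_on_pre(
    state: STDPSynapseState,
    due_synapses: np.ndarray,
    params: STDPParams,
    step_now: int,
    dt: float,
    conn: CompressedConnectivity,
    g_target: np.ndarray,
) -> None:
    """Presynaptic spike arrivals at ``step_now`` (spike step + axonal delay).

    Decays traces, applies depression from the current (decayed) postsynaptic
    trace, increments the presynaptic trace, and increases the postsynaptic
    conductance by the updated weight.  ``due_synapses`` sorted ascending.
    """
    idx = np.sort(np.asarray(due_synapses, dtype=np.int64))
    if idx.size == 0:
        return
    _decay_to(state, idx, step_now, dt, params)
    state.w[idx] = np.clip(state.w[idx] + state.a_post[idx], 0.0, params.w_max)
    state.a_pre[idx] += params.A_pre
    posts = conn.post_of[idx]
    g_target += np.bincount(posts, weights=state.w[idx], minlength=g_target.size)
    state.t_last_step[idx] = step_now


def stdp_on_post(
    state: STDPSynapseState,
    synapses: np.ndarray,
    params: STDPParams,
    step_now: int,
    dt: float,
) -> None:
    """Postsynaptic spikes at ``step_now`` (no delay on this pathway).

    Decays traces, applies facilitation from the current presynaptic trace,
    and increments the postsynaptic trace.  ``synapses`` sorted ascending.
    """
    idx = np.sort(np.asarray(synapses, dtype=np.int64))
    if idx.size == 0:
        return
    _decay_to(state, idx, step_now, dt, params)
    state.w[idx] = np.clip(state.w[idx] + state.a_pre[idx], 0.0, params.w_max)
    state.a_post[idx] += params.A_post
    state.t_last_step[idx] = step_now
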