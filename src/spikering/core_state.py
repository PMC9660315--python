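"""Neuron-population state containers and per-step neuronal kernels.

This module holds the simulation clock, the stochastic leaky integrate-and-fire
(LIF) integrator, Bernoulli-per-step Poisson generation, threshold spike
detection and reset/refractory bookkeeping.  Hodgkin-Huxley dynamics live in
:mod:`spikering.hh`.

Conventions (pinned, see ``docs/methods.md``):

* **Strict threshold** — a neuron spikes when ``v > theta`` (strictly greater).
* **Refractory clamp** — for ``tau_ref`` after a spike the membrane potential
  is clamped at ``v_reset`` and integration is suspended.  Refractory windows
  are bookkept in integer steps so the arithmetic is exact: a spike at step
  ``n`` makes the neuron refractory while ``step < n + round(tau_ref/dt)``, so
  the earliest next spike is exactly ``tau_ref`` later.
* **Noise discretisation** — Euler-Maruyama with per-step increment
  ``sigma_ext * sqrt(2*dt/tau) * eta``, ``eta ~ N(0,1)``, so that ``sigma_ext``
  is the *stationary* standard deviation of the free (threshold-disabled)
  Ornstein-Uhlenbeck process, whose stationary law is
  ``N(mu_ext, sigma_ext^2)``.
* **Deterministic spike order** — spike lists are sorted ascending by neuron
  id, making runs bit-reproducible (the parallel-hardware original selects
  spiking neurons with an atomic counter, whose order is nondeterministic; the
  observable contract is the *set* of spiking ids).

All potentials are in volts, times in seconds, rates in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SimulationError

__all__ = [
    "SimClock",
    "LIFParams",
    "LIFState",
    "PoissonParams",
    "lif_step",
    "poisson_step",
    "detect_spikes",
    "apply_reset",
    "steps_of",
]


def steps_of(duration: float, dt: float) -> int:
    """Number of time steps covering ``duration`` at resolution ``dt``."""
    return int(round(duration / dt))


@dataclass
class SimClock:
    """Discrete simulation clock: ``t = step * dt``.

    Parameters
    ----------
    dt : float
        Time step in seconds (default 1e-4 s, i.e. 0.1 ms).
    step : int
        Nonnegative step counter, advanced by exactly one per engine step.
    """

    dt: float = 1e-4
    step: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.step < 0:
            raise ConfigurationError("step counter must be nonnegative")

    @property
    def t(self) -> float:
        """Current time in seconds."""
        return self.step * self.dt

    def advance(self) -> None:
        self.step += 1


@dataclass
class LIFParams:
    """Parameters of the noise-driven LIF neuron.

    Defaults are the sparse recurrent-inhibition benchmark values
    (homogeneous-delay drive): threshold 20 mV, reset 10 mV, tau 20 ms,
    refractory 2 ms, coupling J = 0.1 mV, noise mean 25 mV and stationary
    noise standard deviation 1 mV.
    """

    tau: float = 20e-3
    theta: float = 20e-3
    v_reset: float = 10e-3
    tau_ref: float = 2e-3
    mu_ext: float = 25e-3
    sigma_ext: float = 1e-3
    J: float = 0.1e-3

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ConfigurationError("tau must be positive")
        if self.tau_ref < 0:
            raise ConfigurationError("tau_ref must be nonnegative")
        if not self.theta > self.v_reset:
            raise ConfigurationError("theta must exceed v_reset")
        if self.sigma_ext < 0:
            raise ConfigurationError("sigma_ext must be nonnegative")

    def ref_steps(self, dt: float) -> int:
        return int(round(self.tau_ref / dt))


@dataclass
class LIFState:
    """Per-neuron membrane potentials and refractory clocks (integer steps)."""

    v: np.ndarray
    refractory_until_step: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.refractory_until_step = np.asarray(
            self.refractory_until_step, dtype=np.int64
        )
        if self.v.shape != self.refractory_until_step.shape:
            raise ConfigurationError("state arrays must have equal length")

    @classmethod
    def zeros(cls, n: int) -> "LIFState":
        return cls(np.zeros(n), np.zeros(n, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.v.size


@dataclass
class PoissonParams:
    """Bernoulli-per-step Poisson generator with mean rate in s^-1."""

    rate: float = 15.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("rate must be nonnegative")


def lif_step(
    state: LIFState,
    params: LIFParams,
    clock: SimClock,
    rng_stream: np.random.Generator,
) -> LIFState:
    """One Euler-Maruyama step of the noisy LIF membrane equation (in place).

    Non-refractory neurons receive
    ``v += (mu_ext - v) * dt/tau + sigma_ext * sqrt(2*dt/tau) * eta``;
    refractory neurons are clamped at ``v_reset``.  One standard-normal draw is
    consumed per neuron per step (refractory draws are discarded), keeping the
    noise stream's consumption independent of the dynamics.
    """
    dt, tau = clock.dt, params.tau
    h = dt / tau
    eta = rng_stream.standard_normal(state.n)
    refractory = state.refractory_until_step > clock.step
    drift = (params.mu_ext - state.v) * h
    diffusion = params.sigma_ext * np.sqrt(2.0 * h) * eta
    state.v = np.where(refractory, params.v_reset, state.v + drift + diffusion)
    if not np.all(np.isfinite(state.v)):
        raise SimulationError(
            f"non-finite membrane potential at step {clock.step} (t={clock.t:g}s)"
        )
    return state


def poisson_step(
    params: PoissonParams,
    n: int,
    clock: SimClock,
    rng_stream: np.random.Generator,
) -> np.ndarray:
    """Sorted ids of generators spiking this step.

    Each of the ``n`` generators performs one independent Bernoulli trial with
    success probability ``rate * dt``.
    """
    p = params.rate * clock.dt
    if p > 1.0:
        raise ConfigurationError(
            f"rate*dt = {p:g} > 1: the rate is undersampled at dt={clock.dt:g}"
        )
    if p == 0.0:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero(rng_stream.random(n) < p).astype(np.int64)


def detect_spikes(state, theta: float, clock: SimClock) -> np.ndarray:
    """Sorted ids of non-refractory neurons with ``v > theta`` (strict).

    Works for any state object carrying ``v`` and ``refractory_until_step``
    arrays (LIF and HH populations share the convention; for HH the refractory
    array is the post-detection lockout).  Idempotent within a step.
    """
    eligible = (state.v > theta) & (state.refractory_until_step <= clock.step)
    return np.flatnonzero(eligible).astype(np.int64)


def apply_reset(
    state: LIFState,
    spikes: np.ndarray,
    params: LIFParams,
    clock: SimClock,
) -> LIFState:
    """Reset spiking neurons and re-apply the refractory clamp (in place).

    Spiking neurons get ``v = v_reset`` and become refractory until
    ``step + round(tau_ref/dt)``.  All currently refractory neurons are
    re-clamped to ``v_reset`` so that synaptic effects landing on a refractory
    target cannot move its observable membrane potential.
    """
    spikes = np.asarray(spikes, dtype=np.int64)
    if spikes.size:
        if spikes.min() < 0 or spikes.max() >= state.n:
            raise ConfigurationError("spike id out of range")
        state.refractory_until_step[spikes] = clock.step + params.ref_steps(clock.dt)
    state.v[state.refractory_until_step > clock.step] = params.v_reset
    state.v[spikes] = params.v_reset
    return state
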