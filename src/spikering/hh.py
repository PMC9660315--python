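"""Conductance-based Hodgkin-Huxley population (COBAHH-style).

Six coupled ODEs per neuron: membrane voltage ``v``, gating variables ``m``,
``h``, ``n`` and exponentially decaying excitatory/inhibitory synaptic
conductances ``g_e``, ``g_i``:

    C_m dv/dt = g_l (E_l - v) + g_e (E_e - v) + g_i (E_i - v)
                - g_na m^3 h (v - E_na) - g_k n^4 (v - E_k) + I_ext
    dx/dt     = alpha_x(v) (1 - x) - beta_x(v) x        for x in {m, h, n}
    dg/dt     = -g / tau_g                              for g in {g_e, g_i}

The default parameter set is the widely used conductance-based benchmark
configuration for a 20,000 um^2 patch (C_m = 200 pF, g_l = 10 nS,
E_l = -60 mV, g_na = 20 uS, E_na = 50 mV, g_k = 6 uS, E_k = -90 mV,
V_T = -63 mV, tau_e = 5 ms, tau_i = 10 ms, E_e = 0, E_i = -80 mV).  These
constants are package conventions, fully overridable; none is treated as a
quantity this package must reproduce.

Integration is exponential Euler: every variable is updated over one step with
all other variables frozen at their start-of-step values, using the exact
exponential solution of the resulting linear ODE.  Gating variables therefore
remain in [0, 1] for any dt.  Spikes are detected as strict upward threshold
crossings ``v > theta`` with a post-detection lockout (default 3 ms) and no
reset: the action potential itself is produced by the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exprel

from .errors import ConfigurationError, SimulationError
from .core_state import SimClock

__all__ = ["HHParams", "HHState", "hh_step", "gating_steady_state",
           "steady_state_current", "equilibrium_state", "leak_state"]


@dataclass
class HHParams:
    """Conductance-based HH parameter set (SI units)."""

    c_m: float = 200e-12        # membrane capacitance (F)
    g_leak: float = 10e-9       # leak conductance (S)
    e_leak: float = -60e-3      # leak reversal (V)
    g_na: float = 20e-6         # max sodium conductance (S)
    e_na: float = 50e-3
    g_k: float = 6e-6           # max delayed-rectifier conductance (S)
    e_k: float = -90e-3
    v_t: float = -63e-3         # rate-function voltage offset (V)
    tau_e: float = 5e-3         # excitatory conductance decay (s)
    tau_i: float = 10e-3        # inhibitory conductance decay (s)
    e_e: float = 0.0
    e_i: float = -80e-3
    theta: float = -20e-3       # spike detection threshold (V)
    t_lockout: float = 3e-3     # post-detection lockout (s)

    def __post_init__(self) -> None:
        for name in ("c_m", "g_leak", "g_na", "g_k", "tau_e", "tau_i"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.t_lockout < 0:
            raise ConfigurationError("t_lockout must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "HHParams":
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"invalid HH parameter set: {exc}") from exc

    def lockout_steps(self, dt: float) -> int:
        return int(round(self.t_lockout / dt))


@dataclass
class HHState:
    """Per-neuron HH state arrays."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n_gate: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    refractory_until_step: np.ndarray  # detection lockout, in steps

    def __post_init__(self) -> None:
        for name in ("v", "m", "h", "n_gate", "g_e", "g_i"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.refractory_until_step = np.asarray(
            self.refractory_until_step, dtype=np.int64
        )
        sizes = {getattr(self, f).size for f in
                 ("v", "m", "h", "n_gate", "g_e", "g_i", "refractory_until_step")}
        if len(sizes) != 1:
            raise ConfigurationError("HH state arrays must have equal length")

    @property
    def n(self) -> int:
        return self.v.size


# Voltage-dependent transition rates (s^-1).  x is the voltage relative to the
# rate-function offset V_T, expressed in mV.  The a/(exp(a/b)-1) forms are
# rewritten with exprel to stay finite at their removable singularities.

def _rates(v: np.ndarray, params: HHParams):
    x = (v - params.v_t) * 1e3  # mV above V_T
    a_m = 0.32e3 * 4.0 / exprel((13.0 - x) / 4.0)
    b_m = 0.28e3 * 5.0 / exprel((x - 40.0) / 5.0)
    a_h = 0.128e3 * np.exp((17.0 - x) / 18.0)
    b_h = 4.0e3 / (1.0 + np.exp((40.0 - x) / 5.0))
    a_n = 0.032e3 * 5.0 / exprel((15.0 - x) / 5.0)
    b_n = 0.5e3 * np.exp((10.0 - x) / 40.0)
    return (a_m, b_m), (a_h, b_h), (a_n, b_n)


def gating_steady_state(v, params: HHParams):
    """Voltage-clamped steady states (m_inf, h_inf, n_inf) at voltage ``v``."""
    v = np.asarray(v, dtype=np.float64)
    out = []
    for a, b in _rates(v, params):
        out.append(a / (a + b))
    return tuple(out)


def steady_state_current(v, params: HHParams, i_ext: float = 0.0):
    """Net membrane current with gates at their voltage-clamped steady state."""
    v = np.asarray(v, dtype=np.float64)
    m, h, ngate = gating_steady_state(v, params)
    return (
        params.g_leak * (params.e_leak - v)
        - params.g_na * m**3 * h * (v - params.e_na)
        - params.g_k * ngate**4 * (v - params.e_k)
        + i_ext
    )


def equilibrium_state(n: int, params: HHParams, i_ext: float = 0.0) -> HHState:
    """Population at a true fixed point of the g_e = g_i = 0 dynamics.

    Note that for the default parameter set the model is intrinsically
    rhythmic: the sodium window current outweighs the leak at subthreshold
    voltages, so the only equilibrium is depolarised and dynamically unstable.
    It is still an exact fixed point of one integration step, which is what
    fixed-point checks need.
    """
    from scipy.optimize import brentq

    grid = np.linspace(-90e-3, 40e-3, 261)
    cur = steady_state_current(grid, params, i_ext)
    crossings = np.flatnonzero(np.sign(cur[:-1]) != np.sign(cur[1:]))
    if crossings.size == 0:
        raise ConfigurationError("no membrane equilibrium in [-90, 40] mV")
    lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
    v_eq = brentq(lambda v: float(steady_state_current(v, params, i_ext)), lo, hi,
                  xtol=1e-15)
    m, h, ngate = gating_steady_state(v_eq, params)
    return HHState(
        v=np.full(n, v_eq),
        m=np.full(n, float(m)),
        h=np.full(n, float(h)),
        n_gate=np.full(n, float(ngate)),
        g_e=np.zeros(n),
        g_i=np.zeros(n),
        refractory_until_step=np.zeros(n, dtype=np.int64),
    )


def leak_state(n: int, params: HHParams) -> HHState:
    """Population at the leak reversal with gates at steady state (default init)."""
    v = np.full(n, params.e_leak)
    m, h, ngate = gating_steady_state(v, params)
    return HHState(
        v=v, m=m, h=h, n_gate=ngate,
        g_e=np.zeros(n), g_i=np.zeros(n),
        refractory_until_step=np.zeros(n, dtype=np.int64),
    )


def hh_step(
    state: HHState,
    params: HHParams,
    clock: SimClock,
    i_ext: float | np.ndarray = 0.0,
) -> HHState:
    """One exponential-Euler update of the HH population (in place).

    ``i_ext`` is an optional external current (A) added to the membrane
    equation, used e.g. for current-clamp probes.
    """
    dt = clock.dt
    v0 = state.v.copy()
    (a_m, b_m), (a_h, b_h), (a_n, b_n) = _rates(v0, params)

    g_na_eff = params.g_na * state.m**3 * state.h
    g_k_eff = params.g_k * state.n_gate**4
    g_tot = params.g_leak + g_na_eff + g_k_eff + state.g_e + state.g_i
    i_const = (
        params.g_leak * params.e_leak
        + g_na_eff * params.e_na
        + g_k_eff * params.e_k
        + state.g_e * params.e_e
        + state.g_i * params.e_i
        + i_ext
    )
    v_inf = i_const / g_tot
    state.v = v_inf + (v0 - v_inf) * np.exp(-g_tot * dt / params.c_m)

    for gate, (a, b) in (("m", (a_m, b_m)), ("h", (a_h, b_h)), ("n_gate", (a_n, b_n))):
        x = getattr(state, gate)
        rate = a + b
        x_inf = a / rate
        setattr(state, gate, x_inf + (x - x_inf) * np.exp(-rate * dt))

    state.g_e = state.g_e * np.exp(-dt / params.tau_e)
    state.g_i = state.g_i * np.exp(-dt / params.tau_i)

    if not np.all(np.isfinite(state.v)):
        raise SimulationError(f"non-finite HH membrane potential at step {clock.step}")
    return state
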