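"""Spike, population-rate and state monitors with TSV/JSON on-disk formats.

Monitors buffer in memory during the run and are flushed to disk at the end.
They only read network state, never write it, so recorded and unrecorded runs
produce identical dynamics.  Sampling happens once per step, after resets.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .core_state import SimClock

__all__ = [
    "SpikeMonitor",
    "RateMonitor",
    "StateMonitor",
    "flush_results",
    "read_spikes_tsv",
    "read_rate_tsv",
    "read_state_tsv",
]


class SpikeMonitor:
    """Records (time, neuron id) for every spike of one population."""

    kind = "spikes"

    def __init__(self, population: str):
        self.population = population
        self._steps: list[np.ndarray] = []
        self._ids: list[np.ndarray] = []

    def sample(self, spikes: dict, populations: dict, clock: SimClock) -> None:
        ids = spikes[self.population]
        if ids.size:
            self._steps.append(np.full(ids.size, clock.step, dtype=np.int64))
            self._ids.append(ids)

    def frame(self, dt: float) -> pd.DataFrame:
        if self._steps:
            steps = np.concatenate(self._steps)
            ids = np.concatenate(self._ids)
        else:
            steps = np.empty(0, dtype=np.int64)
            ids = np.empty(0, dtype=np.int64)
        return pd.DataFrame({"t": steps * dt, "neuron": ids})

    @property
    def n_spikes(self) -> int:
        return int(sum(a.size for a in self._ids))

    def spike_array(self) -> np.ndarray:
        """(n_spikes, 2) array of (step, neuron), sorted by (step, neuron)."""
        frame_steps = (
            np.concatenate(self._steps) if self._steps else np.empty(0, np.int64)
        )
        frame_ids = np.concatenate(self._ids) if self._ids else np.empty(0, np.int64)
        return np.column_stack((frame_steps, frame_ids))


class RateMonitor:
    """Records the fraction of spiking neurons per step for one population."""

    kind = "rate"

    def __init__(self, population: str):
        self.population = population
        self._fractions: list[float] = []

    def sample(self, spikes: dict, populations: dict, clock: SimClock) -> None:
        n = populations[self.population].n
        self._fractions.append(spikes[self.population].size / n)

    def fractions(self) -> np.ndarray:
        return np.asarray(self._fractions)

    def frame(self, dt: float) -> pd.DataFrame:
        frac = self.fractions()
        t = np.arange(frac.size) * dt
        return pd.DataFrame({"t": t, "fraction": frac, "rate": frac / dt})


class StateMonitor:
    """Records selected state variables of selected neurons, one row per step."""

    kind = "state"

    def __init__(self, population: str, variables=("v",), neurons=(0,)):
        self.population = population
        self.variables = tuple(variables)
        self.neurons = np.asarray(neurons, dtype=np.int64)
        self._rows: list[tuple] = []

    def sample(self, spikes: dict, populations: dict, clock: SimClock) -> None:
        pop = populations[self.population]
        for var in self.variables:
            values = pop.state_array(var)[self.neurons]
            for nid, val in zip(self.neurons, values):
                self._rows.append((clock.step, int(nid), var, float(val)))

    def frame(self, dt: float) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=["step", "neuron", "var", "value"])
        out = pd.DataFrame(
            {
                "t": df["step"].to_numpy() * dt if len(df) else np.empty(0),
                "neuron": df["neuron"] if len(df) else np.empty(0, np.int64),
                "var": df["var"] if len(df) else pd.Series(dtype=str),
                "value": df["value"] if len(df) else np.empty(0),
            }
        )
        return out

    def values(self, var: str, neuron: int) -> np.ndarray:
        """Per-step trace of one variable of one neuron."""
        return np.asarray(
            [r[3] for r in self._rows if r[1] == neuron and r[2] == var]
        )


def flush_results(result, out_dir, config: dict | None = None) -> dict:
    """Write monitor records and the run manifest to ``out_dir``.

    Produces ``spikes.tsv`` (t, neuron), ``rate.tsv`` (t, fraction, rate),
    ``state.tsv`` (t, neuron, var, value) — one file per monitor kind present —
    plus ``run.json`` with the resolved configuration, seed and versions.
    Returns a dict of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = result.dt
    written = {}
    for monitor in result.monitors:
        path = out / f"{monitor.kind}.tsv"
        monitor.frame(dt).to_csv(path, sep="\t", index=False)
        written[monitor.kind] = path
    import spikering

    manifest = {
        "config": config if config is not None else result.meta,
        "seed": result.seed,
        "dt": dt,
        "steps": result.step_count,
        "versions": {
            "spikering": spikering.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    manifest_path = out / "run.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    written["run"] = manifest_path
    return written


def read_spikes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"t": float, "neuron": np.int64},
                       float_precision="round_trip")


def read_rate_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_state_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
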