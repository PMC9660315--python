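"""Spike propagation through circular delay structures.

Two structures implement synaptic transmission delays:

* :class:`CircularSpikeBuffer` — homogeneous delays ``d = k*dt``.  A ring of
  ``k+1`` spiking-neuron arrays; the array written this step is labelled
  ``k*dt``, the array read is labelled ``0*dt``, and all labels rotate once per
  step.  Propagation is just an index rotation, so homogeneous delays are
  nearly free.

* :class:`SpikeQueueSet` — heterogeneous delays.  Per postsynaptic partition,
  a ring of ``k+1`` queues of *bundle ids* where ``k`` is the largest delay in
  the synapse population.  When a neuron spikes, each bundle of its bundle
  group is pushed into the queue labelled with the bundle's delay in the
  bundle's partition; the ``0*dt`` queues are consumed each step.

The within-step order is pinned as *push, then pop, then rotate*: a structure
with ``k = 0`` then reduces exactly to direct (same-step) effect application,
unifying the no-delay, homogeneous and heterogeneous paths under one schedule.
Pushes within one step are order-independent — consumers treat queue contents
as a set and apply effects in a fixed ascending-synapse-id order.

Queue capacities only ever grow (amortised doubling via Python lists); the
high-water marks are tracked so the monotone-capacity contract is observable.
"""

from __future__ import annotations

import numpy as np

from .connectivity import BundleIndex
from .errors import ConfigurationError, SimulationError

__all__ = ["n_slots", "CircularSpikeBuffer", "SpikeQueueSet"]

_EMPTY = np.empty(0, dtype=np.int64)


def n_slots(k: int) -> int:
    """Number of ring slots needed for a maximum delay of ``k`` steps: k + 1."""
    if k < 0:
        raise ConfigurationError(f"delay steps must be nonnegative, got {k}")
    return int(k) + 1


class CircularSpikeBuffer:
    """Ring of k+1 spiking-neuron arrays for one homogeneous delay of k steps."""

    def __init__(self, k: int):
        self.k = int(k)
        self._slots = [_EMPTY] * n_slots(k)
        self._head = 0  # index of the slot currently labelled 0*dt

    def advance(self, new_spikes: np.ndarray) -> np.ndarray:
        """Insert this step's spikes, return the spikes due now, rotate.

        For ``k = 0`` the write and read slots coincide, so the output equals
        the input (direct application).
        """
        new_spikes = np.asarray(new_spikes, dtype=np.int64)
        size = self.k + 1
        self._slots[(self._head + self.k) % size] = new_spikes
        due = self._slots[self._head]
        self._slots[self._head] = _EMPTY
        self._head = (self._head + 1) % size
        return due

    def is_empty(self) -> bool:
        return all(s.size == 0 for s in self._slots)

    def state(self) -> tuple:
        """Label-order snapshot (slot contents from label 0 to label k)."""
        size = self.k + 1
        return tuple(
            tuple(self._slots[(self._head + i) % size]) for i in range(size)
        )


class SpikeQueueSet:
    """Per-partition circular lists of k+1 bundle-id queues (heterogeneous delays).

    ``k`` must be the number of steps in the largest delay across the whole
    synapse population; pushing a bundle whose delay exceeds ``k`` means the
    structure was mis-sized and raises :class:`SimulationError`.
    """

    def __init__(self, n_partitions: int, k: int):
        if n_partitions < 1:
            raise ConfigurationError("need at least one partition")
        self.k = int(k)
        self.n_partitions = int(n_partitions)
        size = n_slots(k)
        self._queues: list[list[list[int]]] = [
            [[] for _ in range(size)] for _ in range(n_partitions)
        ]
        self._head = 0
        self.high_water = np.zeros((n_partitions, size), dtype=np.int64)

    def advance(
        self, spiking_neurons: np.ndarray, bundles: BundleIndex
    ) -> list[list[int]]:
        """Push the bundle groups of all spiking neurons; pop the due queues.

        Returns, per partition, the list of bundle ids whose delay elapsed this
        step (including any delay-0 bundle pushed this step).  The consumed
        queues are cleared and the ring rotates.
        """
        size = self.k + 1
        head = self._head
        for neuron in np.asarray(spiking_neurons, dtype=np.int64):
            lo, hi = bundles.bundles_of_neuron(int(neuron))
            for b in range(lo, hi):
                d = int(bundles.bundle_delay[b])
                if d > self.k:
                    raise SimulationError(
                        f"bundle delay {d} steps exceeds structure size k={self.k}"
                    )
                p = int(bundles.bundle_partition[b])
                slot = (head + d) % size
                queue = self._queues[p][slot]
                queue.append(b)
                if len(queue) > self.high_water[p, slot]:
                    self.high_water[p, slot] = len(queue)
        due = []
        for p in range(self.n_partitions):
            ring = self._queues[p]
            due.append(ring[head])
            ring[head] = []
        self._head = (head + 1) % size
        return due

    def is_empty(self) -> bool:
        return all(not q for ring in self._queues for q in ring)

    def state(self) -> tuple:
        """Label-order snapshot of all queues (multiset per slot, sorted)."""
        size = self.k + 1
        return tuple(
            tuple(
                tuple(sorted(self._queues[p][(self._head + i) % size]))
                for i in range(size)
            )
            for p in range(self.n_partitions)
        )
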