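"""Connectivity sampling, delay discretisation and compressed partitioned storage.

Synapses are stored in compressed (YALE/CSR-like) form: one concatenated array
of synapse ids sorted first by the *sort-key* neuron (presynaptic for the
pre-sorted matrix, postsynaptic for the dual post-sorted matrix used by
plasticity), then by the partition of the opposite-side neuron, then by synapse
id (stable).  The synapses sharing one (neuron, partition) pair form a *synapse
group*; within a group, the synapses sharing one delay form a *synapse bundle*,
the unit queued during heterogeneous delay propagation.

Partitions are contiguous, ceil-sized blocks of target-neuron ids.  Synapse
ids are assigned in edge-input order before sorting, and all sorts are stable,
so rebuilding the structures is reproducible.  Indices are 0-based throughout
and delays are stored as integer steps only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core_state import SimClock
from .errors import ConfigurationError, EdgeFileError

__all__ = [
    "EdgeList",
    "ConnectivitySpec",
    "CompressedConnectivity",
    "BundleIndex",
    "sample_bernoulli",
    "discretize_delays",
    "partition_of",
    "build_compressed",
    "build_bundles",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_adjacency_mtx",
    "read_adjacency_mtx",
]

_TSV_COLUMNS = ("pre", "post", "delay_steps", "weight")


@dataclass
class EdgeList:
    """Per-synapse records: (pre, post, delay in steps, weight).

    Synapse ids are implicit: synapse ``s`` is row ``s`` of these arrays.
    """

    pre: np.ndarray
    post: np.ndarray
    delay_steps: np.ndarray
    weight: np.ndarray
    n_pre: int
    n_post: int

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.delay_steps = np.asarray(self.delay_steps, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        n = self.pre.size
        if not (self.post.size == self.delay_steps.size == self.weight.size == n):
            raise ConfigurationError("edge arrays must have equal length")
        if n:
            if self.pre.min() < 0 or self.pre.max() >= self.n_pre:
                raise ConfigurationError("presynaptic id out of bounds")
            if self.post.min() < 0 or self.post.max() >= self.n_post:
                raise ConfigurationError("postsynaptic id out of bounds")
            if self.delay_steps.min() < 0:
                raise ConfigurationError("delay_steps must be nonnegative")

    def __len__(self) -> int:
        return self.pre.size

    @property
    def max_delay(self) -> int:
        return int(self.delay_steps.max()) if len(self) else 0


@dataclass
class ConnectivitySpec:
    """Bernoulli connectivity: every ordered pair connected with p = min(C/n_pre, 1).

    With a target mean of ``C`` synapses per neuron, populations smaller than
    ``C`` become complete graphs (self-connections included when ``allow_self``).
    """

    n_pre: int
    n_post: int
    C: float
    allow_self: bool = True

    def __post_init__(self) -> None:
        if self.n_pre < 1 or self.n_post < 1:
            raise ConfigurationError("population sizes must be >= 1")
        if self.C < 0:
            raise ConfigurationError("C must be nonnegative")

    @property
    def p(self) -> float:
        return min(self.C / self.n_pre, 1.0)


def sample_bernoulli(
    spec: ConnectivitySpec,
    rng_stream: np.random.Generator,
    block_rows: int = 1024,
) -> EdgeList:
    """Sample the Bernoulli graph of ``spec``; edges in (pre, post) row-major order.

    Every ordered pair is an independent trial with probability ``spec.p``;
    sampling proceeds in blocks of presynaptic rows to bound memory.  Delays
    and weights are initialised to zero — builders attach them afterwards.
    """
    p = spec.p
    pres, posts = [], []
    if p > 0.0:
        for start in range(0, spec.n_pre, block_rows):
            stop = min(start + block_rows, spec.n_pre)
            mask = rng_stream.random((stop - start, spec.n_post)) < p
            if not spec.allow_self:
                rows = np.arange(start, stop)
                on_diag = (rows >= 0) & (rows < spec.n_post)
                mask[np.flatnonzero(on_diag), rows[on_diag]] = False
            r, c = np.nonzero(mask)
            pres.append(r + start)
            posts.append(c)
    pre = np.concatenate(pres) if pres else np.empty(0, dtype=np.int64)
    post = np.concatenate(posts) if posts else np.empty(0, dtype=np.int64)
    zeros = np.zeros(pre.size)
    return EdgeList(pre, post, zeros, zeros.copy(), spec.n_pre, spec.n_post)


def discretize_delays(delays_seconds, clock: SimClock) -> np.ndarray:
    """Delays in seconds -> integer steps, round-to-nearest with ties to even.

    Ties-to-even makes a U(0, 4) ms delay distribution at dt = 0.1 ms occupy
    all 41 step values {0, ..., 40} (floor rounding would yield only 40).
    """
    delays = np.asarray(delays_seconds, dtype=np.float64)
    if delays.size and delays.min() < 0:
        raise ConfigurationError("delays must be nonnegative")
    return np.rint(delays / clock.dt).astype(np.int64)


def partition_of(post_id, n_post: int, P: int):
    """Partition index of a target neuron: contiguous blocks of size ceil(n/P)."""
    if not (1 <= P <= n_post):
        raise ConfigurationError(f"partition count P={P} outside [1, {n_post}]")
    block = -(-n_post // P)  # ceil division
    return np.asarray(post_id, dtype=np.int64) // block


@dataclass
class CompressedConnectivity:
    """Partitioned compressed connectivity (YALE-style).

    ``synapse_ids`` concatenates all synapse ids sorted by
    (sort-key neuron, partition, synapse id).  Group ``(i, p)`` occupies
    ``synapse_ids[group_offsets[i*P + p] : group_offsets[i*P + p + 1]]``.
    ``pre_of``/``post_of``/``delay_of``/``weight_of`` are per-synapse lookups
    indexed by synapse id.
    """

    synapse_ids: np.ndarray
    group_offsets: np.ndarray
    n_partitions: int
    direction: str  # "pre" (sorted by presynaptic id) or "post"
    n_pre: int
    n_post: int
    pre_of: np.ndarray
    post_of: np.ndarray
    delay_of: np.ndarray
    weight_of: np.ndarray

    @property
    def n_synapses(self) -> int:
        return self.synapse_ids.size

    @property
    def n_sort_neurons(self) -> int:
        return self.n_pre if self.direction == "pre" else self.n_post

    @property
    def group_counts(self) -> np.ndarray:
        return np.diff(self.group_offsets)

    def group_slice(self, neuron: int, partition: int) -> np.ndarray:
        """Synapse ids of group (neuron, partition)."""
        g = neuron * self.n_partitions + partition
        return self.synapse_ids[self.group_offsets[g]: self.group_offsets[g + 1]]

    def neuron_slice(self, neuron: int) -> np.ndarray:
        """All synapse ids of one sort-key neuron (its partitions are adjacent)."""
        P = self.n_partitions
        lo = self.group_offsets[neuron * P]
        hi = self.group_offsets[(neuron + 1) * P]
        return self.synapse_ids[lo:hi]

    def gather(self, neurons: np.ndarray) -> np.ndarray:
        """Sorted synapse ids of all given sort-key neurons."""
        if len(neurons) == 0:
            return np.empty(0, dtype=np.int64)
        parts = [self.neuron_slice(int(i)) for i in neurons]
        out = np.concatenate(parts)
        out.sort()
        return out


def build_compressed(
    edges: EdgeList, P: int, direction: str = "pre"
) -> CompressedConnectivity:
    """Build the compressed partitioned matrix from an edge list.

    For ``direction="pre"`` synapses are sorted by presynaptic neuron and
    partitioned over postsynaptic ids; for ``direction="post"`` the roles swap
    (the dual matrix used to dispatch postsynaptically triggered effects).
    The sort is stable on (neuron, partition, synapse id), so the construction
    is a bijection on synapse ids.
    """
    if direction not in ("pre", "post"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if direction == "pre":
        key, other, n_key, n_other = edges.pre, edges.post, edges.n_pre, edges.n_post
    else:
        key, other, n_key, n_other = edges.post, edges.pre, edges.n_post, edges.n_pre
    part = partition_of(other, n_other, P)
    syn = np.arange(len(edges), dtype=np.int64)
    order = np.lexsort((syn, part, key))
    group_index = key * P + part
    counts = np.bincount(group_index, minlength=n_key * P)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    return CompressedConnectivity(
        synapse_ids=syn[order],
        group_offsets=offsets.astype(np.int64),
        n_partitions=P,
        direction=direction,
        n_pre=edges.n_pre,
        n_post=edges.n_post,
        pre_of=edges.pre.copy(),
        post_of=edges.post.copy(),
        delay_of=edges.delay_steps.copy(),
        weight_of=edges.weight.copy(),
    )


@dataclass
class BundleIndex:
    """Synapse bundles: per (neuron, partition) group, one bundle per distinct delay.

    ``synapses`` concatenates synapse ids bundle-major (sorted by group, delay,
    synapse id); bundle ``b`` is ``synapses[bundle_offsets[b]:bundle_offsets[b+1]]``
    with delay ``bundle_delay[b]``.  The bundles of group ``g`` (its *bundle
    group*) are ``group_bundle_offsets[g] : group_bundle_offsets[g+1]``.
    With ``per_synapse=True`` every synapse forms its own singleton bundle
    (the queue-per-synapse mode).
    """

    synapses: np.ndarray
    bundle_offsets: np.ndarray
    bundle_delay: np.ndarray
    bundle_partition: np.ndarray
    group_bundle_offsets: np.ndarray
    n_partitions: int
    per_synapse: bool = False

    @property
    def n_bundles(self) -> int:
        return self.bundle_delay.size

    @property
    def max_delay(self) -> int:
        return int(self.bundle_delay.max()) if self.n_bundles else 0

    def bundle_synapses(self, b: int) -> np.ndarray:
        return self.synapses[self.bundle_offsets[b]: self.bundle_offsets[b + 1]]

    def bundles_of_neuron(self, neuron: int) -> tuple[int, int]:
        """Bundle-id range covering all partitions of one sort-key neuron."""
        P = self.n_partitions
        lo = self.group_bundle_offsets[neuron * P]
        hi = self.group_bundle_offsets[(neuron + 1) * P]
        return int(lo), int(hi)


def build_bundles(conn: CompressedConnectivity, per_synapse: bool = False) -> BundleIndex:
    """Group each (neuron, partition) synapse group into bundles by delay."""
    P = conn.n_partitions
    n_groups = conn.n_sort_neurons * P
    counts = conn.group_counts
    group_of_pos = np.repeat(np.arange(n_groups, dtype=np.int64), counts)
    syn = conn.synapse_ids
    delay = conn.delay_of[syn]
    order = np.lexsort((syn, delay, group_of_pos))
    syn_sorted = syn[order]
    delay_sorted = delay[order]
    group_sorted = group_of_pos[order]

    m = syn_sorted.size
    if m == 0:
        empty = np.empty(0, dtype=np.int64)
        return BundleIndex(empty, np.zeros(1, dtype=np.int64), empty, empty,
                           np.zeros(n_groups + 1, dtype=np.int64), P, per_synapse)

    if per_synapse:
        starts = np.arange(m, dtype=np.int64)
    else:
        new = np.empty(m, dtype=bool)
        new[0] = True
        new[1:] = (delay_sorted[1:] != delay_sorted[:-1]) | (
            group_sorted[1:] != group_sorted[:-1]
        )
        starts = np.flatnonzero(new).astype(np.int64)
    bundle_offsets = np.concatenate((starts, [m])).astype(np.int64)
    bundle_delay = delay_sorted[starts]
    bundle_group = group_sorted[starts]
    bundle_partition = bundle_group % P
    group_bundle_offsets = np.searchsorted(
        bundle_group, np.arange(n_groups + 1, dtype=np.int64)
    ).astype(np.int64)
    return BundleIndex(
        synapses=syn_sorted,
        bundle_offsets=bundle_offsets,
        bundle_delay=bundle_delay,
        bundle_partition=bundle_partition,
        group_bundle_offsets=group_bundle_offsets,
        n_partitions=P,
        per_synapse=per_synapse,
    )


# ---------------------------------------------------------------------------
# On-disk formats

def write_edges_tsv(edges: EdgeList, path) -> None:
    """Write a '#'-headed TSV edge list: pre, post, delay_steps, weight."""
    df = pd.DataFrame(
        {
            "pre": edges.pre,
            "post": edges.post,
            "delay_steps": edges.delay_steps,
            "weight": edges.weight,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(_TSV_COLUMNS) + "\n")
        fh.write(f"# n_pre={edges.n_pre}\tn_post={edges.n_post}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_edges_tsv(path, n_pre: int | None = None, n_post: int | None = None) -> EdgeList:
    """Read an edge-list TSV written by :func:`write_edges_tsv`.

    Population sizes are taken from the header comment unless overridden.
    """
    header_sizes = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# n_pre="):
                fields = dict(
                    item.split("=") for item in line[2:].strip().split("\t")
                )
                header_sizes = (int(fields["n_pre"]), int(fields["n_post"]))
            if not line.startswith("#"):
                break
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=list(_TSV_COLUMNS),
            dtype={"pre": np.int64, "post": np.int64,
                   "delay_steps": np.int64, "weight": np.float64},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise EdgeFileError(f"malformed edge list {path}: {exc}") from exc
    if n_pre is None or n_post is None:
        if header_sizes is None:
            size = lambda col: int(df[col].max()) + 1 if len(df) else 1
            header_sizes = (size("pre"), size("post"))
        n_pre = n_pre if n_pre is not None else header_sizes[0]
        n_post = n_post if n_post is not None else header_sizes[1]
    return EdgeList(
        df["pre"].to_numpy(), df["post"].to_numpy(),
        df["delay_steps"].to_numpy(), df["weight"].to_numpy(), n_pre, n_post,
    )


def write_adjacency_mtx(edges: EdgeList, path) -> None:
    """Export the adjacency pattern in MatrixMarket coordinate format."""
    mat = scipy.sparse.coo_matrix(
        (np.ones(len(edges)), (edges.pre, edges.post)),
        shape=(edges.n_pre, edges.n_post),
    )
    scipy.io.mmwrite(str(path), mat)


def read_adjacency_mtx(path) -> EdgeList:
    """Import adjacency from MatrixMarket; delays/weights default to zero."""
    try:
        mat = scipy.io.mmread(str(path)).tocoo()
    except ValueError as exc:
        raise EdgeFileError(f"malformed MatrixMarket file {path}: {exc}") from exc
    order = np.lexsort((mat.col, mat.row))
    pre = mat.row[order].astype(np.int64)
    post = mat.col[order].astype(np.int64)
    zeros = np.zeros(pre.size)
    return EdgeList(pre, post, zeros, zeros.copy(), mat.shape[0], mat.shape[1])
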