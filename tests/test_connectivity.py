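"""Connectivity sampling, delay discretisation, compressed matrices, bundles, IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikering import (
    ConnectivitySpec,
    EdgeList,
    SimClock,
    build_bundles,
    build_compressed,
    discretize_delays,
    partition_of,
    sample_bernoulli,
)
from spikering.connectivity import (
    read_adjacency_mtx,
    read_edges_tsv,
    write_adjacency_mtx,
    write_edges_tsv,
)
from spikering.errors import ConfigurationError, EdgeFileError
from spikering.rng import stream


def toy_edges():
    """The 3-edge example: 0->1, 0->3, 1->0 over 2x4 populations."""
    return EdgeList(pre=[0, 0, 1], post=[1, 3, 0], delay_steps=[0, 0, 0],
                    weight=[1.0, 1.0, 1.0], n_pre=2, n_post=4)


class TestSampling:
    def test_small_population_gives_complete_graph(self):
        """C >= n forces p = 1: N = 500 yields all 500^2 pairs incl. self-loops."""
        spec = ConnectivitySpec(500, 500, 1000.0, allow_self=True)
        edges = sample_bernoulli(spec, stream(0, "connectivity", "t"))
        assert len(edges) == 250_000
        assert np.any(edges.pre == edges.post)  # self-connections present

    def test_mean_in_degree_within_binomial_3_sigma(self):
        n, C = 4000, 400.0
        spec = ConnectivitySpec(n, n, C)
        edges = sample_bernoulli(spec, stream(1, "connectivity", "t"))
        mean_in = len(edges) / n
        # mean of n iid Binomial(n, C/n) in-degrees
        sigma = np.sqrt(C * (1 - C / n) / n)
        assert abs(mean_in - C) < 3 * sigma

    def test_zero_c_gives_empty_edge_list(self):
        spec = ConnectivitySpec(100, 100, 0.0)
        assert len(sample_bernoulli(spec, stream(0, "connectivity", "t"))) == 0

    def test_allow_self_false_excludes_diagonal(self):
        spec = ConnectivitySpec(50, 50, 100.0, allow_self=False)
        edges = sample_bernoulli(spec, stream(0, "connectivity", "t"))
        assert not np.any(edges.pre == edges.post)


class TestDelayDiscretisation:
    def test_exact_multiples(self):
        clock = SimClock(dt=1e-4)
        assert discretize_delays(np.array([2e-3]), clock)[0] == 20

    def test_tie_rounds_to_even(self):
        clock = SimClock(dt=1e-4)
        got = discretize_delays(np.array([0.25e-3, 0.35e-3]), clock)
        assert got.tolist() == [2, 4]

    def test_uniform_0_4ms_occupies_41_step_values(self):
        """10^6 draws from U(0, 4) ms at dt = 0.1 ms hit exactly {0,...,40}."""
        clock = SimClock(dt=1e-4)
        draws = stream(2, "delays", "t").uniform(0.0, 4e-3, 1_000_000)
        steps = discretize_delays(draws, clock)
        assert np.unique(steps).size == 41
        assert steps.min() == 0 and steps.max() == 40

    def test_negative_delay_faults(self):
        with pytest.raises(ConfigurationError):
            discretize_delays(np.array([-1e-3]), SimClock())


class TestPartitioning:
    def test_single_partition_maps_everything_to_zero(self):
        assert np.all(partition_of(np.arange(10), 10, 1) == 0)

    def test_ceil_sized_contiguous_blocks(self):
        got = partition_of(np.arange(5), 5, 2)
        assert got.tolist() == [0, 0, 0, 1, 1]

    def test_partition_per_neuron_is_identity(self):
        ids = np.arange(7)
        assert np.array_equal(partition_of(ids, 7, 7), ids)

    def test_out_of_range_partition_count_faults(self):
        with pytest.raises(ConfigurationError):
            partition_of(0, 4, 5)


class TestCompressed:
    def test_toy_construction_matches_direct_grouping(self):
        conn = build_compressed(toy_edges(), P=2, direction="pre")
        assert conn.group_slice(0, 0).tolist() == [0]   # 0->1 (partition 0)
        assert conn.group_slice(0, 1).tolist() == [1]   # 0->3 (partition 1)
        assert conn.group_slice(1, 0).tolist() == [2]   # 1->0
        assert conn.group_slice(1, 1).tolist() == []

    def test_two_spiking_neurons_with_two_partitions_give_four_groups(self):
        edges = EdgeList(pre=[0, 0, 1, 1], post=[0, 3, 1, 2],
                         delay_steps=[0] * 4, weight=[1.0] * 4, n_pre=2, n_post=4)
        conn = build_compressed(edges, P=2)
        non_trivial = [
            (i, p)
            for i in range(2)
            for p in range(2)
            if conn.group_slice(i, p).size
        ]
        assert len(non_trivial) == 4

    def test_empty_edge_list(self):
        empty = EdgeList(np.empty(0, np.int64), np.empty(0, np.int64),
                         np.empty(0, np.int64), np.empty(0), 3, 3)
        conn = build_compressed(empty, P=2)
        assert np.all(conn.group_counts == 0)
        assert np.all(np.diff(conn.group_offsets) >= 0)

    def test_post_sorted_dual_matrix_swaps_roles(self):
        conn = build_compressed(toy_edges(), P=1, direction="post")
        # sorted by postsynaptic neuron: post 0 <- syn 2, post 1 <- syn 0, post 3 <- syn 1
        assert conn.neuron_slice(0).tolist() == [2]
        assert conn.neuron_slice(1).tolist() == [0]
        assert conn.neuron_slice(3).tolist() == [1]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.data())
    def test_bijection_and_partition_regrouping(self, P, data):
        """Any build is a bijection on synapse ids, and concatenating a
        neuron's partition groups reproduces the P = 1 ordering."""
        n_pre, n_post = 8, 6
        m = data.draw(st.integers(0, 40))
        pre = data.draw(st.lists(st.integers(0, n_pre - 1), min_size=m, max_size=m))
        post = data.draw(st.lists(st.integers(0, n_post - 1), min_size=m, max_size=m))
        edges = EdgeList(pre, post, np.zeros(m, np.int64), np.ones(m),
                         n_pre, n_post)
        conn = build_compressed(edges, P=min(P, n_post))
        assert sorted(conn.synapse_ids.tolist()) == list(range(m))
        base = build_compressed(edges, P=1)
        for i in range(n_pre):
            assert sorted(conn.neuron_slice(i).tolist()) == sorted(
                base.neuron_slice(i).tolist()
            )


class TestBundles:
    def _edges_with_delays(self, delays):
        m = len(delays)
        return EdgeList(pre=[0] * m, post=list(range(m)), delay_steps=delays,
                        weight=[1.0] * m, n_pre=1, n_post=max(m, 1))

    def test_equal_delays_one_bundle_per_group(self):
        conn = build_compressed(self._edges_with_delays([5, 5, 5]), P=1)
        bundles = build_bundles(conn)
        assert bundles.n_bundles == 1
        assert bundles.bundle_synapses(0).tolist() == [0, 1, 2]

    def test_distinct_delays_one_synapse_per_bundle(self):
        conn = build_compressed(self._edges_with_delays([3, 1, 2]), P=1)
        bundles = build_bundles(conn)
        assert bundles.n_bundles == 3
        assert all(bundles.bundle_synapses(b).size == 1 for b in range(3))

    def test_mixed_delays_group_by_delay_value(self):
        conn = build_compressed(self._edges_with_delays([3, 1, 3]), P=1)
        bundles = build_bundles(conn)
        assert bundles.n_bundles == 2
        by_delay = {
            int(bundles.bundle_delay[b]): bundles.bundle_synapses(b).tolist()
            for b in range(2)
        }
        assert by_delay == {1: [1], 3: [0, 2]}

    def test_per_synapse_mode_degenerates_to_singletons(self):
        conn = build_compressed(self._edges_with_delays([3, 1, 3]), P=1)
        bundles = build_bundles(conn, per_synapse=True)
        assert bundles.n_bundles == 3
        assert all(bundles.bundle_synapses(b).size == 1 for b in range(3))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 4), st.lists(st.integers(0, 5), max_size=30))
    def test_bundles_tile_groups_with_unique_delays(self, P, delays):
        m = len(delays)
        rng = np.random.default_rng(0)
        n_pre, n_post = 4, 5
        edges = EdgeList(rng.integers(0, n_pre, m), rng.integers(0, n_post, m),
                         delays, np.ones(m), n_pre, n_post)
        conn = build_compressed(edges, P=P)
        bundles = build_bundles(conn)
        sizes = np.diff(bundles.bundle_offsets)
        assert sizes.sum() == m
        # within every group: delays unique, sizes tile the group
        for g in range(n_pre * P):
            lo, hi = (bundles.group_bundle_offsets[g],
                      bundles.group_bundle_offsets[g + 1])
            ds = bundles.bundle_delay[lo:hi]
            assert np.unique(ds).size == ds.size
            assert sizes[lo:hi].sum() == conn.group_counts[g]


class TestEdgeIO:
    def test_tsv_round_trip_is_lossless(self, tmp_path):
        edges = EdgeList(pre=[0, 2, 1], post=[3, 0, 1],
                         delay_steps=[7, 0, 40], weight=[0.5, -1.25, 1e-18],
                         n_pre=3, n_post=4)
        path = tmp_path / "edges.tsv"
        write_edges_tsv(edges, path)
        back = read_edges_tsv(path)
        for attr in ("pre", "post", "delay_steps", "weight"):
            assert np.array_equal(getattr(edges, attr), getattr(back, attr))
        assert (back.n_pre, back.n_post) == (3, 4)

    def test_empty_edge_list_round_trips_as_header_only(self, tmp_path):
        empty = EdgeList(np.empty(0, np.int64), np.empty(0, np.int64),
                         np.empty(0, np.int64), np.empty(0), 5, 5)
        path = tmp_path / "empty.tsv"
        write_edges_tsv(empty, path)
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert len(read_edges_tsv(path)) == 0

    def test_malformed_rows_fault(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# pre\tpost\tdelay_steps\tweight\n1\ttwo\t3\t4.0\n")
        with pytest.raises(EdgeFileError):
            read_edges_tsv(path)

    def test_matrixmarket_round_trip_of_toy_adjacency(self, tmp_path):
        edges = toy_edges()
        path = tmp_path / "adj.mtx"
        write_adjacency_mtx(edges, path)
        text = path.read_text()
        assert "coordinate" in text.splitlines()[0]
        back = read_adjacency_mtx(path)
        assert len(back) == 3
        assert sorted(zip(back.pre.tolist(), back.post.tolist())) == [
            (0, 1), (0, 3), (1, 0)
        ]
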