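"""Engine schedule, determinism, composability, delivery conservation, config."""

import json

import numpy as np
import pytest

from spikering import (
    EdgeList,
    LIFParams,
    Network,
    SpikeMonitor,
    StateMonitor,
    StaticEffect,
    build_network,
)
from spikering.errors import ConfigurationError
from spikering.rng import stream


def small_random_network(seed, n=30, P=2, delay_mode="heterogeneous",
                         record=True):
    """Noisy LIF population with random sparse inhibition, <= 50 neurons."""
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < 0.2
    pre, post = np.nonzero(mask)
    delays = rng.integers(0, 8, pre.size)
    if delay_mode == "homogeneous":
        delays = np.full(pre.size, 5)
    edges = EdgeList(pre, post, delays, np.full(pre.size, 0.1e-3), n, n)
    net = Network(dt=1e-4, seed=seed)
    pop = net.add_lif("p", n, LIFParams(mu_ext=22e-3, sigma_ext=2e-3))
    pop.state.v = stream(seed, "init", "p").uniform(10e-3, 20e-3, n)
    net.connect("s", "p", "p", edges, delay_mode=delay_mode, partitions=P,
                effect=StaticEffect("v", -1.0))
    if record:
        net.add_monitor(SpikeMonitor("p"))
    return net, edges


class TestSchedule:
    def test_zero_duration_run_changes_nothing(self):
        net, _ = small_random_network(0)
        v_before = net.populations["p"].state.v.copy()
        result = net.run(0.0)
        assert result.step_count == 0
        assert np.array_equal(net.populations["p"].state.v, v_before)

    def test_ten_seconds_at_tenth_millisecond_is_1e5_steps(self):
        net = Network(dt=1e-4, seed=0)
        net.add_poisson("g", 1, rate=0.0)
        result = net.run(10.0)
        assert result.step_count == 100_000

    def test_empty_network_runs_and_records_nothing(self):
        net = Network(dt=1e-4, seed=0)
        result = net.run(0.01)
        assert result.step_count == 100 and result.monitors == []

    def test_delivered_effect_first_influences_next_step(self):
        """An effect landing at step n+k is visible in the step-n+k sample but
        can only change spiking from step n+k+1 on."""
        params = LIFParams(mu_ext=0.0, sigma_ext=0.0)
        net = Network(dt=1e-4, seed=0)
        pop = net.add_lif("p", 2, params)
        pop.state.v = np.array([25e-3, 0.0])
        edges = EdgeList([0], [1], [0], [0.1e-3], 2, 2)  # no delay
        net.connect("s", "p", "p", edges, delay_mode="none",
                    effect=StaticEffect("v", -1.0))
        mon = StateMonitor("p", variables=("v",), neurons=(1,))
        net.add_monitor(mon)
        net.run(3e-4)
        trace = mon.values("v", 1)
        assert trace[0] == -0.1e-3  # spike at step 0 delivered within step 0


class TestDeterminism:
    def test_identical_seed_reproduces_bitwise(self):
        runs = []
        for _ in range(2):
            net, _ = small_random_network(11)
            net.run(0.2)
            runs.append(net.monitors[0].spike_array())
        assert np.array_equal(runs[0], runs[1])
        assert runs[0].size > 0

    @pytest.mark.parametrize("P", [1, 3, 15])
    def test_partition_count_invariance(self, P):
        base, _ = small_random_network(13, P=1)
        base.run(0.2)
        other, _ = small_random_network(13, P=P)
        other.run(0.2)
        assert np.array_equal(base.monitors[0].spike_array(),
                              other.monitors[0].spike_array())

    def test_split_run_equals_single_run(self):
        whole, _ = small_random_network(17)
        whole.run(0.2)
        split, _ = small_random_network(17)
        split.run(0.12)
        split.run(0.08)
        assert np.array_equal(whole.monitors[0].spike_array(),
                              split.monitors[0].spike_array())

    def test_monitors_do_not_perturb_dynamics(self):
        recorded, _ = small_random_network(19, record=True)
        recorded.run(0.2)
        bare, _ = small_random_network(19, record=False)
        bare.run(0.2)
        assert np.array_equal(recorded.populations["p"].state.v,
                              bare.populations["p"].state.v)


class TestDeliveryConservation:
    """Every (spike, synapse) pair delivered exactly once, delay_steps later,
    matching a naive event-list oracle built from the raw spike train."""

    @pytest.mark.parametrize("seed,delay_mode", [
        (1, "heterogeneous"), (2, "heterogeneous"), (3, "homogeneous"),
    ])
    def test_matches_naive_event_list_oracle(self, seed, delay_mode):
        net, edges = small_random_network(seed, n=25, P=3, delay_mode=delay_mode)
        net.record_deliveries()
        net.run(0.1)
        n_steps = net.clock.step
        spikes = net.monitors[0].spike_array()
        assert spikes.size > 0
        # oracle: schedule every outgoing synapse of every spike
        outgoing = {i: np.flatnonzero(edges.pre == i) for i in range(edges.n_pre)}
        expected = sorted(
            (int(step + edges.delay_steps[s]), int(s))
            for step, i in spikes
            for s in outgoing[int(i)]
            if step + edges.delay_steps[s] < n_steps
        )
        got = sorted(
            (int(step), int(s))
            for step, due in net.synapses[0].deliveries
            for s in due
        )
        assert got == expected

    def test_no_neuron_spikes_twice_within_tau_ref(self):
        net, _ = small_random_network(23)
        net.run(0.3)
        spikes = net.monitors[0].spike_array()
        params = net.populations["p"].params
        ref_steps = params.ref_steps(net.clock.dt)
        for neuron in np.unique(spikes[:, 1]):
            steps = np.sort(spikes[spikes[:, 1] == neuron, 0])
            if steps.size > 1:
                assert np.diff(steps).min() >= ref_steps


class TestHeterogeneousHomogeneousCrossCheck:
    def test_uniform_delays_through_queues_match_ring_buffer_bitwise(self):
        """The heterogeneous machinery with every delay = 5 steps reproduces
        the homogeneous path spike-for-spike."""
        trains = []
        for mode in ("homogeneous", "heterogeneous"):
            rng = np.random.default_rng(31)
            n = 40
            mask = rng.random((n, n)) < 0.25
            pre, post = np.nonzero(mask)
            edges = EdgeList(pre, post, np.full(pre.size, 5),
                             np.full(pre.size, 0.1e-3), n, n)
            net = Network(dt=1e-4, seed=31)
            pop = net.add_lif("p", n, LIFParams(mu_ext=22e-3, sigma_ext=2e-3))
            pop.state.v = stream(31, "init", "p").uniform(10e-3, 20e-3, n)
            net.connect("s", "p", "p", edges, delay_mode=mode, partitions=2,
                        effect=StaticEffect("v", -1.0))
            net.add_monitor(SpikeMonitor("p"))
            net.run(0.3)
            trains.append(net.monitors[0].spike_array())
        assert trains[0].size > 0
        assert np.array_equal(trains[0], trains[1])


class TestConfig:
    CONFIG = {
        "populations": [
            {"name": "gen", "model": "poisson", "n": 40, "rate": 100.0},
            {"name": "out", "model": "lif", "n": 10,
             "params": {"mu_ext": 0.0, "sigma_ext": 0.0},
             "v_init": {"uniform": [0.0, 0.005]}},
        ],
        "synapses": [
            {"name": "ff", "pre": "gen", "post": "out",
             "connectivity": {"C": 20},
             "weight": 0.5e-3, "sign": 1.0, "target": "v",
             "delay": {"mode": "heterogeneous", "low": 0.0, "high": 0.002}},
        ],
        "monitors": [
            {"kind": "spikes", "population": "out"},
            {"kind": "rate", "population": "out"},
        ],
        "run": {"duration": 0.2, "dt": 1e-4, "seed": 5, "partitions": 2,
                "bundle_mode": True},
    }

    def test_structured_config_builds_and_runs(self):
        net, run_cfg = build_network(self.CONFIG)
        result = net.run(run_cfg["duration"])
        assert result.step_count == 2000
        assert result.spikes.n_spikes > 0

    def test_config_build_is_reproducible(self, tmp_path):
        path = tmp_path / "net.json"
        path.write_text(json.dumps(self.CONFIG))
        arrays = []
        for _ in range(2):
            net, run_cfg = build_network(json.loads(path.read_text()))
            net.run(run_cfg["duration"])
            arrays.append(net.monitors[0].spike_array())
        assert np.array_equal(arrays[0], arrays[1])

    def test_unknown_references_fault(self):
        bad = {"populations": [{"name": "a", "model": "nope", "n": 1}]}
        with pytest.raises(ConfigurationError):
            build_network(bad)
        bad2 = json.loads(json.dumps(self.CONFIG))
        bad2["synapses"][0]["target"] = "does_not_exist"
        net, run_cfg = build_network(bad2)
        with pytest.raises(ConfigurationError):
            net.run(0.01)
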