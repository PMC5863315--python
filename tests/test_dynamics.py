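"""Unit and property tests for the excitable-node dynamics."""

import numpy as np
import pytest

from retgensync.dynamics import (
    DynamicsParams,
    StimulusSchedule,
    node_input,
    run,
    simulate_batch,
    state_names,
    step,
)
from retgensync.topology import TopologySpec, assemble_network

from conftest import small_random_network


def reference_step(network, states, stimulus, params):
    """Two-buffer pure-Python oracle for one synchronous update."""
    d, T = params.d, params.T
    n = network.n_total
    a = network.adjacency().toarray()
    out = np.zeros(n, dtype=int)
    for i in range(n):
        inp = stimulus[i]
        for j in range(n):
            if a[i, j] and 1 <= states[j] <= d:
                inp += a[i, j]
        s = states[i]
        if s < d:  # susceptible or non-final active stage
            out[i] = s + 1 if inp >= T else 0
        elif s == d:
            out[i] = d + 1  # forced refractory
        else:
            out[i] = 0  # refractory recovers
    return out


class TestStateNames:
    def test_default_chain_is_syzr(self):
        assert state_names(2) == ("S", "Y", "Z", "R")
        assert state_names(3) == ("S", "A1", "A2", "A3", "R")


class TestNodeInput:
    def test_isolated_node_without_stimulus(self):
        net = assemble_network(TopologySpec(N=1), np.random.default_rng(0))
        states = np.zeros(4, dtype=np.int8)
        assert node_input(net, states, np.zeros(4), 0) == 0.0

    def test_counts_active_neighbors(self):
        # 2x2 lattice component: node 0 neighbors 1 and 2
        net = assemble_network(TopologySpec(N=2), np.random.default_rng(0))
        states = np.zeros(16, dtype=np.int8)
        states[1] = 1  # Y
        states[2] = 2  # Z
        states[3] = 3  # R does not output
        assert node_input(net, states, np.zeros(16), 0) == 2.0

    def test_stimulus_adds_to_input(self):
        net = assemble_network(TopologySpec(N=2), np.random.default_rng(0))
        stim = np.zeros(16)
        stim[0] = 0.5
        assert node_input(net, np.zeros(16, dtype=np.int8), stim, 0) == 0.5

    def test_directed_tc_edge_is_one_way(self):
        net = small_random_network(np.random.default_rng(8), N=2, m=0, m_tc=1, m_cc=0)
        lgn, vc = net.tc_edges[0][0]
        states = np.zeros(net.n_total, dtype=np.int8)
        states[lgn] = 1
        zero = np.zeros(net.n_total)
        assert node_input(net, states, zero, vc) == 1.0  # VC hears LGN
        states[:] = 0
        states[vc] = 1
        assert node_input(net, states, zero, lgn) == 0.0  # LGN does not hear VC

    def test_unknown_node_rejected(self):
        net = assemble_network(TopologySpec(N=2), np.random.default_rng(0))
        with pytest.raises(KeyError):
            node_input(net, np.zeros(16, dtype=np.int8), np.zeros(16), 99)


class TestStepRules:
    """The transition table, exercised on a driven isolated node.

    An N=1 network has four isolated single-node components; stimulating
    node 0 controls its input exactly.
    """

    @pytest.fixture()
    def isolated(self):
        return assemble_network(TopologySpec(N=1), np.random.default_rng(0))

    @pytest.mark.parametrize(
        "state, inp, expected",
        [
            (0, 0.0, 0),  # S stays S below threshold
            (0, 1.0, 1),  # S -> Y at threshold
            (0, 2.0, 1),  # S -> Y above threshold
            (1, 1.0, 2),  # Y -> Z while driven
            (1, 0.0, 0),  # Y -> S when input drops
            (2, 5.0, 3),  # Z -> R regardless of input
            (2, 0.0, 3),
            (3, 5.0, 0),  # R -> S regardless of input
            (3, 0.0, 0),
        ],
    )
    def test_transition_table(self, isolated, state, inp, expected):
        params = DynamicsParams()
        states = np.zeros(4, dtype=np.int8)
        states[0] = state
        stim = np.zeros(4)
        stim[0] = inp
        assert step(isolated, states, stim, params)[0] == expected

    def test_longer_active_chain(self, isolated):
        params = DynamicsParams(d=3)
        states = np.array([2, 0, 0, 0], dtype=np.int8)
        stim = np.array([1.0, 0, 0, 0])
        assert step(isolated, states, stim, params)[0] == 3  # A2 -> A3
        states = np.array([3, 0, 0, 0], dtype=np.int8)
        assert step(isolated, states, stim, params)[0] == 4  # A3 -> R

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_two_buffer_oracle(self, seed):
        """Synchronous-update equivalence against an explicit reference."""
        rng = np.random.default_rng(seed)
        net = small_random_network(rng)
        params = DynamicsParams(T=1.0, d=2)
        states = rng.integers(0, 4, size=net.n_total).astype(np.int8)
        stim = rng.choice([0.0, 1.0], size=net.n_total)
        fast = step(net, states, stim, params)
        assert np.array_equal(fast, reference_step(net, states, stim, params))


class TestRun:
    def test_cortices_silent_without_tc_edges(self):
        net = assemble_network(TopologySpec(N=10, m=9, m_tc=0, m_cc=9), np.random.default_rng(1))
        trace = run(net, DynamicsParams(), StimulusSchedule.single_site(net, 0, 0))
        assert trace.counts[:, [1, 3]].sum() == 0  # no path from input to cortex
        assert trace.counts[:, [0, 2]].sum() > 0

    def test_zero_amplitude_keeps_network_quiescent(self, fig1_network):
        params = DynamicsParams(amplitude=0.0)
        trace = run(fig1_network, params, StimulusSchedule.full_row(fig1_network))
        assert trace.counts.sum() == 0

    def test_trace_shape_and_bounds(self, fig1_network):
        params = DynamicsParams(horizon=150, window=100)
        trace = run(fig1_network, params, StimulusSchedule.single_site(fig1_network, 3, 7))
        assert trace.counts.shape == (151, 4)
        assert trace.counts.min() >= 0 and trace.counts.max() <= 100
        assert trace.x.max() <= 100.0
        assert trace.counts[0].sum() == 0  # all susceptible at t = 0

    def test_driven_lgn_locks_to_drive_period(self):
        """With dense shortcut wiring the stimulated nucleus entrains to P.

        Expected period computed with the engine itself and frozen; the
        locking value 10 equals the drive period.
        """
        from retgensync.analysis import detect_period

        net = assemble_network(TopologySpec(N=10, m=81, m_tc=9, m_cc=9), np.random.default_rng(5))
        trace = run(net, DynamicsParams(), StimulusSchedule.single_site(net, 4, 4))
        assert detect_period(trace.counts[:, 0], 100).period == 10

    def test_determinism(self, fig1_network):
        params = DynamicsParams()
        sched = StimulusSchedule.single_site(fig1_network, 2, 9)
        t1 = run(fig1_network, params, sched)
        t2 = run(fig1_network, params, sched)
        assert np.array_equal(t1.counts, t2.counts)

    @pytest.mark.parametrize("seed", range(25))
    def test_no_node_active_longer_than_d(self, seed):
        """Forced inhibition: never more than d consecutive active steps."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 4))
        net = small_random_network(rng, N=3, m=3, m_tc=4, m_cc=3)
        params = DynamicsParams(T=1.0, d=d, P=5, horizon=60, window=10)
        left = int(rng.integers(0, 3))
        right = int(rng.integers(0, 3))
        trace = run(net, params, StimulusSchedule.single_site(net, left, right),
                    record_states=True)
        active = (trace.states >= 1) & (trace.states <= d)
        run_length = np.zeros(net.n_total, dtype=int)
        for t in range(len(active)):
            run_length = np.where(active[t], run_length + 1, 0)
            assert run_length.max() <= d

    def test_node_firing_twice_is_inhibited_next_step(self):
        """A node active at t and t+1 must be refractory at t+2 (d = 2)."""
        net = assemble_network(TopologySpec(N=2, m=2), np.random.default_rng(9))
        params = DynamicsParams(P=5, horizon=40, window=10)
        trace = run(net, params, StimulusSchedule.full_row(net), record_states=True)
        s = trace.states
        active = (s == 1) | (s == 2)
        both = active[:-2] & active[1:-1]
        assert both.any()  # the scenario occurs in this run
        assert np.all(s[2:][both] == 3)

    def test_schedule_outside_input_row_rejected(self, fig1_network):
        bad = StimulusSchedule(targets=((500,), (200,)))
        with pytest.raises(ValueError):
            run(fig1_network, DynamicsParams(), bad)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T": 0.0},
            {"P": 0},
            {"d": 0},
            {"window": 15, "P": 10},  # cannot confirm a period within window
            {"horizon": 50, "window": 100},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DynamicsParams(**kwargs)

    def test_transient_is_horizon_minus_window(self):
        assert DynamicsParams(horizon=200, window=100).transient == 100


class TestSimulateBatch:
    def test_batch_rows_match_independent_runs(self, fig1_network):
        params = DynamicsParams()
        schedules = [
            StimulusSchedule.single_site(fig1_network, a, b)
            for a, b in [(0, 0), (3, 7), (9, 9)]
        ]
        stim = np.stack([s.vector(fig1_network.n_total, 1.0) for s in schedules])
        counts, _ = simulate_batch(
            fig1_network.adjacency(), stim, params, fig1_network.n_per_component
        )
        for row, sched in zip(counts, schedules):
            solo = run(fig1_network, params, sched)
            assert np.array_equal(row, solo.counts)

    def test_shape_mismatch_rejected(self, fig1_network):
        with pytest.raises(ValueError):
            simulate_batch(
                fig1_network.adjacency(), np.zeros((1, 7)), DynamicsParams(), 100
            )
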