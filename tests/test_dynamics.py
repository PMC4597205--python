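"""Update schemes, ensemble frequencies, stabilization and noise."""

import numpy as np
import pytest

import booldyn as bd
from booldyn.dynamics import free_node_indices


def rng(seed=0):
    return np.random.default_rng(seed)


class TestStep:
    def test_negation_oscillator_period_two(self):
        m = bd.parse_model("A* = not A")
        s1 = bd.step(m, np.array([0]), "synchronous", rng())
        s2 = bd.step(m, s1, "synchronous", rng())
        assert s1.tolist() == [1] and s2.tolist() == [0]

    def test_synchronous_swap(self):
        m = bd.parse_model("A* = B\nB* = A")
        out = bd.step(m, np.array([0, 1]), "synchronous", rng())
        assert out.tolist() == [1, 0]

    def test_toggle_ga_one_step_successors(self, toggle):
        # from (0,0) the two possible single-node updates give the two
        # fixed points (1,0) and (0,1)
        seen = set()
        for seed in range(30):
            out = bd.step(toggle, np.array([0, 0]), "general_asynchronous",
                          rng(seed))
            seen.add(tuple(out.tolist()))
        assert seen == {(1, 0), (0, 1)}

    def test_ga_changes_at_most_one_node(self):
        m = bd.parse_model("A* = not B\nB* = not C\nC* = not A\nD* = A and B")
        state = np.array([0, 1, 0, 1])
        for seed in range(25):
            out = bd.step(m, state, "general_asynchronous", rng(seed))
            assert int(np.sum(out != state)) <= 1

    def test_random_order_applies_every_node_once(self):
        # A* = not A under ROA always flips exactly once per step
        m = bd.parse_model("A* = not A")
        out = bd.step(m, np.array([0]), "random_order", rng())
        assert out.tolist() == [1]


class TestEnsemble:
    def test_reproducible_bit_for_bit(self, toggle):
        cfg = bd.SimulationConfig(steps=40, replicates=200, seed=11)
        t1 = bd.simulate_ensemble(toggle, bd.Scenario(), cfg)
        t2 = bd.simulate_ensemble(toggle, bd.Scenario(), cfg)
        assert np.array_equal(t1.frequencies, t2.frequencies)

    def test_frozen_node_frequency_half(self):
        m = bd.parse_model("A* = A")
        cfg = bd.SimulationConfig(steps=30, replicates=10000, seed=5)
        trace = bd.simulate_ensemble(m, bd.Scenario(), cfg)
        # martingale: ~N(0.5, 0.005) at every step
        assert np.all(np.abs(trace.frequencies - 0.5) < 0.02)

    def test_frequencies_are_exact_replicate_fractions(self, toggle):
        cfg = bd.SimulationConfig(steps=25, replicates=64, seed=2)
        trace = bd.simulate_ensemble(toggle, bd.Scenario(), cfg)
        counts = trace.frequencies * trace.replicates
        assert np.allclose(counts, np.round(counts))
        assert trace.frequencies.min() >= 0 and trace.frequencies.max() <= 1

    def test_clamped_nodes_never_move(self):
        m = bd.parse_model("A* = not A\nB* = A")
        sc = bd.Scenario(fixed={"A": True})
        for scheme in ("synchronous", "general_asynchronous", "random_order"):
            cfg = bd.SimulationConfig(scheme=scheme, steps=30, replicates=50,
                                      seed=3, noise_flip_probability=0.05)
            trace = bd.simulate_ensemble(m, sc, cfg)
            assert np.all(trace.frequencies[:, 0] == 1.0)

    def test_clamped_nodes_excluded_from_ga_pool(self):
        m = bd.apply_scenario(bd.parse_model("A* = not A\nB* = A"),
                              bd.Scenario(fixed={"A": True}))
        assert free_node_indices(m).tolist() == [1]

    def test_all_off_initial_policy(self):
        m = bd.parse_model("A* = A\nB* = B")
        cfg = bd.SimulationConfig(steps=5, replicates=20, seed=1)
        trace = bd.simulate_ensemble(m, bd.Scenario(default_initial="all_off"),
                                     cfg)
        assert np.all(trace.frequencies == 0.0)

    def test_single_fixed_point_reached_by_all_schemes(self):
        # A* = TRUE, B* = A has the unique attractor (1, 1)
        m = bd.parse_model("A* = TRUE\nB* = A")
        for scheme in ("synchronous", "general_asynchronous", "random_order"):
            cfg = bd.SimulationConfig(scheme=scheme, steps=60, replicates=300,
                                      seed=7)
            trace = bd.simulate_ensemble(m, bd.Scenario(), cfg)
            assert np.all(trace.frequencies[-1] == 1.0)


class TestStabilization:
    def test_band_classification(self):
        m = bd.parse_model("A* = FALSE\nB* = TRUE\nC* = not C")
        cfg = bd.SimulationConfig(steps=100, replicates=400, seed=9)
        rep = bd.detect_stabilization(bd.simulate_ensemble(m, bd.Scenario(), cfg),
                                      window=40)
        assert rep.status["A"] == "stable_off" and rep.steady["A"] == 0.0
        assert rep.status["B"] == "stable_on" and rep.steady["B"] == 1.0
        assert rep.status["C"] == "oscillating"
        assert abs(rep.steady["C"] - 0.5) < 0.1

    def test_window_longer_than_trace_rejected(self, toggle):
        cfg = bd.SimulationConfig(steps=10, replicates=10, seed=0)
        trace = bd.simulate_ensemble(toggle, bd.Scenario(), cfg)
        with pytest.raises(ValueError):
            bd.detect_stabilization(trace, window=500)

    def test_epsilon_bounds_invariant(self):
        m = bd.parse_model("A* = TRUE\nB* = FALSE")
        cfg = bd.SimulationConfig(steps=50, replicates=100, seed=4)
        rep = bd.detect_stabilization(bd.simulate_ensemble(m, bd.Scenario(), cfg),
                                      window=20, epsilon=0.01)
        for node, status in rep.status.items():
            if status == "stable_on":
                assert rep.steady[node] >= 0.99
            if status == "stable_off":
                assert rep.steady[node] <= 0.01


class TestNoise:
    def test_zero_probability_is_identical(self, toggle):
        cfg0 = bd.SimulationConfig(steps=40, replicates=100, seed=6)
        cfg_eps = bd.SimulationConfig(steps=40, replicates=100, seed=6,
                                      noise_flip_probability=0.0)
        a = bd.simulate_ensemble(toggle, bd.Scenario(), cfg0)
        b = bd.simulate_ensemble(toggle, bd.Scenario(), cfg_eps)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_frozen_node_relaxes_to_half_under_noise(self):
        # a self-maintaining node with flip noise is a two-state symmetric
        # Markov chain whose stationary distribution is uniform
        m = bd.parse_model("A* = A")
        sc = bd.Scenario(initial={"A": True}, default_initial="all_off")
        cfg = bd.SimulationConfig(steps=600, replicates=3000, seed=8,
                                  noise_flip_probability=0.05)
        trace = bd.simulate_ensemble(m, sc, cfg)
        assert abs(trace.frequencies[-1, 0] - 0.5) < 0.05

    def test_noise_comparison_reports_deltas(self, toggle):
        cfg = bd.SimulationConfig(steps=80, replicates=200, seed=1)
        cmp = bd.noise_robustness(toggle, bd.Scenario(), cfg, 0.02, window=30)
        assert set(cmp.delta) == {"A", "B"}
        assert all(0.0 <= v <= 1.0 for v in cmp.delta.values())

    def test_flip_probability_range_enforced(self, toggle):
        cfg = bd.SimulationConfig(steps=10, replicates=10, seed=0)
        with pytest.raises(ValueError):
            bd.noise_robustness(toggle, bd.Scenario(), cfg, 0.5)
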