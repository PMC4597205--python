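"""STG construction, terminal SCCs, basins, patterns and phenotypes."""

import numpy as np
import pytest

import booldyn as bd
from booldyn.attractors import activation_pattern, classify_phenotype
from booldyn.fixtures import RandomNetworkSpec, oracle_attractors, random_model
from booldyn.model import ModelError


def state(model, **bits):
    return sum(int(v) << model.index(k) for k, v in bits.items())


class TestBuildStg:
    def test_toggle_synchronous_structure(self, toggle):
        stg = bd.build_stg(toggle, "synchronous")
        # (0,0) <-> (1,1); the two fixed points have no outgoing edges
        s00, s11 = 0b00, 0b11
        assert stg.successors(s00) == {s11}
        assert stg.successors(s11) == {s00}
        assert stg.successors(0b01) == set()
        assert stg.successors(0b10) == set()

    def test_toggle_ga_successors(self, toggle):
        stg = bd.build_stg(toggle, "general_asynchronous")
        assert stg.successors(0b00) == {0b01, 0b10}

    def test_out_degree_bounded_by_free_nodes(self):
        for seed in range(5):
            m = random_model(RandomNetworkSpec(n=6, in_degree=2, seed=seed))
            stg = bd.build_stg(m, "general_asynchronous")
            assert stg.out_degrees().max() <= m.n

    def test_sync_out_degree_at_most_one(self):
        m = random_model(RandomNetworkSpec(n=6, in_degree=2, seed=3))
        stg = bd.build_stg(m, "synchronous")
        assert stg.out_degrees().max() <= 1

    def test_cap_enforced(self, cac):
        with pytest.raises(ModelError, match="cap"):
            bd.build_stg(cac, "general_asynchronous", cap=10)

    def test_clamped_bits_never_updated(self):
        m = bd.apply_scenario(bd.parse_model("A* = not A\nB* = A"),
                              bd.Scenario(fixed={"A": False}))
        stg = bd.build_stg(m, "general_asynchronous")
        for s in range(stg.n_states):
            for t in stg.successors(s):
                assert t & 1 == s & 1  # bit 0 (A) untouched


class TestFindAttractors:
    def test_toggle_synchronous_three_attractors(self, toggle):
        stg = bd.build_stg(toggle, "synchronous")
        atts = bd.find_attractors(stg)
        summary = {(a.kind, frozenset(a.states.tolist())) for a in atts}
        assert summary == {
            ("fixed_point", frozenset({0b01})),
            ("fixed_point", frozenset({0b10})),
            ("cyclic", frozenset({0b00, 0b11})),
        }

    def test_toggle_ga_only_fixed_points(self, toggle):
        stg = bd.build_stg(toggle, "general_asynchronous")
        atts = bd.find_attractors(stg)
        assert {a.kind for a in atts} == {"fixed_point"}
        assert {int(a.states[0]) for a in atts} == {0b01, 0b10}

    def test_ordering_by_smallest_state(self, toggle):
        stg = bd.build_stg(toggle, "synchronous")
        firsts = [int(a.states[0]) for a in bd.find_attractors(stg)]
        assert firsts == sorted(firsts)


class TestBasins:
    def test_single_fixed_point_full_basin(self):
        m = bd.parse_model("A* = TRUE\nB* = A")
        stg = bd.build_stg(m, "general_asynchronous")
        atts = bd.compute_basins(stg, bd.find_attractors(stg))
        assert len(atts) == 1
        assert atts[0].basin_fraction == 1.0
        assert atts[0].exclusive_basin_fraction == 1.0

    def test_toggle_ga_shared_basins(self, toggle):
        # each fixed point is backward-reachable from itself, (0,0) and
        # (1,1): total 3/4; only the fixed point itself is exclusive: 1/4
        stg = bd.build_stg(toggle, "general_asynchronous")
        atts = bd.compute_basins(stg, bd.find_attractors(stg))
        for att in atts:
            assert att.basin_fraction == pytest.approx(0.75)
            assert att.exclusive_basin_fraction == pytest.approx(0.25)

    def test_synchronous_basins_partition_state_space(self):
        for seed in range(5):
            m = random_model(RandomNetworkSpec(n=7, in_degree=2, seed=seed))
            stg = bd.build_stg(m, "synchronous")
            atts = bd.compute_basins(stg, bd.find_attractors(stg))
            assert sum(a.basin_fraction for a in atts) == pytest.approx(1.0)
            for a in atts:
                assert a.exclusive_basin_fraction == pytest.approx(a.basin_fraction)

    def test_every_state_reaches_some_attractor(self):
        m = random_model(RandomNetworkSpec(n=6, in_degree=2, seed=9))
        stg = bd.build_stg(m, "general_asynchronous")
        atts = bd.compute_basins(stg, bd.find_attractors(stg))
        assert sum(a.basin_fraction for a in atts) >= 1.0  # overlaps allowed


class TestPatternsAndPhenotypes:
    def test_fixed_point_pattern_is_binary(self):
        pattern = activation_pattern(np.array([0b101]), ["X", "Y", "Z"])
        assert pattern == {"X": ("full", 1.0), "Y": ("inactive", 0.0),
                           "Z": ("full", 1.0)}

    def test_two_cycle_pattern_is_half(self):
        pattern = activation_pattern(np.array([0b01, 0b10]), ["X", "Y"])
        assert pattern["X"] == ("partial", 0.5)
        assert pattern["Y"] == ("partial", 0.5)

    @pytest.mark.parametrize("pattern,label", [
        ({"Apoptosis": ("full", 1.0), "Proliferation": ("inactive", 0.0)},
         "apoptosis"),
        ({"Proliferation": ("full", 1.0)}, "proliferation"),
        ({"Proliferation": ("partial", 0.5)}, "limited proliferation"),
        ({"Proliferation": ("inactive", 0.0)}, "resting"),
        ({"CYCLIND1": ("full", 1.0), "P21": ("inactive", 0.0)}, "proliferation"),
        ({"CYCLIND1": ("inactive", 0.0), "P21": ("inactive", 0.0)}, "resting"),
        ({"CYCLIND1": ("full", 1.0), "P21": ("partial", 0.5)},
         "limited proliferation"),
    ])
    def test_phenotype_decision_table(self, pattern, label):
        assert classify_phenotype(pattern) == label

    def test_missing_readouts_reported(self):
        with pytest.raises(ModelError, match="CYCLIND1"):
            classify_phenotype({"GSK3B": ("full", 1.0)})


class TestOracleEquivalence:
    @pytest.mark.parametrize("scheme", ["synchronous", "general_asynchronous"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, scheme, seed):
        m = random_model(RandomNetworkSpec(n=6, in_degree=2, seed=seed))
        stg = bd.build_stg(m, scheme)
        mine = bd.compute_basins(stg, bd.find_attractors(stg))
        ref = oracle_attractors(m, scheme)
        assert len(mine) == len(ref)
        for a, b in zip(mine, ref):
            assert frozenset(int(s) for s in a.states) == b.states
            assert a.kind == b.kind
            assert a.basin_fraction == pytest.approx(b.basin_fraction)
            assert (a.exclusive_basin_fraction
                    == pytest.approx(b.exclusive_basin_fraction))


class TestNodeFixingScan:
    def test_redundant_clamp_keeps_single_attractor(self):
        m = bd.parse_model("A* = TRUE\nB* = A")
        entries = bd.node_fixing_scan(m, ["B"])
        on = next(e for e in entries if e.value)
        assert on.single_attractor and on.n_attractors == 1

    def test_scan_covers_both_values(self):
        m = bd.make_toy("toggle")
        entries = bd.node_fixing_scan(m)
        assert {(e.node, e.value) for e in entries} == {
            ("A", True), ("A", False), ("B", True), ("B", False)}
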