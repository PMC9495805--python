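"""Stability operators: loop signs, conversion, regulation, narrowing,
modular construction."""

import numpy as np
import pytest

import halfchaos as hc
from conftest import build_system


def brute_force_cycles(inputs, max_len):
    """Independent DFS census of simple directed cycles of length <= max_len,
    normalized to start at their smallest node."""
    N, K = inputs.shape
    succ = [[] for _ in range(N)]  # adjacency: src -> targets
    for tgt in range(N):
        for src in inputs[tgt]:
            succ[int(src)].append(tgt)
    found = set()

    def dfs(start, node, path):
        for nxt in succ[node]:
            if nxt == start and len(path) >= 2:
                found.add(tuple(path))
            elif nxt > start and nxt not in path and len(path) < max_len:
                dfs(start, nxt, path + [nxt])

    for start in range(N):
        dfs(start, start, [start])
    return found


def copy_slot_system(slot_values):
    """N=4, K=2, s=4 net where node n's function copies its input slot
    slot_values[n] (or is constant when slot_values[n] is None)."""
    N, K, s = 4, 2, 4
    inputs = np.array([[1, 2], [2, 3], [3, 0], [0, 1]])
    functions = np.zeros((N, s**K), dtype=np.int64)
    idx = np.arange(s**K)
    for n, mode in enumerate(slot_values):
        if mode is None:
            functions[n] = 1
        elif mode >= 0:
            functions[n] = (idx // s**mode) % s
        else:  # reversal on slot -mode-1
            functions[n] = s - 1 - (idx // s ** (-mode - 1)) % s
    return build_system(N, K, s, inputs, functions, np.zeros(N, dtype=np.int64))


class TestLinkSign:
    def test_identity_copy_positive(self):
        sys = copy_slot_system([0, 0, 0, 0])
        # node 0 copies slot 0, which reads node 1
        assert hc.link_influence_sign(sys, 1, 0) == 1

    def test_reversal_negative(self):
        sys = copy_slot_system([-1, 0, 0, 0])  # node 0 = s-1 - slot0
        assert hc.link_influence_sign(sys, 1, 0) == -1

    def test_constant_zero(self):
        sys = copy_slot_system([None, 0, 0, 0])
        assert hc.link_influence_sign(sys, 1, 0) == 0

    def test_irrelevant_input_zero(self):
        sys = copy_slot_system([0, 0, 0, 0])
        # node 0 ignores slot 1 (node 2)
        assert hc.link_influence_sign(sys, 2, 0) == 0


class TestLoopCensus:
    def test_long_ring_empty_at_small_bound(self):
        # K=1 ring of 5: the only cycle has length 5 > max_len=3
        inputs = np.array([[4], [0], [1], [2], [3]])
        sys = build_system(5, 1, 2, inputs, np.tile([0, 1], (5, 1)), np.zeros(5))
        assert hc.find_feedback_loops(sys, max_len=3) == []

    def test_two_cycle_positive(self):
        # 2-ring of copy functions: one loop, both links +, sign +
        inputs = np.array([[1], [0]])
        sys = build_system(2, 1, 2, inputs, np.tile([0, 1], (2, 1)), np.zeros(2))
        loops = hc.find_feedback_loops(sys, max_len=3)
        assert len(loops) == 1
        assert loops[0].cycle == (0, 1)
        assert loops[0].sign == "+"

    def test_mixed_signs_product_rule(self):
        # copy then NOT: + * - = -
        inputs = np.array([[1], [0]])
        functions = np.array([[0, 1], [1, 0]])
        sys = build_system(2, 1, 2, inputs, functions, np.zeros(2))
        loops = hc.find_feedback_loops(sys, max_len=2)
        assert loops[0].sign == "-"

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_brute_force(self, seed):
        spec = hc.NetworkSpec(N=15, K=2, s=2, seed=seed)
        sys = hc.random_system(spec)
        loops = hc.find_feedback_loops(sys, max_len=3)
        assert {r.cycle for r in loops} == brute_force_cycles(sys.inputs, 3)


class TestConversion:
    def test_no_positive_loops_unchanged(self):
        inputs = np.array([[1], [0]])
        functions = np.array([[1, 0], [0, 1]])  # NOT then copy: sign -
        sys = build_system(2, 1, 2, inputs, functions, np.zeros(2))
        out, info = hc.convert_positive_to_negative(sys, max_len=2)
        assert np.array_equal(out.functions, sys.functions)
        assert info["positive_remaining"] == 0

    def test_invert_link_is_table_permutation(self):
        spec = hc.NetworkSpec(N=20, K=3, s=4, seed=1)
        sys = hc.random_system(spec)
        src, tgt = int(sys.inputs[5, 1]), 5
        out = hc.invert_link(sys, src, tgt)
        assert sorted(out.functions[tgt]) == sorted(sys.functions[tgt])  # permutation
        assert np.array_equal(hc.invert_link(out, src, tgt).functions, sys.functions)

    @pytest.mark.parametrize("seed", range(4))
    def test_pass_does_not_increase_positive_count(self, seed):
        spec = hc.NetworkSpec(N=25, K=2, s=2, seed=seed)
        sys = hc.random_system(spec)
        before = sum(r.sign == "+" for r in hc.find_feedback_loops(sys, 3))
        out, _ = hc.convert_positive_to_negative(sys, max_len=3, recursive=True)
        after = sum(r.sign == "+" for r in hc.find_feedback_loops(out, 3))
        assert after <= before

    def test_topology_preserved(self):
        spec = hc.NetworkSpec(N=30, K=3, s=2, seed=3)
        sys = hc.random_system(spec)
        out, _ = hc.convert_positive_to_negative(sys, max_len=3, recursive=True)
        assert np.array_equal(out.inputs, sys.inputs)
        assert np.array_equal(out.state, sys.state)


class TestRegulation:
    @pytest.fixture()
    def pas(self):
        spec = hc.NetworkSpec(N=60, K=3, s=4, seed=4)
        return hc.make_point_attractor(hc.random_system(spec))

    def test_level_c_identity(self, pas):
        out = hc.add_pas_regulation(pas, "c")
        assert np.array_equal(out.functions, pas.functions)

    def test_level_a_entry_budget_and_pas_preserved(self, pas):
        out = hc.add_pas_regulation(pas, "a")
        per_node = (out.functions != pas.functions).sum(axis=1)
        assert (per_node <= 3 * (4 - 1)).all()  # K(s-1) distance-1 tuples
        assert np.array_equal(hc.step(out, out.state), out.state)

    def test_level_b_one_tuple_per_node(self, pas):
        out = hc.add_pas_regulation(pas, "b", seed=1)
        per_node = (out.functions != pas.functions).sum(axis=1)
        assert (per_node <= 1).all()
        assert np.array_equal(hc.step(out, out.state), out.state)

    def test_non_pas_rejected(self):
        spec = hc.NetworkSpec(N=60, K=3, s=4, seed=6)
        sys = hc.random_system(spec)
        assert not np.array_equal(hc.step(sys, sys.state), sys.state)
        with pytest.raises(ValueError, match="PAS"):
            hc.add_pas_regulation(sys, "a")


class TestNarrowing:
    def test_homogeneity_bounds(self):
        spec = hc.NetworkSpec(N=50, K=3, s=4, seed=2)
        P, mean_P = hc.internal_homogeneity(hc.random_system(spec))
        assert (P >= 0.25).all() and (P <= 1.0).all()

    def test_monotone_and_reaches_target(self):
        spec = hc.NetworkSpec(N=40, K=3, s=4, seed=8)
        sys = hc.random_system(spec)
        _, before = hc.internal_homogeneity(sys)
        out, info = hc.narrow_functions(sys, target_P=0.6, seed=8)
        _, after = hc.internal_homogeneity(out)
        assert after >= before
        assert after >= 0.6
        assert not info["warning"]

    def test_full_narrowing_gives_fixed_point_in_one_step(self):
        spec = hc.NetworkSpec(N=30, K=2, s=3, seed=1)
        out, _ = hc.narrow_functions(hc.random_system(spec), target_P=1.0, iterations=200, seed=1)
        P, mean_P = hc.internal_homogeneity(out)
        assert mean_P == 1.0  # all functions constant
        s1 = hc.step(out, out.state)
        assert np.array_equal(hc.step(out, s1), s1)

    def test_unreachable_target_warns(self):
        spec = hc.NetworkSpec(N=20, K=3, s=4, seed=3)
        _, info = hc.narrow_functions(hc.random_system(spec), target_P=0.99, iterations=1, seed=0)
        assert info["warning"]

    def test_invalid_target(self):
        spec = hc.NetworkSpec(N=20, K=3, s=4, seed=3)
        with pytest.raises(ValueError):
            hc.narrow_functions(hc.random_system(spec), target_P=0.25)


class TestModular:
    def test_zero_coupling_disconnects(self):
        spec = hc.NetworkSpec(N=60, K=3, s=2, seed=5)
        sys = hc.build_modular_network(spec, n_modules=6, inter_frac=0.0)
        import networkx as nx

        g = hc.methods.topology_digraph(sys).to_undirected()
        assert nx.number_connected_components(g) >= 6

    def test_inter_fraction_census(self):
        """Empirical inter-module link share ~ inter_frac (binomial 3 sigma)."""
        inter_frac = 0.2
        total = inter = 0
        for seed in range(100):
            spec = hc.NetworkSpec(N=60, K=3, s=2, seed=seed)
            sys = hc.build_modular_network(spec, n_modules=6, inter_frac=inter_frac)
            mod = np.arange(60) // 10
            for tgt in range(60):
                for src in sys.inputs[tgt]:
                    total += 1
                    inter += mod[tgt] != mod[int(src)]
        p_hat = inter / total
        sigma = np.sqrt(inter_frac * (1 - inter_frac) / total)
        assert abs(p_hat - inter_frac) <= 3 * sigma

    def test_indivisible_rejected(self):
        spec = hc.NetworkSpec(N=50, K=3, s=2, seed=0)
        with pytest.raises(ValueError):
            hc.build_modular_network(spec, n_modules=7, inter_frac=0.1)
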