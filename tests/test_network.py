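"""Network construction: topology, function tables, PAS, disturbances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import halfchaos as hc


class TestInputIndex:
    @pytest.mark.parametrize(
        "tup,s,expected",
        [
            ((0, 0, 0), 4, 0),
            ((1, 2), 4, 9),  # 1 + 2*4, slot 0 least significant
            ((3, 3, 3), 4, 63),  # s**K - 1
            ((1,), 2, 1),
        ],
    )
    def test_examples(self, tup, s, expected):
        assert hc.input_index(tup, s) == expected

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            hc.input_index((0, 4), 4)

    @given(st.integers(2, 5), st.integers(1, 4), st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bijective_over_table(self, s, K, data):
        tup = data.draw(st.tuples(*[st.integers(0, s - 1)] * K))
        idx = hc.input_index(tup, s)
        assert 0 <= idx < s**K
        # decode and re-encode
        decoded = tuple((idx // s**j) % s for j in range(K))
        assert decoded == tup


class TestTopology:
    @pytest.mark.parametrize("topology_type", ["er", "ss", "sf"])
    def test_link_conservation_and_no_self(self, topology_type):
        spec = hc.NetworkSpec(N=400, K=3, s=4, topology_type=topology_type, seed=3)
        inputs = hc.generate_topology(spec)
        assert inputs.shape == (400, 3)
        assert inputs.size == 1200  # K*N links
        for n in range(400):
            row = inputs[n]
            assert n not in row, "self-link"
            assert len(set(row.tolist())) == 3, "duplicate link"

    def test_two_node_k1(self):
        spec = hc.NetworkSpec(N=2, K=1, s=2, topology_type="er", seed=0)
        inputs = hc.generate_topology(spec)
        assert inputs[0, 0] == 1 and inputs[1, 0] == 0

    def test_seed_determinism(self):
        spec = hc.NetworkSpec(N=50, K=3, s=4, topology_type="sf", seed=9)
        a = hc.random_system(spec)
        b = hc.random_system(spec)
        assert a.equal(b)

    def test_out_degree_variance_ordering(self):
        """Degree census over ensembles: var(sf) > var(ss) >~ var(er)."""
        var = {}
        for topo in ("er", "ss", "sf"):
            vs = []
            for seed in range(100):
                spec = hc.NetworkSpec(N=400, K=3, s=4, topology_type=topo, seed=seed)
                inputs = hc.generate_topology(spec)
                k = np.bincount(inputs.ravel(), minlength=400)
                vs.append(k.var())
            var[topo] = np.mean(vs)
        assert var["sf"] > var["ss"]
        assert var["ss"] > 0.8 * var["er"]  # ss at least comparable to binomial
        assert var["sf"] > var["er"]


class TestFunctions:
    def test_shape_and_range(self):
        spec = hc.NetworkSpec(N=400, K=3, s=4, seed=1)
        f = hc.generate_functions(spec)
        assert f.shape == (400, 64)  # s**K = 64 entries per node
        assert f.min() >= 0 and f.max() <= 3

    def test_reproducible(self):
        spec = hc.NetworkSpec(N=30, K=3, s=4, seed=5)
        assert np.array_equal(hc.generate_functions(spec), hc.generate_functions(spec))

    def test_entry_uniformity_chi_square(self):
        """10^5+ entries: value histogram consistent with uniform."""
        spec = hc.NetworkSpec(N=2000, K=3, s=4, seed=13)
        f = hc.generate_functions(spec)
        counts = np.bincount(f.ravel(), minlength=4)
        assert counts.sum() == 2000 * 64
        chi2, p = stats.chisquare(counts)
        assert p > 0.0027  # within 3 sigma of multinomial expectation


class TestPointAttractor:
    def test_fixed_point_by_construction(self):
        for seed in range(5):
            spec = hc.NetworkSpec(N=100, K=3, s=4, seed=seed)
            pas = hc.make_point_attractor(hc.random_system(spec))
            assert np.array_equal(hc.step(pas, pas.state), pas.state)

    def test_modification_audit(self):
        spec = hc.NetworkSpec(N=100, K=3, s=4, seed=2)
        sys = hc.random_system(spec)
        pas = hc.make_point_attractor(sys)
        diff = np.argwhere(pas.functions != sys.functions)
        assert len(diff) <= 100  # at most one entry per node
        observed = hc.network.observed_indices(sys)
        for node, idx in diff:
            assert idx == observed[node]


class TestDisturbances:
    @pytest.mark.parametrize("N,s,expected", [(400, 4, 1200), (10, 2, 10)])
    def test_completeness(self, N, s, expected):
        spec = hc.NetworkSpec(N=N, K=3, s=s, seed=1)
        sys = hc.random_system(spec)
        ds = hc.enumerate_disturbances(sys)
        assert len(ds) == expected  # N*(s-1)
        assert len({(d.node, d.input_index, d.new_output) for d in ds}) == expected

    def test_t0_encoding(self):
        spec = hc.NetworkSpec(N=50, K=3, s=4, seed=4)
        sys = hc.random_system(spec)
        observed = hc.network.observed_indices(sys)
        for d in hc.enumerate_disturbances(sys):
            assert d.input_index == observed[d.node]
            assert d.new_output != sys.functions[d.node, d.input_index]

    def test_apply_single_entry_and_involution(self):
        spec = hc.NetworkSpec(N=50, K=3, s=4, seed=4)
        sys = hc.random_system(spec)
        d = hc.enumerate_disturbances(sys)[17]
        disturbed = hc.apply_disturbance(sys, d)
        assert (disturbed.functions != sys.functions).sum() == 1
        back = hc.apply_disturbance(
            disturbed,
            hc.Disturbance(d.node, d.input_index, int(sys.functions[d.node, d.input_index])),
        )
        assert np.array_equal(back.functions, sys.functions)

    def test_noop_disturbance_rejected(self):
        spec = hc.NetworkSpec(N=20, K=2, s=3, seed=0)
        sys = hc.random_system(spec)
        idx = int(hc.network.observed_indices(sys)[0])
        cur = int(sys.functions[0, idx])
        with pytest.raises(ValueError):
            hc.apply_disturbance(sys, hc.Disturbance(0, idx, cur))

    def test_random_disturbance_is_member(self):
        spec = hc.NetworkSpec(N=30, K=3, s=4, seed=8)
        sys = hc.random_system(spec)
        members = {(d.node, d.input_index, d.new_output) for d in hc.enumerate_disturbances(sys)}
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = hc.random_disturbance(sys, rng)
            assert (d.node, d.input_index, d.new_output) in members


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=1, K=1, s=2),
            dict(N=10, K=0, s=2),
            dict(N=10, K=3, s=1),
            dict(N=3, K=3, s=2),  # N <= K
            dict(N=10, K=2, s=2, topology_type="xx"),
        ],
    )
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            hc.NetworkSpec(**kwargs)
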