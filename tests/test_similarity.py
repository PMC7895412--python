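import numpy as np
import pytest

from kinunify.similarity import (
    JaccardMatrix, between_matrix, jaccard, order_matrix, overlap_graph,
    randomize_network, rank_cdf, significant_pairs, top_percent_flags,
    within_matrix, graph_edge_list,
)
from kinunify.stringency import ThresholdedNetwork


def net(sets, level="low", algo="a"):
    return ThresholdedNetwork(algo, level, sets)


class TestJaccard:
    def test_examples(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set(), set()) == 0.0

    def test_range_symmetry_identity_on_1000_random_pairs(self):
        rng = np.random.default_rng(5)
        universe = np.arange(50)
        for _ in range(1000):
            a = set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
            b = set(rng.choice(universe, size=rng.integers(0, 30), replace=False))
            j = jaccard(a, b)
            assert 0.0 <= j <= 1.0
            assert j == jaccard(b, a)
            if a:
                assert jaccard(a, a) == 1.0


class TestSignificantPairs:
    def make_matrix(self, vals, sizes):
        names = [f"k{i}" for i in range(len(vals))]
        return JaccardMatrix(names, list(names), np.array(vals, dtype=float),
                             True, ("low", "low"),
                             dict(zip(names, sizes)), dict(zip(names, sizes)))

    def test_threshold_and_size_guard(self):
        m = self.make_matrix([[1.0, 0.5, 0.6], [0.5, 1.0, 0.2],
                              [0.6, 0.2, 1.0]], [150, 150, 40])
        flags, per_kinase, frac = significant_pairs(m)
        assert flags[0, 1] and flags[1, 0]      # J=0.5 >= 0.49, both n >= 100
        assert not flags[0, 2]                  # J=0.6 but one set of 40
        assert per_kinase == {"k0": True, "k1": True, "k2": False}
        assert frac == pytest.approx(2 / 3)

    def test_diagonal_excluded(self):
        m = self.make_matrix([[1.0, 0.0], [0.0, 1.0]], [200, 200])
        flags, per_kinase, frac = significant_pairs(m)
        assert not flags.any()
        assert frac == 0.0


class TestOrderMatrix:
    def test_two_by_two_unchanged(self):
        m = JaccardMatrix(["a", "b"], ["a", "b"],
                          np.array([[1.0, 0.2], [0.2, 1.0]]), True,
                          ("low", "low"), {"a": 10, "b": 10}, {"a": 10, "b": 10})
        assert order_matrix(m).row_kinases == ["a", "b"]

    def _block_network(self, perm):
        # two planted clusters sharing most substrates within a block
        sets = {
            "c1a": set(range(0, 100)), "c1b": set(range(0, 95)) | {200},
            "c1c": set(range(5, 100)),
            "c2a": set(range(1000, 1100)), "c2b": set(range(1000, 1095)) | {300},
            "c2c": set(range(1005, 1100)),
        }
        names = list(sets)
        ordered = [names[i] for i in perm]
        return net({k: {str(s) for s in sets[k]} for k in ordered})

    @pytest.mark.parametrize("perm", [(0, 1, 2, 3, 4, 5), (3, 0, 4, 1, 5, 2)])
    def test_planted_clusters_contiguous(self, perm):
        m = order_matrix(within_matrix(self._block_network(perm)))
        labels = ["1" if k.startswith("c1") else "2" for k in m.row_kinases]
        # members of each planted cluster are adjacent in the leaf order
        assert labels in (["1"] * 3 + ["2"] * 3, ["2"] * 3 + ["1"] * 3)

    def test_values_unchanged_as_multiset(self):
        m = within_matrix(self._block_network(range(6)))
        om = order_matrix(m)
        assert sorted(m.values.ravel()) == sorted(om.values.ravel())


class TestOverlapGraph:
    def test_no_significant_pairs_empty_graph(self):
        m = within_matrix(net({"a": {"1"}, "b": {"2"}}))
        assert overlap_graph(m).number_of_edges() == 0

    def test_three_mutually_significant_form_triangle(self):
        shared = {str(i) for i in range(120)}
        m = within_matrix(net({
            "a": shared | {"x"}, "b": shared | {"y"}, "c": shared | {"z"}}))
        g = overlap_graph(m)
        assert g.number_of_edges() == 3
        assert set(g.nodes) == {"a", "b", "c"}

    def test_edge_count_matches_flagged_upper_triangle(self):
        rng = np.random.default_rng(2)
        universe = [str(i) for i in range(300)]
        sets = {f"k{i}": set(rng.choice(universe, size=150, replace=False))
                for i in range(8)}
        m = within_matrix(net(sets))
        flags, _, _ = significant_pairs(m)
        g = overlap_graph(m)
        assert g.number_of_edges() == int(np.triu(flags, k=1).sum())
        df = graph_edge_list(g)
        assert len(df) == g.number_of_edges()


class TestBetweenMatrix:
    def test_identical_networks_diagonal_is_row_max(self):
        rng = np.random.default_rng(8)
        universe = [str(i) for i in range(200)]
        sets = {f"k{i}": set(rng.choice(universe, size=60, replace=False))
                for i in range(6)}
        m = between_matrix(net(sets), net(sets, algo="b"))
        for i in range(len(m.row_kinases)):
            assert m.values[i, i] == m.values[i].max() == 1.0

    def test_top_one_percent_flags_with_tie_policy(self):
        names = [f"k{i}" for i in range(10)]
        vals = np.zeros((10, 10))
        vals[3, 4] = 0.9
        m = JaccardMatrix(names, list(names), vals, False, ("low", "low"))
        flags = top_percent_flags(m)
        assert flags.sum() == 1 and flags[3, 4]
        # boundary ties are all flagged
        vals2 = vals.copy()
        vals2[5, 6] = 0.9
        m2 = JaccardMatrix(names, list(names), vals2, False, ("low", "low"))
        assert top_percent_flags(m2).sum() == 2

    def test_direction_asymmetry_of_self_match_ranks(self):
        # agreement from A to B need not equal agreement from B to A: the
        # matrix is just transposed, but row-wise self-match ranks differ
        a_sets = {"SRC": {"1", "2", "3", "4"}, "LCK": {"9"}}
        b_sets = {"SRC": {"1", "2"}, "LCK": {"1", "2", "3", "4"}}
        ab = between_matrix(net(a_sets), net(b_sets, algo="b"))
        ba = between_matrix(net(b_sets, algo="b"), net(a_sets))
        assert np.allclose(ab.values, ba.values.T)  # Jaccard is symmetric
        r_ab = rank_cdf(ab, 2).ranks
        r_ba = rank_cdf(ba, 2).ranks
        assert r_ab["SRC"] == 2 and r_ba["SRC"] == 1  # directions disagree


class TestRankCDF:
    def test_unique_row_maximum_gives_cdf_one(self):
        names = ["a", "b", "c"]
        vals = np.array([[0.9, 0.1, 0.1], [0.2, 0.8, 0.1], [0.0, 0.1, 0.7]])
        m = JaccardMatrix(names, list(names), vals, False, ("low", "low"))
        cdf = rank_cdf(m, 3)
        assert cdf.cdf(1) == 1.0

    def test_all_equal_row_takes_worst_rank(self):
        names = ["a", "b", "c"]
        vals = np.array([[0.5, 0.5, 0.5], [0.0, 0.9, 0.0], [0.0, 0.0, 0.9]])
        m = JaccardMatrix(names, list(names), vals, False, ("low", "low"))
        cdf = rank_cdf(m, 3)
        assert cdf.ranks["a"] == 3  # N_B under the worst-rank tie policy

    def test_random_expectation_line(self):
        names = [f"k{i}" for i in range(20)]
        m = JaccardMatrix(names, list(names), np.zeros((20, 20)), False,
                          ("low", "low"))
        cdf = rank_cdf(m, 20)
        assert cdf.random_expectation(5) == pytest.approx(5 / 20)

    def test_uniform_random_matrices_track_expectation(self):
        # Monte-Carlo: mean cdf(k) within 3 standard errors of k / N_B
        rng = np.random.default_rng(3)
        N, reps = 10, 1000
        names = [f"k{i}" for i in range(N)]
        total = np.zeros(N)
        for _ in range(reps):
            m = JaccardMatrix(names, list(names), rng.random((N, N)),
                              False, ("low", "low"))
            c = rank_cdf(m, N)
            total += [c.cdf(k) for k in range(1, N + 1)]
        mean = total / reps
        expect = np.arange(1, N + 1) / N
        se = np.sqrt(expect * (1 - expect) / (reps * N)) + 1e-12
        assert np.all(np.abs(mean - expect)[:-1] <= 3 * se[:-1] + 0.01)
        assert mean[-1] == 1.0


class TestRandomize:
    def base(self):
        rng = np.random.default_rng(0)
        universe = [str(i) for i in range(400)]
        return net({f"k{i}": set(rng.choice(universe, size=30 + 5 * i,
                                            replace=False))
                    for i in range(10)})

    def test_kinase_degrees_preserved_exactly(self):
        base = self.base()
        rand = randomize_network(base, seed=1)
        assert rand.kinase_degree() == base.kinase_degree()

    def test_seed_determinism(self):
        base = self.base()
        assert randomize_network(base, 5).kinase_sets \
            == randomize_network(base, 5).kinase_sets
        assert randomize_network(base, 5).kinase_sets \
            != randomize_network(base, 6).kinase_sets

    def test_swap_method_preserves_both_degree_sequences(self):
        base = self.base()
        rand = randomize_network(base, 2, method="swap")
        assert rand.kinase_degree() == base.kinase_degree()
        assert rand.substrate_degree() == base.substrate_degree()
        assert rand.edges() != base.edges()

    def test_randomized_rank_cdf_tracks_random_expectation(self):
        # over 100 replicate pairs of independently randomized networks the
        # mean self-match rank CDF follows the k / N_B line
        # kinase degrees heterogeneous and independent between the two
        # networks (as observed between real algorithms): candidate columns
        # are then exchangeable and self-match ranks are uniform
        rng = np.random.default_rng(0)
        universe = [str(i) for i in range(1000)]
        sizes_a = rng.integers(80, 200, size=9)
        sizes_b = rng.integers(80, 200, size=9)
        a = net({f"k{i}": set(rng.choice(universe, size=s, replace=False))
                 for i, s in enumerate(sizes_a)})
        b = net({f"k{i}": set(rng.choice(universe, size=s, replace=False))
                 for i, s in enumerate(sizes_b)}, algo="b")
        N = 9
        total = np.zeros(N)
        for i in range(100):
            ra = randomize_network(a, [1000, i])
            rb = randomize_network(b, [2000, i])
            c = rank_cdf(between_matrix(ra, rb), N)
            total += [c.cdf(k) for k in range(1, N + 1)]
        mean = total / 100
        expect = np.arange(1, N + 1) / N
        assert np.max(np.abs(mean - expect)) <= 0.05


class TestPlantedRecovery:
    @pytest.mark.parametrize("jstar", [0.2, 0.5, 0.8])
    def test_planted_jaccard_recovered(self, jstar):
        from kinunify.pipeline import run_all
        from kinunify.simulate import (
            FixtureSpec, generate_predictions, generate_reference,
        )
        from kinunify.stringency import builtin_schemes

        spec = FixtureSpec(seed=5, n_proteins=60,
                           planted_jaccard=(("CDK1", "CK2A1", jstar),),
                           planted_union=200)
        ref = generate_reference(spec)
        preds = generate_predictions(spec, ref)
        results = run_all(preds.raw, ref.proteome, ref.phospho,
                          ref.kinase_map, builtin_schemes(preds.gps_cutoffs))
        for res in results.values():
            nlow = res.networks["low"]
            j = jaccard(nlow.kinase_sets["CDK1"], nlow.kinase_sets["CK2A1"])
            assert j == pytest.approx(jstar, abs=0.05)
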