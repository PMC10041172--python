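"""Similarity counts, the partial triplet oracle, threshold splitting, and
Aho supertree assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from castree.bounds import BoundQuery, k_conditions_i_ii
from castree.evaluation import exact_reconstruction
from castree.model import LineageParams, delta_star
from castree.simulate import overlay_mutations, simulate_experiment, TopologyConfig
from castree.topdown import (
    OracleConfig,
    OracleReconstructor,
    ThresholdReconstructor,
    aho_supertree,
    oracle_reconstruct,
    oracle_threshold,
    partial_oracle,
    similarity,
    similarity_matrix,
    threshold_split_reconstruct,
    triplet_similarity_missing,
)

from conftest import all_triplets, random_binary_tree, triplet_tree


class TestSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 0, 3], [1, 0, 5, 3], 2),
        ([0, 0, 0], [0, 0, 0], 0),
        ([1, 2, 3], [1, 2, 3], 3),
        ([-1, 2, -1], [-1, 2, 5], 1),   # shared missingness never counts
    ])
    def test_examples(self, a, b, expected):
        assert similarity(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            similarity([1, 2], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(hnp.arrays(np.int64, (2, 20), elements=st.integers(-1, 4)))
    def test_symmetry_and_bounds(self, pair):
        a, b = pair
        s = similarity(a, b)
        assert s == similarity(b, a)
        assert 0 <= s <= 20
        assert similarity(a, a) == int(np.sum(a > 0))

    def test_matrix_matches_pairwise(self, rng):
        X = rng.integers(-1, 5, size=(12, 30))
        S = similarity_matrix(X)
        for i, j in itertools.combinations(range(12), 2):
            assert S[i, j] == similarity(X[i], X[j])
        assert np.array_equal(S, S.T)


class TestTripletSimilarityMissing:
    def test_reduces_to_plain_without_missing(self, rng):
        X = rng.integers(0, 5, size=(3, 40))
        s_ab, s_ac, s_bc = triplet_similarity_missing(*X)
        assert (s_ab, s_ac, s_bc) == (similarity(X[0], X[1]),
                                      similarity(X[0], X[2]),
                                      similarity(X[1], X[2]))

    def test_dropout_in_third_excludes_from_pair(self):
        a = np.array([1, 2, 3])
        b = np.array([1, 2, 3])
        c = np.array([-1, 2, 3])
        s_ab, _, _ = triplet_similarity_missing(a, b, c)
        assert s_ab == 2  # character 0 is missing in c, so excluded from all

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(hnp.arrays(np.int64, (3, 50), elements=st.integers(-1, 3)))
    def test_matches_per_character_recount(self, X):
        a, b, c = X
        got = triplet_similarity_missing(a, b, c)
        expected = [0, 0, 0]
        for i in range(50):
            if a[i] < 0 or b[i] < 0 or c[i] < 0:
                continue
            expected[0] += int(a[i] == b[i] > 0)
            expected[1] += int(a[i] == c[i] > 0)
            expected[2] += int(b[i] == c[i] > 0)
        assert list(got) == expected
        # symmetric under relabeling
        s_ba = triplet_similarity_missing(b, a, c)
        assert s_ba[0] == got[0]


class TestPartialOracle:
    params = LineageParams.uniform(k=40, lam=1.0, q=0.1)
    cfg = OracleConfig(l_star=0.1, d_star=1.0)

    def test_threshold_formula(self):
        t = oracle_threshold(40, 1.0, 0.1, self.cfg)
        assert t == pytest.approx(0.5 * 40 * 1.0 * 0.1 *
                                  delta_star(1.0, 1.0, 0.1))
        cfg_md = OracleConfig(l_star=0.1, missing_mode="worst_case", p_d=0.2)
        t_md = oracle_threshold(40, 1.0, 0.1, cfg_md)
        assert t_md == pytest.approx(t * 0.8**3)

    def test_extreme_margin_returns_outgroup(self):
        a = np.array([1] * 30 + [0] * 10)
        b = a.copy()
        c = np.zeros(40, dtype=int)
        assert partial_oracle(a, b, c, self.cfg, self.params) == 2
        assert partial_oracle(c, a, b, self.cfg, self.params) == 0

    def test_identical_vectors_abstain(self):
        a = np.array([1, 2, 3, 0] * 10)
        assert partial_oracle(a, a, a, self.cfg, self.params) is None

    def test_lam_lstar_warning(self):
        with pytest.warns(UserWarning):
            oracle_threshold(40, 30.0, 0.1, OracleConfig(l_star=0.5))

    def test_guarantee_at_lemma_bound(self):
        # triplets with alpha >= l*, depth <= d* and k at the sufficient
        # bound must be resolved correctly in >= 1 - zeta of trials
        lam, q, l_star, d_star, zeta = 1.0, 0.1, 0.2, 0.5, 0.1
        query = BoundQuery(n=3, zeta=zeta, lam=lam, collision_q=q,
                           l_star=l_star, d_star=d_star)
        k = int(np.ceil(k_conditions_i_ii(query)))
        trials = 500
        tree = triplet_tree(d=0.3, l_prime=0.25)   # depth 0.3, alpha 0.25
        big = LineageParams.uniform(k=k * trials, lam=lam, q=q)
        mt = overlay_mutations(tree, big, np.random.default_rng(42))
        A, B, C = (mt.states(x).reshape(trials, k) for x in "abc")
        cfg = OracleConfig(l_star=l_star, d_star=d_star, zeta=zeta)
        per_trial = LineageParams.uniform(k=k, lam=lam, q=q)
        correct = sum(
            partial_oracle(A[i], B[i], C[i], cfg, per_trial) == 2
            for i in range(trials))
        # binomial slack: 3 sigma below 1 - zeta at 500 trials
        assert correct >= trials * (1 - zeta) - 3 * np.sqrt(
            trials * zeta * (1 - zeta))

    def test_one_sidedness_on_unseparated_triplets(self):
        # alpha = 0 (star geometry): any non-Null answer is wrong; the rate
        # of wrong answers must stay within the failure budget
        lam, q, l_star, d_star, zeta = 1.0, 0.1, 0.2, 0.5, 0.1
        query = BoundQuery(n=3, zeta=zeta, lam=lam, collision_q=q,
                           l_star=l_star, d_star=d_star)
        k = int(np.ceil(k_conditions_i_ii(query)))
        trials = 500
        tree = triplet_tree(d=0.3, l_prime=0.0)
        big = LineageParams.uniform(k=k * trials, lam=lam, q=q)
        mt = overlay_mutations(tree, big, np.random.default_rng(43))
        A, B, C = (mt.states(x).reshape(trials, k) for x in "abc")
        cfg = OracleConfig(l_star=l_star, d_star=d_star, zeta=zeta)
        per_trial = LineageParams.uniform(k=k, lam=lam, q=q)
        wrong = sum(
            partial_oracle(A[i], B[i], C[i], cfg, per_trial) is not None
            for i in range(trials))
        assert wrong <= trials * zeta + 3 * np.sqrt(trials * zeta * (1 - zeta))


class TestThresholdSplit:
    def test_two_cherries_with_private_mutations(self):
        # clade-private shared mutations, no homoplasy
        X = np.array([
            [1, 1, 0, 0, 2],
            [1, 1, 0, 0, 3],
            [0, 0, 1, 1, 4],
            [0, 0, 1, 1, 5],
        ])
        tree = threshold_split_reconstruct(X, leaf_names=list("abcd"))
        assert tree.lca("a", "b") != tree.root
        assert tree.lca("c", "d") != tree.root
        assert tree.lca("a", "c") == tree.root

    def test_single_cell(self):
        tree = threshold_split_reconstruct(np.array([[1, 2, 0]]))
        assert tree.n_leaves == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_split_reconstruct(np.zeros((0, 5), dtype=int))

    def test_all_identical_cells_give_star(self):
        X = np.tile([1, 2, 3], (5, 1))
        tree = threshold_split_reconstruct(X)
        assert tree.graph.out_degree(tree.root) == 5

    def test_deterministic(self, rng):
        X = rng.integers(0, 4, size=(20, 60))
        t1 = threshold_split_reconstruct(X)
        t2 = threshold_split_reconstruct(X)
        assert t1.to_newick() == t2.to_newick()


class TestAhoSupertree:
    def test_four_leaf_balanced(self):
        R = [("a", "b", "c"), ("a", "b", "d"), ("c", "d", "a"),
             ("c", "d", "b")]
        tree = aho_supertree(R, "abcd")
        assert tree.lca("a", "b") != tree.root
        assert tree.lca("c", "d") != tree.root
        assert tree.lca("a", "d") == tree.root

    def test_no_constraints_gives_star(self):
        tree = aho_supertree([], "abc")
        assert tree.graph.out_degree(tree.root) == 3

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            aho_supertree([("a", "b", "z")], "abc")

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (10, 2), (12, 3)])
    def test_round_trip_recovers_tree(self, n, seed):
        true = random_binary_tree(n, np.random.default_rng(seed))
        rebuilt = aho_supertree(all_triplets(true), true.leaves)
        assert exact_reconstruction(true, rebuilt, depth_limit=np.inf)


class TestOracleReconstruct:
    def test_small_simulated_exact(self):
        params = LineageParams.uniform(k=1024, lam=1.0, q=0.01)
        cfg = TopologyConfig(regime="uniform", n_target=16)
        true, X = simulate_experiment(params, cfg, np.random.default_rng(0))
        ocfg = OracleConfig(l_star=1.0 / 5, d_star=1.0)
        rec = oracle_reconstruct(X, ocfg, params)
        assert exact_reconstruction(true, rec)

    def test_missing_data_mode_still_reconstructs(self):
        params = LineageParams.uniform(k=2048, lam=1.0, q=0.01, p_d=0.2)
        cfg = TopologyConfig(regime="uniform", n_target=16)
        true, X = simulate_experiment(params, cfg, np.random.default_rng(1))
        ocfg = OracleConfig(l_star=1.0 / 5, d_star=1.0,
                            missing_mode="worst_case", p_d=0.2)
        rec = oracle_reconstruct(X, ocfg, params)
        assert exact_reconstruction(true, rec)


class TestEstimators:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = OracleReconstructor(lam=2.0, q=0.05, l_star=0.1)
        assert est.get_params()["lam"] == 2.0
        est2 = clone(est).set_params(d_star=0.5)
        assert est2.get_params()["d_star"] == 0.5

    def test_fit_produces_tree(self):
        params = LineageParams.uniform(k=512, lam=1.0, q=0.01)
        cfg = TopologyConfig(regime="uniform", n_target=8)
        true, X = simulate_experiment(params, cfg, np.random.default_rng(2))
        for est in (ThresholdReconstructor(),
                    OracleReconstructor(lam=1.0, q=0.01, l_star=0.25)):
            est.fit(X)
            assert sorted(est.leaf_names_) == true.leaves
            assert exact_reconstruction(true, est.tree_)
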