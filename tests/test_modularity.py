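import networkx as nx
import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from seedgraph.network import SignedAdjacency, threshold_graph
from seedgraph.modularity import (
    ConsensusResult,
    Partition,
    SignedLouvain,
    canonicalize,
    consensus_partition,
    first_level_split,
    flag_unassigned,
    louvain_signed,
    modularity_significance,
    null_model,
    participation_coefficient,
    q_star,
    within_module_zscore,
)

from _oracles import q_star_direct


def _adj(W):
    W = np.asarray(W, float)
    return SignedAdjacency(W, [f"n{i}" for i in range(W.shape[0])])


def _two_cliques(k=3):
    n = 2 * k
    W = np.zeros((n, n))
    W[:k, :k] = 1.0
    W[k:, k:] = 1.0
    np.fill_diagonal(W, 0.0)
    return W


def _planted_signed(rng=None, noise=0.0):
    # 8 nodes: modules {0..2}, {3..5} positive, {6,7} anticorrelated
    W = np.full((8, 8), 0.1)
    W[:3, :3] = 0.5
    W[3:6, 3:6] = 0.5
    W[6:, 6:] = 0.5
    W[:6, 6:] = -0.3
    W[6:, :6] = -0.3
    if noise and rng is not None:
        J = rng.normal(0, noise, (8, 8))
        W = W + 0.5 * (J + J.T)
    np.fill_diagonal(W, 0.0)
    return W


class TestQStar:
    def test_two_disconnected_cliques_score_half(self):
        W = _two_cliques()
        assert q_star(W, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_single_module_scores_zero_on_positive_network(self):
        W = _two_cliques()
        assert q_star(W, [0] * 6) == pytest.approx(0.0)

    def test_negative_between_module_edge_raises_q_star(self):
        W = _two_cliques()
        labels = [0, 0, 0, 1, 1, 1]
        before = q_star(W, labels)
        W2 = W.copy()
        W2[0, 3] = W2[3, 0] = -0.5
        after = q_star(W2, labels)
        assert after > before
        # both agree with the literal formula oracle
        assert after == pytest.approx(q_star_direct(W2, np.array(labels)))

    def test_matches_formula_oracle_on_random_signed_input(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            W = rng.normal(0, 0.4, (n, n))
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 0)
            labels = rng.integers(0, 3, n)
            assert q_star(W, labels) == pytest.approx(
                q_star_direct(W, labels), abs=1e-12
            )

    def test_reduces_to_newman_girvan_modularity_without_negatives(self, rng):
        for seed in range(10):
            g = nx.gnm_random_graph(10, 20, seed=seed)
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            W = nx.to_numpy_array(g)
            labels = rng.integers(0, 3, 10)
            communities = [
                {i for i in range(10) if labels[i] == m}
                for m in np.unique(labels)
            ]
            expected = nx.community.modularity(g, communities, weight="weight")
            assert q_star(W, labels) == pytest.approx(expected, abs=1e-12)

    def test_bounds_hold_under_fuzzing(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 10))
            W = rng.normal(0, 1.0, (n, n))
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 0)
            if np.abs(W).sum() == 0:
                continue
            labels = rng.integers(0, n, n)
            assert -1.0 - 1e-9 <= q_star(W, labels) <= 1.0 + 1e-9

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            q_star(np.zeros((3, 3)), [0, 1, 2])


class TestLouvain:
    def test_recovers_disconnected_cliques_exactly(self):
        part = louvain_signed(_two_cliques(), seed=5)
        assert part.q_star == pytest.approx(0.5)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], part.labels) == 1.0

    def test_planted_signed_structure_beats_planted_labels(self):
        W = _planted_signed()
        part = louvain_signed(W, seed=0)
        planted = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        assert part.q_star >= q_star(W, planted) - 1e-9
        # and any merge or split of the planted labels
        for alt in ([0, 0, 0, 0, 0, 0, 1, 1], [0, 0, 1, 1, 2, 2, 3, 3],
                    [0, 0, 0, 1, 1, 1, 2, 3]):
            assert part.q_star >= q_star(W, alt) - 1e-9

    def test_single_node_is_one_trivial_module(self):
        part = louvain_signed(np.zeros((1, 1)), seed=0)
        assert part.labels.tolist() == [0]
        assert part.q_star == 0.0

    def test_labels_are_canonical(self, rng):
        W = _planted_signed(rng, noise=0.05)
        part = louvain_signed(W, seed=3)
        np.testing.assert_array_equal(part.labels, canonicalize(part.labels))


class TestConsensus:
    def test_unambiguous_network_gives_unanimous_mode(self):
        result = consensus_partition(_two_cliques(), n_runs=100, seed=0)
        assert result.frequency_of_chosen() == 100
        assert result.chosen.q_star == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(result.agreement_matrix), 1.0)

    def test_single_run_consensus_is_that_run(self):
        result = consensus_partition(_two_cliques(), n_runs=1, seed=4)
        assert result.runs == 1
        assert sum(result.partition_frequencies.values()) == 1

    def test_reproducible_across_invocations(self, rng):
        W = _planted_signed(rng, noise=0.1)
        a = consensus_partition(W, n_runs=50, seed=11)
        b = consensus_partition(W, n_runs=50, seed=11)
        np.testing.assert_array_equal(a.chosen.labels, b.chosen.labels)
        assert a.partition_frequencies == b.partition_frequencies

    def test_frequencies_sum_to_runs(self, rng):
        W = _planted_signed(rng, noise=0.2)
        result = consensus_partition(W, n_runs=30, seed=2)
        assert sum(result.partition_frequencies.values()) == 30

    def test_hierarchy_hook_partitions_only_the_submatrix(self):
        W = _planted_signed()
        part = consensus_partition(W, n_runs=20, seed=0).chosen
        module0 = np.where(part.labels == part.labels[0])[0]
        sub = W[np.ix_(module0, module0)]
        sub_part = consensus_partition(sub, n_runs=20, seed=1).chosen
        assert sub_part.labels.size == module0.size


class TestSignedLouvainEstimator:
    def test_fit_sets_sklearn_attributes(self):
        est = SignedLouvain(n_runs=20, random_state=0)
        labels = est.fit_predict(_two_cliques())
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], labels) == 1.0
        assert est.q_star_ == pytest.approx(0.5)
        assert isinstance(est.consensus_, ConsensusResult)

    def test_clone_preserves_params(self):
        est = clone(SignedLouvain(n_runs=7, random_state=3))
        assert est.get_params() == {"n_runs": 7, "random_state": 3}


class TestNodeRoles:
    def test_participation_examples(self):
        # all edges internal -> 0
        g = threshold_graph(_adj(_two_cliques()), 0.5)
        P = participation_coefficient(g, [0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(P, 0.0)

    def test_participation_split_between_two_modules(self):
        W = np.zeros((5, 5))
        # node 0: one edge into module of 1,2 and one into module of 3,4
        W[0, 1] = W[1, 0] = 1.0
        W[0, 3] = W[3, 0] = 1.0
        g = threshold_graph(_adj(W), 0.5)
        P = participation_coefficient(g, [0, 1, 1, 2, 2])
        assert P[0] == pytest.approx(0.5)

    def test_participation_2_1_1_over_three_modules(self):
        W = np.zeros((6, 6))
        for j in (1, 2, 3, 4):
            W[0, j] = W[j, 0] = 1.0
        g = threshold_graph(_adj(W), 0.5)
        labels = [0, 0, 0, 1, 2, 2]  # edges from 0: two into m0, one m1, one m2
        P = participation_coefficient(g, labels)
        assert P[0] == pytest.approx(1 - (4 + 1 + 1) / 16)

    def test_isolated_node_has_zero_participation(self):
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 1.0
        g = threshold_graph(_adj(W), 0.5)
        P = participation_coefficient(g, [0, 0, 0])
        assert P[0] == 0.0

    def test_within_z_clique_is_degenerate_zero(self):
        g = threshold_graph(_adj(_two_cliques()), 0.5)
        z, flags = within_module_zscore(g, [0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(z, 0.0)
        assert flags.all()

    def test_within_z_star_center_is_module_maximum(self):
        W = np.zeros((5, 5))
        for j in range(1, 5):
            W[0, j] = W[j, 0] = 1.0
        g = threshold_graph(_adj(W), 0.5)
        z, flags = within_module_zscore(g, [0, 0, 0, 0, 0])
        assert z[0] == z.max() and z[0] > 0
        assert not flags.any()
        assert abs(z.mean()) < 1e-12

    def test_within_z_relabelling_equivariance(self, rng):
        W = _planted_signed(rng, noise=0.1)
        Wp = np.where(W > 0, W, 0.0)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        perm = rng.permutation(8)
        z1, _ = within_module_zscore(Wp, labels)
        z2, _ = within_module_zscore(Wp[np.ix_(perm, perm)], labels[perm])
        np.testing.assert_allclose(z2, z1[perm])


class TestNullModel:
    def test_preserves_signed_degree_sequences_and_weight_multiset(self, rng):
        W = _planted_signed(rng, noise=0.15)
        adj = _adj(W)
        nm = null_model(adj, seed=3)
        for sign in (1, -1):
            d0 = ((sign * W) > 0).sum(axis=1)
            d1 = ((sign * nm.weights) > 0).sum(axis=1)
            np.testing.assert_array_equal(d0, d1)
            w0 = np.sort(sign * W[np.triu(sign * W > 0, k=1)])
            w1 = np.sort(sign * nm.weights[np.triu(sign * nm.weights > 0, k=1)])
            np.testing.assert_allclose(w0, w1)

    def test_rank_assignment_also_preserves_invariants(self, rng):
        W = _planted_signed(rng, noise=0.15)
        nm = null_model(_adj(W), seed=3, weight_assignment="rank")
        np.testing.assert_allclose(np.sort(nm.weights.ravel()),
                                   np.sort(W.ravel()))

    def test_destroys_planted_community_structure(self, adjacency):
        emp = consensus_partition(adjacency.weights, n_runs=20, seed=0).chosen
        nulls = [
            consensus_partition(
                null_model(adjacency, seed=b).weights, n_runs=20, seed=100 + b
            ).chosen.q_star
            for b in range(20)
        ]
        assert np.mean(nulls) < emp.q_star


class TestSignificance:
    def test_degenerate_null_distribution_is_flagged(self):
        # two disjoint positive edges with equal weights: rewiring can
        # only reproduce the same weighted topology up to relabelling
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.5
        ens = modularity_significance(_adj(W), n_null=20, n_boot=100, seed=0,
                                      n_runs=5)
        assert ens.degenerate
        assert np.isnan(ens.p_parametric)
        assert 0 <= ens.p_quantile <= 1

    def test_parameter_contracts(self, adjacency):
        with pytest.raises(ValueError, match="n_null"):
            modularity_significance(adjacency, n_null=5)
        with pytest.raises(ValueError, match="n_boot"):
            modularity_significance(adjacency, n_null=20, n_boot=10)


class TestFirstLevel:
    def test_positive_only_adjacency_is_flagged(self):
        res = first_level_split(_adj(_two_cliques()), [1, 1, 1, -1, -1, -1],
                                n_runs=10, seed=0)
        assert "no_negative_weights" in res.flags

    def test_uniform_sign_labels_are_flagged(self, rng):
        W = _planted_signed(rng, noise=0.05)
        res = first_level_split(_adj(W), [1] * 8, n_runs=10, seed=0)
        assert "sign_labels_degenerate" in res.flags

    def test_no_module_mixes_signs_on_planted_input(self, rng):
        # on a small matrix the Q*-optimal partition may refine the sign
        # split into sub-modules, but it must never place positive and
        # anticorrelated nodes in the same module
        W = _planted_signed(rng, noise=0.05)
        sign = np.array([1, 1, 1, 1, 1, 1, -1, -1])
        res = first_level_split(_adj(W), sign, n_runs=20, seed=0)
        for m in np.unique(res.consensus.chosen.labels):
            members = res.consensus.chosen.labels == m
            assert len(np.unique(sign[members])) == 1
        assert -1.0 <= res.ari_vs_sign <= 1.0


def test_flag_unassigned_marks_singleton_modules():
    labels = np.array([0, 0, 1])
    agreement = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
    result = ConsensusResult(
        10, {tuple(labels): 10}, Partition(labels, 0.3), agreement
    )
    np.testing.assert_array_equal(flag_unassigned(result), [False, False, True])


def test_flag_unassigned_marks_low_agreement_members():
    labels = np.array([0, 0, 0, 1, 1])
    agreement = np.eye(5)
    agreement[0, 1] = agreement[1, 0] = 0.9
    agreement[3, 4] = agreement[4, 3] = 0.8
    result = ConsensusResult(
        10, {tuple(labels): 10}, Partition(labels, 0.3), agreement
    )
    flags = flag_unassigned(result)
    # node 2 agrees with nobody in its module
    np.testing.assert_array_equal(flags, [False, False, True, False, False])
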