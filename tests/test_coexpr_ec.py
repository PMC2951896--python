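import numpy as np
import pytest

import xspec_ec as x
from xspec_ec.data_io import ValidationError
from xspec_ec.coexpr_ec import UndefinedCorrelationError

import _oracles as oracle


def random_pcm_pair(seed, k=6, t=5):
    """PCMs from a small simulated instance (valid, generically non-degenerate)."""
    cfg = x.SimulationConfig(k=k, t_A=t, t_B=t, n_common=min(3, t), m=2, seed=seed)
    paired, _ = x.simulate_paired_expression(cfg)
    return (
        x.pairwise_correlation_matrix(paired.matrix_A),
        x.pairwise_correlation_matrix(paired.matrix_B),
    )


class TestPairwiseCorrelationMatrix:
    def test_affine_dependence_gives_one(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 50, 5)
        M = x.ExpressionMatrix(
            ["g1", "g2", "g3"],
            [f"t{j}" for j in range(5)],
            np.vstack([base, 2 * base + 5, rng.uniform(1, 50, 5)]),
        )
        pcm = x.pairwise_correlation_matrix(M)
        np.testing.assert_allclose(pcm.values[0, 1], 1.0, atol=1e-12)

    def test_anticorrelated_rows_give_minus_one(self):
        base = np.array([1.0, 4.0, 2.0, 8.0])
        M = x.ExpressionMatrix(
            ["g1", "g2"], ["t1", "t2", "t3", "t4"], np.vstack([base, 10.0 - base])
        )
        pcm = x.pairwise_correlation_matrix(M)
        np.testing.assert_allclose(pcm.values[0, 1], -1.0, atol=1e-12)

    def test_matches_oracle_on_random_matrix(self):
        rng = np.random.default_rng(7)
        V = rng.uniform(1, 100, (6, 5))
        M = x.ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"t{j}" for j in range(5)], V
        )
        pcm = x.pairwise_correlation_matrix(M)
        expected = oracle.pcm([list(row) for row in V])
        np.testing.assert_allclose(pcm.values, expected, atol=1e-10)
        assert np.array_equal(pcm.values, pcm.values.T)
        np.testing.assert_allclose(np.diag(pcm.values), 1.0)

    def test_constant_row_names_offender(self):
        M = x.ExpressionMatrix(
            ["g1", "gBAD"], ["t1", "t2", "t3"], np.array([[1.0, 2, 3], [5.0, 5, 5]])
        )
        with pytest.raises(ValidationError, match="gBAD"):
            x.pairwise_correlation_matrix(M)


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_plain_pearson(self):
        rng = np.random.default_rng(1)
        xv, yv = rng.normal(size=10), rng.normal(size=10)
        plain = oracle.pearson(list(xv), list(yv))
        assert abs(x.weighted_pearson(xv, yv, np.ones(10)) - plain) <= 1e-12
        assert abs(x.weighted_pearson(xv, yv, np.full(10, 0.37)) - plain) <= 1e-12

    def test_two_point_support_is_plus_minus_one(self):
        xv = np.array([0.0, 1.0, 5.0, 2.0])
        w = np.array([1.0, 1.0, 0.0, 0.0])
        assert x.weighted_pearson(xv, np.array([3.0, 7.0, 0.0, 9.0]), w) == 1.0
        assert x.weighted_pearson(xv, np.array([7.0, 3.0, 0.0, 9.0]), w) == -1.0

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            xv = rng.normal(size=10)
            yv = rng.normal(size=10)
            w = rng.uniform(0.1, 2.0, size=10)
            expected = oracle.weighted_pearson(list(xv), list(yv), list(w))
            assert abs(x.weighted_pearson(xv, yv, w) - expected) < 1e-12

    def test_zero_weighted_variance_signalled(self):
        with pytest.raises(UndefinedCorrelationError):
            x.weighted_pearson(
                np.array([3.0, 3.0, 3.0, 9.0]),
                np.array([1.0, 2.0, 3.0, 4.0]),
                np.array([1.0, 1.0, 1.0, 0.0]),
            )


class TestDutilhEC:
    def test_identical_pcms_give_one(self):
        pcm_A, _ = random_pcm_pair(3, k=8)
        res = x.dutilh_ec(pcm_A, pcm_A)
        assert res.valid.all()
        np.testing.assert_allclose(res.ec, 1.0, atol=1e-12)

    def test_matches_off_diagonal_row_oracle(self):
        pcm_A, pcm_B = random_pcm_pair(4, k=4)
        res = x.dutilh_ec(pcm_A, pcm_B)
        for i in range(4):
            refs = [j for j in range(4) if j != i]
            expected = oracle.row_ec(pcm_A.values[i], pcm_B.values[i], refs)
            np.testing.assert_allclose(res.ec[i], expected, atol=1e-10)

    def test_jointly_permuted_pcm_null_is_centred(self):
        # relabeling the reference genes consistently in B only: EC ~ 0 on average
        cfg = x.SimulationConfig(k=200, seed=11)
        paired, _ = x.simulate_paired_expression(cfg)
        pcm_A = x.pairwise_correlation_matrix(paired.matrix_A)
        pcm_B = x.pairwise_correlation_matrix(paired.matrix_B)
        rng = np.random.default_rng(99)
        perm = rng.permutation(200)
        shuffled = x.PCM(pcm_B.values[np.ix_(perm, perm)], params={})
        res = x.dutilh_ec(pcm_A, shuffled)
        v = res.valid_ec()
        se = v.std(ddof=1) / np.sqrt(v.size)
        assert abs(v.mean()) < 3 * se

    def test_species_symmetry(self):
        pcm_A, pcm_B = random_pcm_pair(5, k=10)
        fwd = x.dutilh_ec(pcm_A, pcm_B)
        rev = x.dutilh_ec(pcm_B, pcm_A)
        np.testing.assert_allclose(fwd.ec, rev.ec, atol=1e-12)

    def test_k_mismatch_rejected(self):
        pcm_A, _ = random_pcm_pair(6, k=5)
        pcm_B, _ = random_pcm_pair(6, k=6)
        with pytest.raises(ValidationError, match="dimensions differ"):
            x.dutilh_ec(pcm_A, pcm_B)


class TestEssienEC:
    def test_full_node_set_equals_dutilh_exactly(self):
        pcm_A, pcm_B = random_pcm_pair(8, k=12)
        full = x.essien_ec(pcm_A, pcm_B, set(range(12)))
        base = x.dutilh_ec(pcm_A, pcm_B)
        assert np.array_equal(full.ec, base.ec, equal_nan=True)
        assert np.array_equal(full.valid, base.valid)

    def test_three_external_nodes_boundary(self):
        pcm_A, pcm_B = random_pcm_pair(9, k=8)
        nodes = {0, 1, 2, 3}
        res = x.essien_ec(pcm_A, pcm_B, nodes)
        # for i = 7 (not a node) the reference has exactly 4 positions
        expected = oracle.row_ec(pcm_A.values[7], pcm_B.values[7], sorted(nodes))
        np.testing.assert_allclose(res.ec[7], expected, atol=1e-10)
        # for i = 2 (a node) self is excluded: 3 positions
        expected2 = oracle.row_ec(pcm_A.values[2], pcm_B.values[2], [0, 1, 3])
        np.testing.assert_allclose(res.ec[2], expected2, atol=1e-10)

    def test_restricted_positions_match_oracle(self):
        pcm_A, pcm_B = random_pcm_pair(10, k=6)
        nodes = {0, 1, 3, 5}
        res = x.essien_ec(pcm_A, pcm_B, nodes)
        for i in range(6):
            refs = sorted(nodes - {i})
            expected = oracle.row_ec(pcm_A.values[i], pcm_B.values[i], refs)
            np.testing.assert_allclose(res.ec[i], expected, atol=1e-10)

    def test_too_small_reference_set_rejected(self):
        pcm_A, pcm_B = random_pcm_pair(11, k=6)
        with pytest.raises(ValidationError, match="reference set too small"):
            x.essien_ec(pcm_A, pcm_B, {0, 1, 2})


class TestICC:
    def test_identical_pcms_fixed_point(self):
        pcm_A, _ = random_pcm_pair(12, k=8)
        res, history = x.icc(pcm_A, pcm_A)
        np.testing.assert_allclose(history[0].ec_current, 1.0, atol=1e-12)
        assert res.params["converged"] and res.params["iterations"] == 1
        assert history[-1].max_delta == 0.0

    def test_iteration_zero_equals_dutilh_exactly(self):
        pcm_A, pcm_B = random_pcm_pair(13, k=10)
        _, history = x.icc(pcm_A, pcm_B)
        base = x.dutilh_ec(pcm_A, pcm_B)
        assert np.array_equal(history[0].ec_current, base.ec, equal_nan=True)

    def test_weighted_iteration_matches_oracle(self):
        pcm_A, pcm_B = random_pcm_pair(14, k=7)
        res, history = x.icc(pcm_A, pcm_B, max_iter=1)
        w = history[1].weights
        for i in range(7):
            refs = [j for j in range(7) if j != i and w[j] > 0]
            expected = oracle.weighted_pearson(
                [pcm_A.values[i][j] for j in refs],
                [pcm_B.values[i][j] for j in refs],
                [w[j] for j in refs],
            )
            np.testing.assert_allclose(history[1].ec_current[i], expected, atol=1e-10)

    def test_converges_and_separates_classes_on_simulation(self):
        cfg = x.SimulationConfig(k=200, seed=21)
        paired, truth = x.simulate_paired_expression(cfg)
        pcm_A = x.pairwise_correlation_matrix(paired.matrix_A)
        pcm_B = x.pairwise_correlation_matrix(paired.matrix_B)
        res, history = x.icc(pcm_A, pcm_B)
        assert res.params["converged"]
        assert history[-1].max_delta < 1e-3
        v = res.valid & np.isfinite(res.ec)
        mean_cons = res.ec[v & truth.conserved].mean()
        mean_div = res.ec[v & ~truth.conserved].mean()
        assert mean_cons > mean_div

    def test_species_symmetry(self):
        pcm_A, pcm_B = random_pcm_pair(15, k=10)
        fwd, _ = x.icc(pcm_A, pcm_B)
        rev, _ = x.icc(pcm_B, pcm_A)
        np.testing.assert_allclose(fwd.ec, rev.ec, atol=1e-12)


class TestCoexprDistance:
    def test_identical_pcms_give_zero(self):
        pcm_A, _ = random_pcm_pair(16, k=6)
        res = x.coexpr_distance(pcm_A, pcm_A)
        np.testing.assert_allclose(res.distance, 0.0, atol=1e-12)

    def test_single_coordinate_difference(self):
        pcm_A, _ = random_pcm_pair(17, k=5)
        values = pcm_A.values.copy()
        values[0, 2] += 0.6 if values[0, 2] < 0.3 else -0.6
        pcm_B = x.PCM(values, symmetric=False)
        res = x.coexpr_distance(pcm_A, pcm_B)
        np.testing.assert_allclose(res.distance[0], 0.6, atol=1e-12)

    def test_matches_brute_force_sum(self):
        pcm_A, pcm_B = random_pcm_pair(18, k=6)
        res_all = x.coexpr_distance(pcm_A, pcm_B)
        nodes = {0, 2, 3, 5}
        res_nodes = x.coexpr_distance(pcm_A, pcm_B, nodes)
        for i in range(6):
            refs = [j for j in range(6) if j != i]
            np.testing.assert_allclose(
                res_all.distance[i],
                oracle.euclidean(pcm_A.values[i], pcm_B.values[i], refs),
                atol=1e-10,
            )
            refs_n = sorted(nodes - {i})
            np.testing.assert_allclose(
                res_nodes.distance[i],
                oracle.euclidean(pcm_A.values[i], pcm_B.values[i], refs_n),
                atol=1e-10,
            )
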