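import numpy as np
import pytest
from scipy.special import erf
from scipy.stats import ks_2samp

from kncfs import (
    LabeledDataset,
    correlation_matrix,
    minmax_normalize,
    partition_alpha,
    sample_correlated_threshold,
    select_features,
)
from kncfs.weighting import CorrelationMatrix, _cholesky_with_jitter
from conftest import random_labeled


class TestCorrelationMatrix:
    def test_single_feature(self, rng):
        ds = LabeledDataset(
            X=rng.standard_normal((5, 1)), y=np.arange(5) % 2
        )
        np.testing.assert_array_equal(correlation_matrix(ds).R, [[1.0]])

    def test_perfect_linear_dependence(self, rng):
        f = rng.standard_normal(20)
        ds = LabeledDataset(
            X=np.column_stack([f, 2.0 * f]), y=np.arange(20) % 2
        )
        R = correlation_matrix(ds).R
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementary_formula(self, rng):
        X = rng.standard_normal((15, 5))
        ds = LabeledDataset(X=X, y=np.arange(15) % 2)
        R = correlation_matrix(ds).R
        for i in range(5):
            for j in range(5):
                xi, xj = X[:, i], X[:, j]
                want = (
                    ((xi - xi.mean()) * (xj - xj.mean())).sum()
                    / (
                        np.sqrt(((xi - xi.mean()) ** 2).sum())
                        * np.sqrt(((xj - xj.mean()) ** 2).sum())
                    )
                )
                assert R[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_column_convention(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 5.0
        ds = LabeledDataset(X=X, y=np.arange(10) % 2)
        R = correlation_matrix(ds).R
        assert R[1, 1] == 1.0
        assert R[0, 1] == 0.0 and R[2, 1] == 0.0

    def test_symmetric_unit_diagonal_bounded(self, rng):
        ds = random_labeled(rng, n=12, d=6)
        R = correlation_matrix(ds).R
        np.testing.assert_array_equal(R, R.T)
        np.testing.assert_array_equal(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0)


class TestCholeskyJitter:
    def test_identity_needs_no_jitter(self):
        L, eps = _cholesky_with_jitter(np.eye(4))
        assert eps == 0.0
        np.testing.assert_allclose(L, np.eye(4))

    def test_singular_matrix_gets_jitter(self, rng):
        # rank-1 correlation matrix: singular, needs diagonal inflation
        f = rng.standard_normal(10)
        X = np.column_stack([f, f, f])
        ds = LabeledDataset(X=X, y=np.arange(10) % 2)
        R = correlation_matrix(ds)
        L, eps = _cholesky_with_jitter(R.R)
        assert 0 < eps <= 1e-2
        np.testing.assert_allclose(
            L @ L.T, R.R + eps * np.eye(3), atol=1e-10
        )

    def test_wide_matrix_factorizes(self, rng):
        # d > n: R is always singular on wide data
        ds = random_labeled(rng, n=8, d=30)
        R = correlation_matrix(ds)
        sample = sample_correlated_threshold(R, seed=0)
        assert sample.u.shape == (30,)
        assert R.jitter > 0


class TestThresholdSample:
    def test_u_from_v_zero_is_half(self):
        # erf(0) = 0 so a zero draw maps to threshold 0.5 exactly;
        # realized by a deterministic check of the transform itself
        assert 0.5 * (1.0 + erf(0.0)) == 0.5

    def test_u_strictly_inside_unit_interval(self, rng):
        ds = random_labeled(rng, n=20, d=10)
        R = correlation_matrix(ds)
        for seed in range(20):
            u = sample_correlated_threshold(R, seed=seed).u
            assert np.all(u > 0.0) and np.all(u < 1.0)

    def test_u_monotone_in_v(self, rng):
        s = sample_correlated_threshold(
            CorrelationMatrix(R=np.eye(50)), seed=1
        )
        order_v = np.argsort(s.v)
        order_u = np.argsort(s.u)
        np.testing.assert_array_equal(order_v, order_u)

    def test_identity_R_matches_erf_distribution(self):
        """10,000 draws with R = I pass a two-sample KS test against
        (1 + erf(Z))/2 with Z standard normal."""
        R = CorrelationMatrix(R=np.eye(100))
        rng = np.random.default_rng(42)
        draws = np.concatenate(
            [
                sample_correlated_threshold(R, seed=rng).u
                for _ in range(100)
            ]
        )
        ref = 0.5 * (1.0 + erf(np.random.default_rng(43).standard_normal(10_000)))
        assert ks_2samp(draws, ref).pvalue > 0.01

    def test_v_reproduces_correlation_structure(self):
        """Sample correlation of v over 10,000 draws reproduces R (plus
        jitter) within 0.05, including on a two-block structure."""
        block = np.array(
            [
                [1.0, 0.9, 0.0, 0.0],
                [0.9, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.9],
                [0.0, 0.0, 0.9, 1.0],
            ]
        )
        R = CorrelationMatrix(R=block)
        rng = np.random.default_rng(7)
        V = np.array(
            [
                sample_correlated_threshold(R, seed=rng).v
                for _ in range(10_000)
            ]
        )
        emp = np.corrcoef(V.T)
        assert np.max(np.abs(emp - block)) < 0.05

    def test_gauss_cdf_variant(self):
        from scipy.special import ndtr

        R = CorrelationMatrix(R=np.eye(5))
        s_erf = sample_correlated_threshold(R, seed=3, cdf="erf")
        s_gauss = sample_correlated_threshold(R, seed=3, cdf="gauss")
        np.testing.assert_array_equal(s_erf.v, s_gauss.v)
        np.testing.assert_allclose(s_gauss.u, ndtr(s_gauss.v))
        with pytest.raises(ValueError, match="cdf"):
            sample_correlated_threshold(R, seed=3, cdf="probit")


class TestMinmaxNormalize:
    def test_basic(self):
        np.testing.assert_allclose(
            minmax_normalize(np.array([1.0, 2.0, 3.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_vector_maps_to_half(self):
        np.testing.assert_array_equal(
            minmax_normalize(np.full(4, 9.0)), 0.5
        )

    def test_monotone_transform_preserves_order(self, rng):
        w = rng.standard_normal(20)
        np.testing.assert_array_equal(
            np.argsort(minmax_normalize(w)), np.argsort(w)
        )


class TestSelectFeatures:
    def test_strict_threshold(self):
        pi = np.array([0.9, 0.1])
        u = np.array([0.5, 0.5])
        assert select_features(pi, u).tolist() == [0]

    def test_equality_excluded(self, rng):
        pi = rng.uniform(size=6)
        assert select_features(pi, pi).size == 0

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            pi = rng.uniform(size=15)
            u = rng.uniform(size=15)
            want = [k for k in range(15) if pi[k] > u[k]]
            assert select_features(pi, u).tolist() == want


class TestPartitionAlpha:
    def test_empty_selection_scores_zero(self, small_dataset):
        score = partition_alpha(small_dataset, np.empty(0, dtype=int))
        assert score.alpha == 0.0

    def test_separable_feature_scores_high(self):
        """A single perfectly separating feature should give alpha >= 0.95
        in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 60
            y = np.arange(n) % 2
            X = g.standard_normal((n, 4)) * 0.1
            X[:, 0] += np.where(y == 0, -5.0, 5.0)
            ds = LabeledDataset(X=X, y=y)
            score = partition_alpha(ds, np.array([0]), seed=seed)
            hits += int(score.alpha >= 0.95)
        assert hits >= 9

    def test_permuted_labels_score_near_chance(self):
        """With labels shuffled, 3-NN accuracy hovers around 0.5 on
        balanced binary data."""
        alphas = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 80
            X = g.standard_normal((n, 6))
            y = g.permutation(np.arange(n) % 2)
            ds = LabeledDataset(X=X, y=y)
            alphas.append(
                partition_alpha(ds, np.arange(6), seed=seed).alpha
            )
        assert abs(np.mean(alphas) - 0.5) < 0.15

    def test_alpha_bounds(self, small_dataset, rng):
        for seed in range(5):
            sel = rng.choice(5, size=3, replace=False)
            a = partition_alpha(small_dataset, sel, seed=seed).alpha
            assert 0.0 <= a <= 1.0

    def test_resubstitution_protocol(self, separable_dataset):
        score = partition_alpha(
            separable_dataset, np.array([0]), protocol="resub"
        )
        assert score.alpha == 1.0

    def test_tiny_class_falls_back(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        y = np.array([0, 0, 0, 0, 1])  # one singleton class
        ds = LabeledDataset(X=X, y=y)
        a = partition_alpha(ds, np.arange(3), seed=0).alpha
        assert 0.0 <= a <= 1.0
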