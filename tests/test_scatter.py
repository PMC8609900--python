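import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepida.scatter import (between_scatter, class_means, cross_scatter,
                             inv_sqrt_psd, total_scatter, whiten_and_build,
                             within_scatter)


def balanced_labels(n_per_class, K):
    return np.repeat(np.arange(1, K + 1), n_per_class)


class TestClassMeans:
    def test_two_singleton_classes(self):
        H = np.array([[0.0, 0.0], [2.0, 2.0]])
        mu_k, mu = class_means(H, np.array([1, 2]))
        np.testing.assert_allclose(mu_k, [[0, 0], [2, 2]])
        np.testing.assert_allclose(mu, [1, 1])

    def test_balanced_equals_grand_mean(self, rng):
        H = rng.standard_normal((12, 3))
        _, mu = class_means(H, balanced_labels(4, 3))
        np.testing.assert_allclose(mu, H.mean(axis=0), atol=1e-12)

    def test_unbalanced_mean_of_class_means(self):
        # hand computation: classes {0,0} and {3} -> mu = (0 + 3)/2
        H = np.array([[0.0], [0.0], [3.0]])
        _, mu = class_means(H, np.array([1, 1, 2]))
        assert mu[0] == pytest.approx(1.5)
        assert mu[0] != pytest.approx(H.mean())


class TestBetweenScatter:
    def test_zero_when_means_equal(self, rng):
        block = rng.standard_normal((4, 3))
        H = np.vstack([block, block])
        S = between_scatter(H, balanced_labels(4, 2))
        np.testing.assert_allclose(S, 0, atol=1e-12)

    def test_hand_value_1d(self):
        # classes at 0 and 2: mu=1, S_b = (2*1 + 2*1)/3 = 4/3
        H = np.array([[0.0], [0.0], [2.0], [2.0]])
        S = between_scatter(H, np.array([1, 1, 2, 2]))
        assert S[0, 0] == pytest.approx(4.0 / 3.0)

    def test_rank_at_most_K_minus_1(self, rng):
        H = rng.standard_normal((30, 6))
        S = between_scatter(H, balanced_labels(10, 3))
        assert np.linalg.matrix_rank(S, tol=1e-10) <= 2


class TestTotalScatter:
    def test_zero_for_constant(self):
        H = np.full((6, 2), 3.14)
        np.testing.assert_allclose(total_scatter(H, balanced_labels(3, 2)), 0,
                                   atol=1e-12)

    def test_balanced_matches_sample_covariance(self, rng):
        H = rng.standard_normal((20, 4))
        S = total_scatter(H, balanced_labels(10, 2))
        np.testing.assert_allclose(S, np.cov(H.T), atol=1e-10)

    def test_unbalanced_hand_value(self):
        # mu = 1.5; deviations (-1.5,-1.5,1.5) -> 3*2.25/2 = 3.375
        H = np.array([[0.0], [0.0], [3.0]])
        S = total_scatter(H, np.array([1, 1, 2]))
        assert S[0, 0] == pytest.approx(3.375)


class TestWithinScatter:
    def test_zero_for_repeated_rows(self):
        H = np.array([[1.0, 2.0]] * 3 + [[0.0, 5.0]] * 3)
        np.testing.assert_allclose(within_scatter(H, balanced_labels(3, 2)), 0,
                                   atol=1e-12)

    def test_hand_value_single_class_pair(self):
        H = np.array([[0.0], [2.0]])
        # deviations +-1 from class mean 1, divisor n-1=1
        assert within_scatter(H, np.array([1, 1]))[0, 0] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_decomposition_balanced(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((18, 3))
        labels = balanced_labels(6, 3)
        S_t = total_scatter(H, labels)
        S_b = between_scatter(H, labels)
        S_w = within_scatter(H, labels)
        np.testing.assert_allclose(S_t, S_b + S_w, atol=1e-10)


class TestCrossScatter:
    def test_self_cross_equals_total(self, rng):
        H = rng.standard_normal((12, 3))
        labels = balanced_labels(6, 2)
        np.testing.assert_allclose(cross_scatter(H, H, labels),
                                   total_scatter(H, labels), atol=1e-12)

    def test_column_permutation_equivariance(self, rng):
        H = rng.standard_normal((12, 4))
        labels = balanced_labels(6, 2)
        perm = np.array([2, 0, 3, 1])
        S = cross_scatter(H, H[:, perm], labels)
        np.testing.assert_allclose(S, total_scatter(H, labels)[:, perm], atol=1e-12)

    def test_transpose_symmetry(self, rng):
        Hd = rng.standard_normal((10, 3))
        Hj = rng.standard_normal((10, 5))
        labels = balanced_labels(5, 2)
        np.testing.assert_allclose(cross_scatter(Hd, Hj, labels),
                                   cross_scatter(Hj, Hd, labels).T, atol=1e-12)

    def test_independent_views_shrink(self):
        rng = np.random.default_rng(7)
        n = 4000
        labels = balanced_labels(n // 2, 2)
        A = rng.standard_normal((n, 2))
        B = rng.standard_normal((n, 2))
        assert np.abs(cross_scatter(A, B, labels)).max() < 0.08


class TestWhitening:
    def test_diagonal_closed_form(self):
        # S_t = diag(4,1), S_b = I, ridge 0 -> M = diag(1/4, 1)
        labels = np.array([1, 1, 2, 2])
        H = np.array([[2.0, 1.0], [-2.0, -1.0], [2.0, -1.0], [-2.0, 1.0]])
        H = H * np.sqrt(3.0) / np.sqrt(np.array([8.0, 2.0]) / 2.0) / np.sqrt(2)
        # construct directly instead: use explicit matrices through inv_sqrt_psd
        S_t = np.diag([4.0, 1.0])
        R, _, _ = inv_sqrt_psd(S_t, ridge=0.0)
        M = R @ np.eye(2) @ R
        np.testing.assert_allclose(M, np.diag([0.25, 1.0]), atol=1e-12)

    def test_inverse_square_root_identity(self, rng):
        A = rng.standard_normal((5, 8))
        S = A @ A.T / 8
        R, _, _ = inv_sqrt_psd(S, ridge=0.0)
        np.testing.assert_allclose(R @ S @ R, np.eye(5), atol=1e-8)

    def test_zero_cross_gives_zero_N(self, rng):
        H1 = rng.standard_normal((40, 3))
        labels = balanced_labels(20, 2)
        # second view constructed orthogonal to the centered first view
        basis = np.hstack([H1 - H1.mean(0), np.ones((40, 1))])
        H2 = rng.standard_normal((40, 2))
        H2 -= basis @ np.linalg.lstsq(basis, H2, rcond=None)[0]
        ss = whiten_and_build([H1, H2], labels, ridge=1e-3)
        np.testing.assert_allclose(ss.S_cross[(0, 1)], 0, atol=1e-10)
        np.testing.assert_allclose(ss.N[(0, 1)], 0, atol=1e-8)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_balanced_M_eigenvalues_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((24, 4))
        ss = whiten_and_build([H, rng.standard_normal((24, 3))],
                              balanced_labels(8, 3), ridge=0.0)
        for M in ss.M:
            lam = np.linalg.eigvalsh(M)
            assert lam.min() >= -1e-8
            assert lam.max() <= 1 + 1e-8

    def test_row_reordering_invariance(self, rng):
        H1 = rng.standard_normal((12, 3))
        H2 = rng.standard_normal((12, 2))
        labels = balanced_labels(4, 3)
        ss = whiten_and_build([H1, H2], labels)
        perm = rng.permutation(12)
        ss_p = whiten_and_build([H1[perm], H2[perm]], labels[perm])
        np.testing.assert_allclose(ss.S_b[0], ss_p.S_b[0], atol=1e-10)
        np.testing.assert_allclose(ss.S_t[1], ss_p.S_t[1], atol=1e-10)
        np.testing.assert_allclose(ss.S_cross[(0, 1)], ss_p.S_cross[(0, 1)],
                                   atol=1e-10)

    def test_balanced_N_singular_values_bounded(self, rng):
        H1 = rng.standard_normal((30, 3))
        H2 = 0.5 * H1[:, :2] + 0.1 * rng.standard_normal((30, 2))
        ss = whiten_and_build([H1, H2], balanced_labels(15, 2), ridge=0.0)
        assert np.linalg.svd(ss.N[(0, 1)], compute_uv=False).max() <= 1 + 1e-6
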