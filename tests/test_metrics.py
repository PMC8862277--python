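import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcnet.metrics import (DegenerateWarning, center_distance_matrix,
                           distance_correlation, distance_covariance_sq, mic,
                           pairwise_matrix, pearson, permutation_pvalue,
                           spearman)
from oracles import dcor_bruteforce, dcov_sq_bruteforce, mic_exhaustive


class TestPearsonSpearman:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_parabola_on_symmetric_grid_is_zero(self):
        x = np.round(np.arange(-1.0, 1.05, 0.1), 10)
        assert pearson(x, x**2) == pytest.approx(0.0, abs=1e-10)

    def test_hand_expanded_four_points(self):
        # cov = 4, var_x = var_y = 5 => r = 4/5
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_spearman_monotone_and_reversal(self):
        assert spearman([1, 2, 3], [10, 100, 1000]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_spearman_ties_rank_then_pearson(self):
        # ranks of x: (1.5, 1.5, 3, 4); hand Pearson = 4.5/sqrt(4.5*5)
        expected = 4.5 / np.sqrt(4.5 * 5.0)
        assert spearman([1, 1, 2, 3], [1, 2, 3, 4]) == pytest.approx(expected)

    def test_constant_convention_and_errors(self):
        with pytest.warns(DegenerateWarning):
            assert pearson([1, 1, 1], [1, 2, 3]) == 0.0
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1], [2])
        with pytest.raises(ValueError):
            pearson([1, np.nan, 3], [1, 2, 3])


class TestCenteredDistance:
    def test_constant_input_all_zero(self):
        assert np.allclose(center_distance_matrix([0, 0, 0]), 0.0)

    def test_rows_and_columns_sum_to_zero(self, rng):
        for n in (2, 3, 7):
            a = center_distance_matrix(rng.standard_normal(n))
            assert np.allclose(a.sum(axis=0), 0.0, atol=1e-10)
            assert np.allclose(a.sum(axis=1), 0.0, atol=1e-10)
            assert np.allclose(a, a.T)

    def test_explicit_double_loop(self):
        x = np.array([0.0, 1.0, 3.0])
        a = np.abs(np.subtract.outer(x, x))
        expected = np.array(
            [[a[k, l] - a[k].mean() - a[:, l].mean() + a.mean()
              for l in range(3)] for k in range(3)])
        assert np.allclose(center_distance_matrix(x), expected, atol=1e-12)


class TestDistanceCorrelation:
    def test_dcov_constant_is_zero(self):
        assert distance_covariance_sq(np.ones(4), [1., 2, 3, 4]) == 0.0

    def test_dcov_matches_bruteforce(self):
        assert distance_covariance_sq([0, 1, 3], [0, 1, 3]) == pytest.approx(
            dcov_sq_bruteforce([0, 1, 3], [0, 1, 3]), abs=1e-12)
        assert distance_covariance_sq([0, 1], [1, 0]) == pytest.approx(
            dcov_sq_bruteforce([0, 1], [1, 0]), abs=1e-12)

    def test_affine_dependence_gives_one(self, rng):
        x = rng.standard_normal(15)
        assert distance_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert distance_correlation(x, -3 * x + 5) == pytest.approx(1.0)

    def test_constant_partner_convention(self):
        with pytest.warns(DegenerateWarning):
            assert distance_correlation([1., 2, 3], [5., 5, 5]) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([0.0, 1.0, 4.0, 16.0])
        assert distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-12)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            assert distance_correlation(a, b) == pytest.approx(
                dcor_bruteforce(a, b), abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=25),
           st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=25))
    def test_symmetry_and_range(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateWarning)
            d1 = distance_correlation(x, y)
            d2 = distance_correlation(y, x)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0 + 1e-12

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.floats(-50, 50).filter(lambda a: abs(a) > 1e-3),
           st.floats(-50, 50), st.integers(0, 1000))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        base = distance_correlation(x, y)
        assert distance_correlation(a * x + b, y) == pytest.approx(
            base, abs=1e-10)


class TestMic:
    def test_monotone_bijection_is_one(self):
        x = np.arange(16.0)
        assert mic(x, x) == pytest.approx(1.0)
        assert mic(x, np.exp(x)) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        with pytest.warns(DegenerateWarning):
            assert mic(np.arange(8.0), np.ones(8)) == 0.0

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            mic([1., 2, 3], [1., 2, 3])

    def test_checkerboard_matches_exhaustive_oracle(self):
        # 8 points on the diagonal cells of a 2x2 board
        x = np.array([0.0, 0.1, 0.2, 0.3, 1.0, 1.1, 1.2, 1.3])
        y = np.array([0.0, 0.2, 1.0, 1.2, 0.1, 0.3, 1.1, 1.3])
        assert mic(x, y) == pytest.approx(mic_exhaustive(x, y), abs=1e-10)

    def test_matches_exhaustive_oracle_on_random_data(self, rng):
        for n in (8, 12, 16, 20):
            for _ in range(5):
                x = rng.standard_normal(n)
                y = rng.standard_normal(n)
                assert mic(x, y) == pytest.approx(
                    mic_exhaustive(x, y), abs=1e-10)

    def test_orientation_symmetry_and_range(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal(20), rng.standard_normal(20)
            m = mic(x, y)
            assert m == pytest.approx(mic(y, x), abs=1e-12)
            assert 0.0 <= m <= 1.0


class TestPermutationPvalue:
    def test_perfect_relation_gives_minimum_p(self):
        x = np.arange(30.0)
        for metric in ("pearson", "spearman", "dcor", "mic"):
            assert permutation_pvalue(metric, x, x, 199, 0) == pytest.approx(
                1 / 200)

    def test_deterministic_given_seed(self, rng):
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        for metric in ("pearson", "spearman", "dcor", "mic"):
            p1 = permutation_pvalue(metric, x, y, 99, seed=42)
            p2 = permutation_pvalue(metric, x, y, 99, seed=42)
            assert p1 == p2

    def test_invalid_metric_and_nperm(self):
        with pytest.raises(ValueError):
            permutation_pvalue("kendall", [1., 2, 3], [1., 2, 3])
        with pytest.raises(ValueError):
            permutation_pvalue("pearson", [1., 2, 3], [1., 2, 3], n_perm=0)

    def test_signed_metric_uses_absolute_statistic(self):
        x = np.arange(20.0)
        assert permutation_pvalue("pearson", x, -x, 199, 0) == pytest.approx(
            1 / 200)


class TestPairwiseMatrix:
    def test_proportional_genes_score_one_for_all_metrics(self):
        expr = np.array([[1.0, 2, 3, 4, 5, 6],
                         [2.0, 4, 6, 8, 10, 12],
                         [6.0, 4, 3, 1, 2, 5]])
        for metric in ("pearson", "spearman", "dcor", "mic"):
            m = pairwise_matrix(expr, metric)
            assert m.values[0, 1] == pytest.approx(1.0)
            assert np.array_equal(m.values, m.values.T)

    def test_dcor_matrix_matches_per_pair_calls(self, rng):
        expr = rng.standard_normal((10, 20))
        m = pairwise_matrix(expr, "dcor")
        for i in range(10):
            for j in range(i + 1, 10):
                assert m.values[i, j] == pytest.approx(
                    distance_correlation(expr[i], expr[j]), abs=1e-10)

    def test_constant_gene_flagged_and_zeroed(self):
        expr = np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4], [4.0, 2, 1, 3]])
        with pytest.warns(DegenerateWarning):
            m = pairwise_matrix(expr, "pearson")
        assert m.constant_genes == [0]
        assert np.all(m.values[0] == 0.0)

    def test_signed_ranges_and_unit_diagonal(self, rng):
        expr = rng.standard_normal((6, 15))
        for metric in ("pearson", "spearman"):
            m = pairwise_matrix(expr, metric)
            assert np.all(m.values >= -1.0) and np.all(m.values <= 1.0)
            assert np.allclose(np.diag(m.values), 1.0)
        for metric in ("dcor", "mic"):
            m = pairwise_matrix(expr, metric)
            assert np.all(m.values >= 0.0) and np.all(m.values <= 1.0)
            assert np.allclose(np.diag(m.values), 1.0)
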