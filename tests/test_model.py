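"""Core label-aware distance: weights, scatter, whitening, metric axioms."""

import numpy as np
import pytest

from ladist import (
    BatchDesign,
    ExpressionMatrix,
    LabelAwareDistance,
    compute_batch_summary,
    compute_label_weights,
    compute_sigma_tilde,
    fit,
    pairwise_lad,
)
from ladist.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    NumericalConditioningError,
)

from conftest import mahalanobis_explicit, random_instance, sigma_tilde_bruteforce


class TestLabelWeights:
    @pytest.mark.parametrize(
        "t_a, t_b, length_scale, expected",
        [
            ([3.0], [3.0], 0.5, 1.0),  # identical labels
            ([1.0], [2.0], 1.0, np.exp(-0.5)),  # one length scale apart
            # week/location vectors with the 0/2/4 location spacing
            ([11.5, 0.0], [11.5, 2.0], 1.0, np.exp(-2.0)),
            ([11.5, 0.0], [11.5, 4.0], 1.0, np.exp(-8.0)),
        ],
    )
    def test_closed_form(self, t_a, t_b, length_scale, expected):
        w = compute_label_weights(np.array([t_a, t_b]), length_scale)
        assert w[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_structure(self, rng):
        labels = rng.normal(size=(6, 2))
        w = compute_label_weights(labels, 0.7)
        assert np.array_equal(w, w.T)
        assert np.allclose(np.diag(w), 1.0)
        assert np.all((w > 0) & (w <= 1))

    def test_nonpositive_length_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_label_weights(np.array([[0.0], [1.0]]), 0.0)

    def test_mismatched_label_dimensions_rejected(self):
        with pytest.raises(InvalidInputError):
            BatchDesign(["a", "b"], np.array([[1.0], [1.0, 2.0]], dtype=object))


class TestBatchSummary:
    def test_two_point_mean(self):
        X = ExpressionMatrix(np.array([[0.0, 0.0], [2.0, 2.0]]))
        design = BatchDesign(["b", "b"], [0.0])
        summary = compute_batch_summary(X, design)
        assert np.allclose(summary.batch_means, [[1.0, 1.0]])
        assert summary.batch_sizes.tolist() == [2]

    def test_singleton_batch_is_its_own_mean(self):
        X = ExpressionMatrix(np.array([[1.0, 5.0], [3.0, -1.0]]))
        design = BatchDesign(["u", "v"], [0.0, 1.0])
        summary = compute_batch_summary(X, design)
        assert np.allclose(summary.batch_means, X.values)

    def test_matches_naive_loop(self, rng):
        X, design, batch_idx = random_instance(rng, n=10, k=4, B=3)
        summary = compute_batch_summary(X, design)
        for b in range(3):
            expected = X.values[batch_idx == b].mean(axis=0)
            assert np.allclose(summary.batch_means[b], expected, atol=1e-10)
        assert summary.batch_sizes.sum() == 10

    def test_empty_batch_names_the_batch(self):
        X = ExpressionMatrix(np.ones((2, 2)))
        design = BatchDesign(["u", "u"], [0.0, 1.0], batch_ids=["u", "ghost"])
        with pytest.raises(InvalidInputError, match="ghost"):
            compute_batch_summary(X, design)


class TestSigmaTilde:
    def test_single_batch_is_empty_sum(self, rng):
        X = ExpressionMatrix(rng.normal(size=(8, 3)))
        design = BatchDesign(["b"] * 8, [0.0])
        sigma = compute_sigma_tilde(X, design, np.ones((1, 1)))
        assert np.array_equal(sigma, np.zeros((3, 3)))

    def test_zero_weights_give_zero_matrix(self, rng):
        X, design, _ = random_instance(rng, n=12, k=3, B=3)
        sigma = compute_sigma_tilde(X, design, np.zeros((3, 3)))
        assert np.array_equal(sigma, np.zeros((3, 3)))

    def test_tiny_integer_case_matches_handmade_loop(self):
        values = np.array([[1.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        batch_idx = np.array([0, 0, 1])
        X = ExpressionMatrix(values)
        design = BatchDesign(["a", "a", "b"], [0.0, 0.0], batch_ids=["a", "b"])
        weights = np.ones((2, 2))
        sigma = compute_sigma_tilde(X, design, weights)
        assert np.allclose(sigma, sigma_tilde_bruteforce(values, batch_idx, weights), atol=1e-12)
        # cross-check one entry fully by hand: m_a=(0.5,1), m_b=(2,2)
        # cell0 vs b: (-1,-2); cell1 vs b: (-2,0); cell2 vs a: (1.5,1)
        assert sigma[0, 0] == pytest.approx(1 + 4 + 2.25)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_on_random_instances(self, trial):
        rng = np.random.default_rng(trial)
        n, k, B = int(rng.integers(5, 51)), int(rng.integers(2, 9)), int(rng.integers(2, 6))
        X, design, batch_idx = random_instance(rng, n=n, k=k, B=B)
        weights = compute_label_weights(design.batch_labels, 1.0)
        sigma = compute_sigma_tilde(X, design, weights)
        expected = sigma_tilde_bruteforce(X.values, batch_idx, weights)
        assert np.allclose(sigma, expected, rtol=1e-9, atol=1e-9)

    def test_unit_weights_reproduce_alternative_clustering_scatter(self, rng):
        """With W pinned to 1 the scatter is the Qi-Davidson construction."""
        X, design, batch_idx = random_instance(rng, n=25, k=4, B=3)
        results = fit(X, design, length_scale=1e8)
        expected = sigma_tilde_bruteforce(X.values, batch_idx, np.ones((3, 3)))
        assert np.allclose(results.weight_matrix, 1.0)
        assert np.allclose(results.sigma_tilde, expected, rtol=1e-9, atol=1e-9)

    def test_permutation_invariance(self, rng):
        X, design, batch_idx = random_instance(rng, n=20, k=3, B=3)
        weights = compute_label_weights(design.batch_labels, 1.0)
        sigma = compute_sigma_tilde(X, design, weights)
        perm = rng.permutation(20)
        Xp = ExpressionMatrix(X.values[perm])
        designp = BatchDesign(
            design.batch_of_cell[perm], design.batch_labels, batch_ids=design.batch_ids
        )
        sigmap = compute_sigma_tilde(Xp, designp, weights)
        assert np.allclose(sigma, sigmap, atol=1e-10)

    def test_scale_covariance_is_self_normalizing(self, rng):
        """Scaling X by c scales sigma_tilde by c^2; with ridge scaled by c^2
        all distances are unchanged (the metric is self-normalizing)."""
        X, design, _ = random_instance(rng, n=20, k=3, B=3)
        r1 = fit(X, design, ridge=1e-2)
        c = 3.7
        r2 = fit(ExpressionMatrix(c * X.values), design, ridge=1e-2 * c**2)
        assert np.allclose(r2.sigma_tilde, c**2 * r1.sigma_tilde, rtol=1e-9)
        d1 = r1.pairwise(X)
        d2 = r2.pairwise(ExpressionMatrix(c * X.values))
        assert np.allclose(d2, d1, rtol=1e-8, atol=1e-10)


class TestFitAndTransform:
    def test_single_batch_degenerates_to_scaled_euclidean(self, rng):
        X = ExpressionMatrix(rng.normal(size=(10, 3)))
        design = BatchDesign(["b"] * 10, [0.0])
        with pytest.warns(UserWarning, match="single batch"):
            results = fit(X, design, ridge=1.0)
        assert np.array_equal(results.sigma_tilde, np.zeros((3, 3)))
        assert np.allclose(results.cholesky_factor, np.eye(3))
        assert np.allclose(results.transform(X).values, X.values)

    def test_cholesky_reconstructs_sigma_plus_ridge(self, rng):
        X, design, _ = random_instance(rng, n=50, k=5, B=3)
        results = fit(X, design)
        L = results.cholesky_factor
        target = results.sigma_tilde + results.ridge * np.eye(5)
        assert np.allclose(L @ L.T, target, rtol=1e-6)
        assert np.allclose(L, np.tril(L))

    def test_fit_is_deterministic(self, rng):
        X, design, _ = random_instance(rng)
        r1, r2 = fit(X, design), fit(X, design)
        assert np.array_equal(r1.sigma_tilde, r2.sigma_tilde)
        assert np.array_equal(r1.cholesky_factor, r2.cholesky_factor)

    def test_sigma_is_symmetric_psd(self, rng):
        X, design, _ = random_instance(rng, n=40, k=6, B=4)
        results = fit(X, design)
        s = results.sigma_tilde
        assert np.allclose(s, s.T, atol=1e-8)
        eig = np.linalg.eigvalsh(s)
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)

    def test_identity_model_transform_is_identity(self, rng):
        X = ExpressionMatrix(rng.normal(size=(6, 2)))
        design = BatchDesign(["b"] * 6, [0.0])
        with pytest.warns(UserWarning):
            results = fit(X, design, ridge=1.0)  # sigma=0 -> sigma+I = I
        assert np.allclose(results.transform(X).values, X.values)

    def test_diagonal_model_halves_coordinates(self):
        X = ExpressionMatrix(np.array([[2.0, 4.0], [6.0, 8.0]]))
        design = BatchDesign(["b", "b"], [0.0])
        with pytest.warns(UserWarning):
            results = fit(X, design, ridge=4.0)  # sigma+ridge*I = diag(4,4)
        assert np.allclose(results.transform(X).values, X.values / 2.0)

    def test_singular_scatter_with_zero_ridge_advises_larger_ridge(self, rng):
        X = ExpressionMatrix(rng.normal(size=(8, 3)))
        design = BatchDesign(["b"] * 8, [0.0])  # sigma_tilde = 0, ridge 0
        with pytest.warns(UserWarning), pytest.raises(
            NumericalConditioningError, match="ridge"
        ):
            fit(X, design, ridge=0.0)

    def test_negative_ridge_rejected(self, rng):
        X, design, _ = random_instance(rng)
        with pytest.raises(InvalidParameterError):
            LabelAwareDistance(X, design, ridge=-1.0)

    def test_dimension_mismatch_rejected(self, rng):
        X, design, _ = random_instance(rng, n=20, k=4)
        results = fit(X, design)
        with pytest.raises(InvalidInputError):
            results.transform(np.ones((5, 3)))
        with pytest.raises(InvalidInputError):
            results.distance(np.ones(3), np.ones(3))

    def test_summary_mentions_key_quantities(self, rng):
        X, design, _ = random_instance(rng)
        text = fit(X, design).summary()
        for token in ("cells", "batches", "length scale", "ridge"):
            assert token in text


class TestDistances:
    def test_zero_self_distance(self, rng):
        X, design, _ = random_instance(rng)
        results = fit(X, design)
        assert results.distance(X.values[0], X.values[0]) == 0.0

    def test_identity_model_reduces_to_euclidean(self):
        X = ExpressionMatrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        design = BatchDesign(["b", "b"], [0.0])
        with pytest.warns(UserWarning):
            results = fit(X, design, ridge=1.0)
        assert results.distance(X.values[0], X.values[1]) == pytest.approx(5.0)

    def test_matches_explicit_inverse_quadratic_form(self, rng):
        X, design, _ = random_instance(rng, n=40, k=5, B=4)
        results = fit(X, design)
        matrix = results.sigma_tilde + results.ridge * np.eye(5)
        for _ in range(20):
            i, j = rng.integers(0, 40, size=2)
            expected = mahalanobis_explicit(X.values[i], X.values[j], matrix)
            assert results.distance(X.values[i], X.values[j]) == pytest.approx(
                expected, rel=1e-8, abs=1e-10
            )

    def test_transformed_pair_distance_matches_explicit_inverse(self, rng):
        X, design, _ = random_instance(rng, n=30, k=4, B=3)
        results = fit(X, design)
        Y = results.transform(X).values
        matrix = results.sigma_tilde + results.ridge * np.eye(4)
        d = np.linalg.norm(Y[3] - Y[17])
        assert d == pytest.approx(
            mahalanobis_explicit(X.values[3], X.values[17], matrix), rel=1e-8
        )

    def test_pairwise_structure_and_elementwise_agreement(self, rng):
        X, design, _ = random_instance(rng, n=15, k=3, B=3)
        results = fit(X, design)
        D = pairwise_lad(X, results)
        assert D.shape == (15, 15)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for _ in range(10):
            i, j = rng.integers(0, 15, size=2)
            assert D[i, j] == pytest.approx(
                results.distance(X.values[i], X.values[j]), abs=1e-10
            )

    def test_single_cell_pairwise(self, rng):
        X = ExpressionMatrix(rng.normal(size=(1, 3)))
        design = BatchDesign(["b"], [0.0])
        with pytest.warns(UserWarning):
            results = fit(X, design, ridge=1.0)
        assert np.array_equal(results.pairwise(X), np.zeros((1, 1)))

    def test_metric_axioms_on_random_triples(self, rng):
        X, design, _ = random_instance(rng, n=60, k=5, B=4)
        results = fit(X, design)
        D = pairwise_lad(X, results)
        idx = rng.integers(0, 60, size=(1000, 3))
        i, j, m = idx[:, 0], idx[:, 1], idx[:, 2]
        assert np.all(D >= 0)
        assert np.all(D[i, j] <= D[i, m] + D[m, j] + 1e-9)


class TestBatchSuppression:
    @staticmethod
    def _offset_instance(delta, rng_seed=0, times=(0.0, 0.0)):
        """Two batches identical up to an additive offset delta*v on v=e1."""
        rng = np.random.default_rng(rng_seed)
        base = rng.normal(size=(40, 4))
        v = np.zeros(4)
        v[0] = 1.0
        values = np.vstack([base, base + delta * v])
        batches = ["a"] * 40 + ["b"] * 40
        design = BatchDesign(batches, list(times), batch_ids=["a", "b"])
        return ExpressionMatrix(values), design, v

    def test_batch_direction_suppression_monotone_in_offset(self):
        """Growing a pure batch offset along v shrinks the Lad/Euclidean
        ratio of distances measured along v."""
        ratios = []
        for delta in (1.0, 10.0, 100.0):
            X, design, v = self._offset_instance(delta)
            results = fit(X, design)
            lad = results.distance(np.zeros(4), v)
            ratios.append(lad / 1.0)  # Euclidean length of v is 1
        assert ratios[0] >= ratios[1] >= ratios[2]
        assert ratios[2] < ratios[0]

    def test_locality_ordering_of_suppression(self):
        """Identical offsets between time-adjacent batches are suppressed
        more than between time-distant batches (weights exp(-1/2) vs
        exp(-50))."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(50, 4))
        v01 = np.array([1.0, 0.0, 0.0, 0.0])  # offset direction batch0 -> batch1
        v02 = np.array([0.0, 1.0, 0.0, 0.0])  # offset direction batch0 -> batch2
        delta = 20.0
        values = np.vstack([base, base + delta * v01, base + delta * v02])
        design = BatchDesign(
            ["t0"] * 50 + ["t1"] * 50 + ["t10"] * 50,
            [0.0, 1.0, 10.0],
            batch_ids=["t0", "t1", "t10"],
        )
        results = fit(ExpressionMatrix(values), design)
        # same Euclidean length, so the Lad lengths compare the suppression
        assert results.distance(np.zeros(4), v01) < results.distance(np.zeros(4), v02)
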