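"""Sparse linear classifier, nested LOOCV and permutation testing."""

import numpy as np
import pytest

import divprof as dp
from divprof.classify import (
    HyperparameterGrid,
    NoAdmissibleModelError,
    ProfileFeatureMatrix,
    fit_sparse_linear_classifier,
    is_significant,
    nested_loocv,
    permutation_test,
    scores_from_confusion,
    single_index_baseline,
)


def make_pfm(X, labels, positive="B"):
    X = np.asarray(X, float)
    return ProfileFeatureMatrix(
        X,
        np.arange(X.shape[1], dtype=float),
        tuple(f"s{i}" for i in range(X.shape[0])),
        tuple(labels),
        positive,
    )


@pytest.fixture(scope="module")
def separable_pfm():
    """One feature carries the labels with a wide margin; rest is noise."""
    rng = np.random.default_rng(0)
    n = 16
    y = np.array([1.0] * (n // 2) + [-1.0] * (n // 2))
    X = rng.normal(size=(n, 12))
    X[:, 3] = y * 5 + rng.normal(0, 0.1, n)
    return make_pfm(X, ["B" if v > 0 else "A" for v in y])


class TestSolver:
    def test_matches_reference_objective_across_grid(self):
        """Cross-check against the independent L1 squared-hinge reference."""
        sklearn = pytest.importorskip("sklearn.svm")
        import warnings

        rng = np.random.default_rng(1)
        X = np.ascontiguousarray(rng.normal(size=(20, 30)))
        y = rng.integers(0, 2, 20) * 2.0 - 1.0

        def objective(w, c, eps):
            m = np.maximum(0, 1 - y * (X @ w))
            return c * np.sum(m**2) + eps * np.sum(np.abs(w))

        for c in (1.0, 17.0):
            for eps in (0.125, 2.0, 16.0):
                model = fit_sparse_linear_classifier(X, y, c, eps, standardize=False)
                ref = sklearn.LinearSVC(
                    penalty="l1",
                    loss="squared_hinge",
                    dual=False,
                    C=c / eps,
                    fit_intercept=False,
                    max_iter=200000,
                    tol=1e-10,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ref.fit(X, (y > 0).astype(int))
                ours = objective(model.weights, c, eps)
                theirs = objective(ref.coef_[0], c, eps)
                assert ours <= theirs * (1 + 1e-6) + 1e-9

    def test_separable_single_feature_selected(self, separable_pfm):
        model = fit_sparse_linear_classifier(separable_pfm.X, separable_pfm.y, 5.0, 2.0)
        assert 3 in model.selected
        assert np.array_equal(model.predict(separable_pfm.X), separable_pfm.y)

    def test_large_epsilon_maximally_sparse(self, separable_pfm):
        model = fit_sparse_linear_classifier(separable_pfm.X, separable_pfm.y, 1.0, 500.0)
        assert model.selected.size <= 1

    def test_sparsity_monotone_in_epsilon(self, separable_pfm):
        sizes = [
            fit_sparse_linear_classifier(separable_pfm.X, separable_pfm.y, 5.0, e).selected.size
            for e in (0.125, 2.0, 32.0)
        ]
        assert sizes[0] >= sizes[-1]

    def test_duplicated_feature_columns_keep_selection_compact(self, separable_pfm):
        base = fit_sparse_linear_classifier(separable_pfm.X, separable_pfm.y, 5.0, 2.0)
        X2 = np.hstack([separable_pfm.X, separable_pfm.X[:, [3]]])
        dup = fit_sparse_linear_classifier(X2, separable_pfm.y, 5.0, 2.0)
        assert dup.selected.size <= base.selected.size + 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_sparse_linear_classifier(np.ones((4, 3)), np.ones(4), 1.0, 1.0)


class TestScores:
    def test_confusion_arithmetic(self):
        sens, spec, bacc = scores_from_confusion(tp=10, fn=2, tn=11, fp=1)
        assert sens == pytest.approx(83.3, abs=0.05)
        assert spec == pytest.approx(91.7, abs=0.05)
        assert bacc == pytest.approx(87.5, abs=1e-9)

    def test_significance_boundary(self):
        # fewer than 10 exceedances in 1000 is significant; exactly 10 is not
        assert is_significant(9, 1000)
        assert not is_significant(10, 1000)


class TestNestedLOOCV:
    def test_separable_data_perfect_bacc(self, separable_pfm):
        result = nested_loocv(separable_pfm)
        assert result.bacc == 100.0
        assert result.sensitivity == 100.0 and result.specificity == 100.0
        assert result.bacc == (result.sensitivity + result.specificity) / 2

    def test_median_alphas_counts_selected_features(self, separable_pfm):
        result = nested_loocv(separable_pfm)
        assert result.median_n_alphas >= 1
        assert all(len(s) <= 20 for s in result.selected_alphas_per_fold)

    def test_no_outer_leakage(self, separable_pfm):
        """Scrambling one held-out sample's features must not change the
        hyperparameters its inner loop selects."""
        res = nested_loocv(separable_pfm)
        X2 = separable_pfm.X.copy()
        rng = np.random.default_rng(99)
        X2[0] = rng.normal(size=X2.shape[1]) * 100
        res2 = nested_loocv(
            ProfileFeatureMatrix(
                X2,
                separable_pfm.alphas,
                separable_pfm.sample_ids,
                separable_pfm.labels,
                separable_pfm.positive_label,
            )
        )
        assert res.chosen_hyperparams_per_fold[0] == res2.chosen_hyperparams_per_fold[0]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nested_loocv(make_pfm(np.eye(4), ["A", "A", "B", "B"]))

    def test_single_index_baseline_restricts_features(self, separable_pfm):
        # restricting to one feature caps the number of selectable alphas
        res = single_index_baseline(separable_pfm, alphas=(3.0,))
        assert res.median_n_alphas <= 1
        assert 0 <= res.bacc <= 100


class TestPermutationTest:
    def test_separable_data_p_zero(self, separable_pfm):
        observed = nested_loocv(separable_pfm)
        perm = permutation_test(
            separable_pfm, n_permutations=30, seed=1, observed=observed
        )
        # no label shuffle can strictly exceed BACC 100 %
        assert perm.n_exceeding == 0
        assert perm.p_value == 0.0
        assert perm.significant

    def test_low_resolution_warns(self, separable_pfm):
        observed = nested_loocv(separable_pfm)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(separable_pfm, n_permutations=5, seed=1, observed=observed)
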