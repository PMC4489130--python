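"""Supervised prediction of immunological status from diversity profiles.

Diversity and Evenness profiles share one alpha grid across samples, so
repertoires of arbitrary clonal composition become comparable feature
vectors: rows are samples, columns are alpha values.  A sparse linear
classifier (L1-penalized squared-hinge objective; cost parameter ``c``
weighs misclassification, regularization parameter ``eps`` drives feature
selection) classifies binary immunological status while selecting a
minimal subset of informative alpha values.

Performance is measured by nested leave-one-out cross-validation: the
outer loop holds out one sample; the inner loop, blind to it, scores
every hyperparameter pair ``(c, eps)`` by inner LOOCV, excludes pairs for
which more than ``max_violations`` inner models select more than
``max_selected_features`` alpha values, refits the winner and predicts
the held-out sample.  Pooled outer predictions give sensitivity,
specificity and the balanced accuracy BACC = (sensitivity +
specificity)/2.  Significance is assessed by permutation testing: the
label vector is shuffled many times, the full nested procedure is re-run,
and the p-value is the share of shuffles whose BACC strictly exceeds the
observed one.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solver import FEATURE_EPS, fit_l1_squared_hinge, nested_loocv_core

__all__ = [
    "HyperparameterGrid",
    "ProfileFeatureMatrix",
    "SparseLinearModel",
    "ClassificationResult",
    "PermutationTestResult",
    "NoAdmissibleModelError",
    "fit_sparse_linear_classifier",
    "nested_loocv",
    "permutation_test",
    "single_index_baseline",
    "scores_from_confusion",
    "is_significant",
]

_REFIT_MAX_ITER = 2000
_REFIT_TOL = 1e-9
_FIT_MAX_ITER = 20000  # standalone single fits can afford full convergence
_PAIR_MAX_ITER = 600
_PAIR_TOL = 1e-8
_INNER_MAX_ITER = 250


class NoAdmissibleModelError(RuntimeError):
    """Every hyperparameter pair was excluded by the feature-cap rule."""


@dataclass(frozen=True)
class HyperparameterGrid:
    """Hyperparameter search space of the nested cross-validation.

    Defaults: cost ``c`` in {1, 5, 9, 13, 17} (1 to 17 in five equally
    spaced steps); regularization ``eps`` in {2^i : i = -3..4}; at most
    20 selected alpha values, with a pair excluded once more than 3 inner
    models exceed that cap.
    """

    c_values: tuple[float, ...] = (1.0, 5.0, 9.0, 13.0, 17.0)
    epsilon_values: tuple[float, ...] = tuple(float(2.0**i) for i in range(-3, 5))
    max_selected_features: int = 20
    max_violations: int = 3


@dataclass(frozen=True)
class ProfileFeatureMatrix:
    """Samples-by-alphas feature matrix with binary status labels."""

    X: np.ndarray
    alphas: np.ndarray
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    positive_label: str

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        if X.ndim != 2 or X.shape[1] != self.alphas.size:
            raise ValueError("X must be (n_samples, n_alphas)")
        if len(self.sample_ids) != X.shape[0] or len(self.labels) != X.shape[0]:
            raise ValueError("sample_ids and labels must match rows of X")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains missing/non-finite values")
        classes = set(self.labels)
        if len(classes) != 2:
            raise ValueError(f"need exactly two label classes, got {sorted(classes)}")
        if self.positive_label not in classes:
            raise ValueError(f"positive_label {self.positive_label!r} not among labels")

    @property
    def y(self) -> np.ndarray:
        """Labels as +1 (positive class) / -1."""
        return np.where(np.array(self.labels) == self.positive_label, 1.0, -1.0)

    def restrict_alphas(self, alphas) -> "ProfileFeatureMatrix":
        """Keep only the feature columns at the given alpha values."""
        wanted = np.asarray(alphas, dtype=float)
        cols = []
        for a in wanted:
            hits = np.nonzero(np.isclose(self.alphas, a))[0]
            if hits.size == 0:
                raise ValueError(f"alpha {a} not on the feature grid")
            cols.append(int(hits[0]))
        return ProfileFeatureMatrix(
            self.X[:, cols], self.alphas[cols], self.sample_ids, self.labels, self.positive_label
        )


@dataclass(frozen=True)
class SparseLinearModel:
    """A fitted sparse linear decision function over alpha features.

    The decision function is intercept-free on standardized features;
    the all-zero model therefore scores exactly chance-level balanced
    accuracy rather than tracking the training class imbalance.
    """

    weights: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    c: float
    epsilon: float

    @property
    def selected(self) -> np.ndarray:
        """Indices of features with nonzero weight."""
        return np.nonzero(np.abs(self.weights) > FEATURE_EPS)[0]

    def decision_function(self, X) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.feature_means) / self.feature_scales
        return Xs @ self.weights

    def predict(self, X) -> np.ndarray:
        """Predicted labels in {-1, +1}."""
        return np.where(self.decision_function(X) >= 0.0, 1.0, -1.0)


def fit_sparse_linear_classifier(
    X, y, c: float, epsilon: float, standardize: bool = True
) -> SparseLinearModel:
    """Fit the L1-penalized squared-hinge classifier on training data.

    ``y`` must be in {-1, +1} with both classes present (at least two
    samples each).  Sparsity grows with ``epsilon``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.sum(y > 0) < 2 or np.sum(y < 0) < 2:
        raise ValueError("need >= 2 training samples per class")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = np.ascontiguousarray((X - mu) / sd)
    w = fit_l1_squared_hinge(
        Xs, y, float(c), float(epsilon), np.zeros(X.shape[1]), _FIT_MAX_ITER, 1e-12
    )
    return SparseLinearModel(
        weights=w,
        feature_means=mu,
        feature_scales=sd,
        c=float(c),
        epsilon=float(epsilon),
    )


def scores_from_confusion(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, BACC) in percent from pooled counts."""
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    return sens, spec, (sens + spec) / 2.0


@dataclass(frozen=True)
class ClassificationResult:
    """Pooled nested-LOOCV outcome for one feature matrix."""

    bacc: float
    sensitivity: float
    specificity: float
    selected_alphas_per_fold: tuple[tuple[float, ...], ...]
    median_n_alphas: float
    chosen_hyperparams_per_fold: tuple[tuple[float, float], ...]
    permutation_p: float | None = None

    def __post_init__(self) -> None:
        if abs(self.bacc - (self.sensitivity + self.specificity) / 2.0) > 1e-9:
            raise ValueError("BACC must equal (sensitivity + specificity)/2")


def _run_nested(X, y, grid: HyperparameterGrid):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    cs = np.asarray(grid.c_values, dtype=float)
    epss = np.asarray(grid.epsilon_values, dtype=float)
    return nested_loocv_core(
        X,
        y,
        cs,
        epss,
        grid.max_selected_features,
        grid.max_violations,
        _INNER_MAX_ITER,
        _PAIR_MAX_ITER,
        _PAIR_TOL,
        _REFIT_MAX_ITER,
        _REFIT_TOL,
    )


def nested_loocv(pfm: ProfileFeatureMatrix, grid: HyperparameterGrid | None = None) -> ClassificationResult:
    """Nested leave-one-out cross-validation with embedded feature selection."""
    grid = grid or HyperparameterGrid()
    y = pfm.y
    n = y.size
    if n < 6:
        raise ValueError("need at least 6 samples for nested LOOCV")
    if np.sum(y > 0) < 2 or np.sum(y < 0) < 2:
        raise ValueError("need >= 2 samples per class")
    pred, ci, ei, nsel, mask, feasible = _run_nested(pfm.X, y, grid)
    if not np.all(feasible):
        bad = [pfm.sample_ids[i] for i in np.nonzero(~feasible)[0]]
        raise NoAdmissibleModelError(
            f"all hyperparameter pairs excluded by the feature cap for folds {bad}"
        )
    tp = int(np.sum((y > 0) & (pred > 0)))
    fn = int(np.sum((y > 0) & (pred < 0)))
    tn = int(np.sum((y < 0) & (pred < 0)))
    fp = int(np.sum((y < 0) & (pred > 0)))
    sens, spec, bacc = scores_from_confusion(tp, fn, tn, fp)
    cs = np.asarray(grid.c_values, float)
    epss = np.asarray(grid.epsilon_values, float)
    return ClassificationResult(
        bacc=bacc,
        sensitivity=sens,
        specificity=spec,
        selected_alphas_per_fold=tuple(
            tuple(float(a) for a in pfm.alphas[mask[k]]) for k in range(n)
        ),
        median_n_alphas=float(statistics.median(nsel.tolist())),
        chosen_hyperparams_per_fold=tuple(
            (float(cs[ci[k]]), float(epss[ei[k]])) for k in range(n)
        ),
    )


def is_significant(n_exceeding: int, n_permutations: int) -> bool:
    """Permutation significance rule: exceed-count below 1 % of shuffles.

    With 1000 shuffles, fewer than 10 exceeding BACCs (p < 0.01) counts as
    significant; exactly 10 does not.
    """
    return n_exceeding < 0.01 * n_permutations


@dataclass(frozen=True)
class PermutationTestResult:
    """Permutation-test summary for an observed classification result."""

    p_value: float
    n_exceeding: int
    n_permutations: int
    observed_bacc: float
    null_baccs: np.ndarray = field(repr=False)

    @property
    def significant(self) -> bool:
        return is_significant(self.n_exceeding, self.n_permutations)


def _bacc_only(X, y, grid) -> float:
    pred, _ci, _ei, _nsel, _mask, feasible = _run_nested(X, y, grid)
    if not np.all(feasible):
        raise NoAdmissibleModelError("all hyperparameter pairs excluded during permutation run")
    tp = int(np.sum((y > 0) & (pred > 0)))
    fn = int(np.sum((y > 0) & (pred < 0)))
    tn = int(np.sum((y < 0) & (pred < 0)))
    fp = int(np.sum((y < 0) & (pred > 0)))
    return scores_from_confusion(tp, fn, tn, fp)[2]


def permutation_test(
    pfm: ProfileFeatureMatrix,
    grid: HyperparameterGrid | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    observed: ClassificationResult | None = None,
) -> PermutationTestResult:
    """Label-shuffling significance test of the nested-LOOCV BACC.

    Each permutation independently shuffles the label vector and re-runs
    the entire nested procedure; ``p = #(null BACC > observed BACC) /
    n_permutations`` (strict exceedance).
    """
    grid = grid or HyperparameterGrid()
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} gives coarse p-value resolution",
            stacklevel=2,
        )
    if observed is None:
        observed = nested_loocv(pfm, grid)
    rng = np.random.default_rng(seed)
    y = pfm.y
    null_baccs = np.empty(n_permutations)
    for i in range(n_permutations):
        null_baccs[i] = _bacc_only(pfm.X, rng.permutation(y), grid)
    n_exceeding = int(np.sum(null_baccs > observed.bacc))
    return PermutationTestResult(
        p_value=n_exceeding / n_permutations,
        n_exceeding=n_exceeding,
        n_permutations=n_permutations,
        observed_bacc=observed.bacc,
        null_baccs=null_baccs,
    )


def single_index_baseline(
    pfm: ProfileFeatureMatrix,
    alphas=(1.0,),
    grid: HyperparameterGrid | None = None,
) -> ClassificationResult:
    """Run the same pipeline restricted to single classical indices.

    ``alphas=(1.0,)`` keeps only the exponential-Shannon feature,
    ``(2.0,)`` the inverse-Simpson one, ``(1.0, 2.0)`` both; used to
    compare full profiles against conventional single diversity indices.
    """
    return nested_loocv(pfm.restrict_alphas(alphas), grid)
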