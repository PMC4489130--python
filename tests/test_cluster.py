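"""Distance matrices, complete-linkage trees and cophenetic comparison."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.cluster import hierarchy

import divprof as dp
from divprof.cluster import (
    alpha_sweep,
    cophenetic_correlation,
    distance_matrix,
    hierarchical_cluster,
)


class TestDistanceMatrix:
    def test_identical_vectors_zero_distance(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 5.0]])
        for metric in ("euclidean", "pearson_correlation_distance"):
            dm = distance_matrix(X, ["a", "b", "c"], metric=metric)
            assert dm.square[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_scale_invariance(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        dm = distance_matrix([v, 2 * v], metric="pearson_correlation_distance")
        assert dm.condensed[0] == pytest.approx(0.0, abs=1e-12)
        dm_e = distance_matrix([v, 2 * v], metric="euclidean")
        assert dm_e.condensed[0] == pytest.approx(np.linalg.norm(v))

    def test_anticorrelated_vectors_distance_two(self):
        dm = distance_matrix(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], metric="pearson_correlation_distance"
        )
        assert dm.condensed[0] == pytest.approx(2.0)

    def test_zero_variance_vector_named_in_error(self):
        with pytest.raises(ValueError, match="flatliner"):
            distance_matrix(
                [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                ["flatliner", "ok"],
                metric="pearson_correlation_distance",
            )


class TestHierarchicalCluster:
    def test_hand_agglomeration_three_points(self):
        # complete linkage takes the max: (A,B) merge at 1, C joins at 6
        from scipy.spatial.distance import squareform

        from divprof.cluster import DistanceMatrix

        sq = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 6.0], [5.0, 6.0, 0.0]])
        tree = hierarchical_cluster(
            DistanceMatrix(("A", "B", "C"), squareform(sq), "euclidean")
        )
        heights = sorted(tree.linkage[:, 2])
        assert heights == [1.0, 6.0]

    def test_two_leaves(self):
        dm = distance_matrix([[0.0, 1.0], [3.0, 5.0]], ["a", "b"])
        tree = hierarchical_cluster(dm)
        assert tree.linkage.shape[0] == 1
        assert tree.linkage[0, 2] == pytest.approx(dm.condensed[0])

    def test_cophenetic_ultrametric_against_bruteforce(self):
        # cophenetic distances from complete linkage satisfy the ultrametric
        # inequality d(i,k) <= max(d(i,j), d(j,k))
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        tree = hierarchical_cluster(distance_matrix(X))
        from scipy.spatial.distance import squareform

        C = squareform(tree.cophenetic_distances())
        n = C.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, k] <= max(C[i, j], C[j, k]) + 1e-9

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(2)
        tree = hierarchical_cluster(distance_matrix(rng.normal(size=(5, 3)), list("abcde")))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk


class TestCopheneticCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        tree = hierarchical_cluster(distance_matrix(rng.normal(size=(10, 6))))
        assert cophenetic_correlation(tree, tree).r == pytest.approx(1.0)

    def test_same_distances_same_tree(self):
        rng = np.random.default_rng(1)
        dm = distance_matrix(rng.normal(size=(12, 5)))
        t1 = hierarchical_cluster(dm)
        t2 = hierarchical_cluster(dm)
        assert cophenetic_correlation(t1, t2).r == pytest.approx(1.0)

    def test_uncorrelated_data_near_zero(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(6):
            t1 = hierarchical_cluster(distance_matrix(rng.normal(size=(40, 8))))
            t2 = hierarchical_cluster(distance_matrix(rng.normal(size=(40, 8))))
            rs.append(cophenetic_correlation(t1, t2).r)
        assert abs(np.mean(rs)) < 0.3

    def test_label_order_alignment(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        labels = list("abcdef")
        t1 = hierarchical_cluster(distance_matrix(X, labels))
        perm = [3, 1, 5, 0, 2, 4]
        t2 = hierarchical_cluster(distance_matrix(X[perm], [labels[i] for i in perm]))
        assert cophenetic_correlation(t1, t2).r == pytest.approx(1.0)

    def test_leaf_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        t1 = hierarchical_cluster(distance_matrix(rng.normal(size=(4, 3)), list("abcd")))
        t2 = hierarchical_cluster(distance_matrix(rng.normal(size=(4, 3)), list("abcx")))
        with pytest.raises(ValueError):
            cophenetic_correlation(t1, t2)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
    def test_against_r_hclust_oracle(self, tmp_path):
        """Independent oracle: R stats::hclust + cophenetic + cor."""
        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 6))
        t1 = hierarchical_cluster(distance_matrix(X))
        t2 = hierarchical_cluster(distance_matrix(Y))
        ours = cophenetic_correlation(t1, t2).r
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
        script = textwrap.dedent(
            """
            x <- as.matrix(read.csv("x.csv", header=FALSE))
            y <- as.matrix(read.csv("y.csv", header=FALSE))
            t1 <- hclust(dist(x), method="complete")
            t2 <- hclust(dist(y), method="complete")
            cat(cor(as.vector(cophenetic(t1)), as.vector(cophenetic(t2))))
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), abs=1e-6)


class TestAlphaSweep:
    def test_bounds_and_reproducibility(self):
        reps = dp.simulate_cohort(n_repertoires=12, n_reads=10**4, seed=3)
        X, labels = dp.frequency_matrix(reps)
        P = np.vstack([dp.diversity_profile(r.distribution).values for r in reps])
        res1 = alpha_sweep(X, P, [2, 10, 51], labels=labels)
        res2 = alpha_sweep(X, P, [2, 10, 51], labels=labels)
        assert [r.n_alphas_used for r in res1] == [2, 10, 51]
        for a, b in zip(res1, res2):
            assert -1.0 <= a.r <= 1.0
            assert a.r == b.r

    def test_two_shape_cohort_high_r(self):
        # a cohort of two clearly different distribution shapes (even vs
        # strongly expanded) plus replicate noise: distribution clustering
        # and full-profile clustering must agree on the split
        rng = np.random.default_rng(8)
        even = np.ones(30) / 30
        expanded = np.geomspace(1.0, 1e-4, 30)
        expanded /= expanded.sum()
        X = []
        for i in range(10):
            base = even if i < 5 else expanded
            f = base * np.exp(rng.normal(0, 0.05, 30))
            X.append(f / f.sum())
        X = np.array(X)
        dists = [dp.ClonalFrequencyDistribution.from_frequencies(x) for x in X]
        P = np.vstack([dp.diversity_profile(d).values for d in dists])
        res = alpha_sweep(X, P, [51])
        assert res[0].r > 0.6

    def test_invalid_n_alpha(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(20), size=6)
        P = rng.normal(size=(6, 51)) ** 2 + 1
        with pytest.raises(ValueError):
            alpha_sweep(X, P, [1])
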