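import subprocess
from itertools import combinations

import numpy as np
import pytest

from ramanid import ValidationError, cut_clusters, hca, pca
from ramanid.chemometrics import cophenetic_matrix, correlation_dissimilarity


class TestPca:
    def test_rank_one_data_pc1_explains_everything(self):
        v = np.linspace(0, 1, 20)
        X = np.outer([1.0, 2.0, 3.0, 4.0], v) + 5.0
        res = pca(X, n_components=1)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_eigenvalues_sum_to_total_variance(self):
        X = np.random.default_rng(0).normal(size=(12, 30))
        res = pca(X)
        assert res.eigenvalues.sum() == pytest.approx(X.var(axis=0, ddof=1).sum())
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(1).normal(size=(10, 25))
        res = pca(X, n_components=5)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-8)

    def test_reconstruction_with_all_components(self):
        X = np.random.default_rng(2).normal(size=(8, 5))
        res = pca(X)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_sample_order_invariance(self):
        X = np.random.default_rng(3).normal(size=(9, 12))
        perm = np.random.default_rng(4).permutation(9)
        res_a = pca(X, 3)
        res_b = pca(X[perm], 3)
        np.testing.assert_allclose(res_b.scores, res_a.scores[perm], atol=1e-8)
        np.testing.assert_allclose(res_b.eigenvalues, res_a.eigenvalues)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        X = np.random.default_rng(5).normal(size=(10, 40))
        res = pca(X, 4)
        sk = SkPCA(n_components=4).fit(X)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_, rtol=1e-10)

    def test_too_many_components_rejected(self):
        X = np.zeros((4, 10))
        with pytest.raises(Exception):
            pca(X, n_components=5)


def ward_oracle(d):
    """Independent Ward agglomeration: cluster distances from the centroid-form
    identity over raw pairwise dissimilarities, recomputed from scratch each
    merge (no Lance-Williams recurrence)."""
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []

    def delta(A, B):
        sAB = sum(d[a][b] for a in A for b in B) / (len(A) * len(B))
        sAA = sum(d[a][b] for a in A for b in A) / (2 * len(A) ** 2)
        sBB = sum(d[a][b] for a in B for b in B) / (2 * len(B) ** 2)
        return len(A) * len(B) / (len(A) + len(B)) * 2 * (sAB - sAA - sBB)

    while len(clusters) > 1:
        best = None
        for i, j in combinations(sorted(clusters), 2):
            v = delta(clusters[i], clusters[j])
            if best is None or v < best[0] - 1e-15:
                best = (v, i, j)
        v, i, j = best
        merges.append((i, j, v, len(clusters[i]) + len(clusters[j])))
        clusters[next_id] = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        next_id += 1
    return np.array(merges)


class TestHca:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 15))
        X[3] = X[1]
        res = hca(X)
        a, b, h, size = res.merge_tree[0]
        assert {int(a), int(b)} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_four_sample_merge_tree_equals_oracle(self, seed):
        X = np.random.default_rng(seed).normal(size=(4, 12))
        res = hca(X)
        Z = ward_oracle(correlation_dissimilarity(X))
        np.testing.assert_array_equal(res.merge_tree[:, :2], Z[:, :2])
        np.testing.assert_allclose(res.merge_tree[:, 2], Z[:, 2])

    def test_matches_r_hclust_ward_d(self, tmp_path):
        """Cross-check against R's hclust(method='ward.D') on 1-r dissimilarities."""
        X = np.random.default_rng(10).normal(size=(7, 20))
        d = correlation_dissimilarity(X)
        np.savetxt(tmp_path / "d.txt", d)
        r_code = (
            f'd <- as.matrix(read.table("{tmp_path}/d.txt"));'
            'h <- hclust(as.dist(d), method="ward.D");'
            'cat(paste(h$height, collapse=","))'
        )
        proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript unavailable: {proc.stderr[:100]}")
        r_heights = np.array([float(x) for x in proc.stdout.strip().split(",")])
        res = hca(X)
        np.testing.assert_allclose(np.sort(res.merge_tree[:, 2]), np.sort(r_heights),
                                   rtol=1e-10)

    def test_ward_heights_monotone(self):
        X = np.random.default_rng(7).normal(size=(10, 30))
        res = hca(X)
        assert np.all(np.diff(res.merge_tree[:, 2]) >= -1e-12)

    def test_zero_variance_row_rejected_by_name(self):
        X = np.random.default_rng(8).normal(size=(4, 10))
        X[2] = 3.0
        with pytest.raises(ValidationError, match="s2"):
            hca(X, labels=["s0", "s1", "s2", "s3"])

    def test_cophenetic_ultrametric(self):
        X = np.random.default_rng(9).normal(size=(8, 20))
        C = cophenetic_matrix(hca(X))
        np.testing.assert_allclose(C, C.T)
        n = C.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-10

    def test_scipy_agreement_for_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        X = np.random.default_rng(12).normal(size=(6, 18))
        d = correlation_dissimilarity(X)
        res = hca(X, linkage="average")
        ref = linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(res.merge_tree[:, 2], ref[:, 2])


class TestCutClusters:
    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(13).normal(size=(5, 10))
        res = hca(X)
        assert sorted(cut_clusters(res, 5).tolist()) == [0, 1, 2, 3, 4]

    def test_k_one_gives_single_cluster(self):
        X = np.random.default_rng(14).normal(size=(5, 10))
        assert set(cut_clusters(hca(X), 1).tolist()) == {0}

    def test_every_k_yields_exactly_k_nonempty_clusters(self):
        X = np.random.default_rng(15).normal(size=(9, 25))
        res = hca(X)
        for k in range(1, 10):
            groups = cut_clusters(res, k)
            assert len(set(groups.tolist())) == k

    def test_two_cluster_cut_matches_oracle_top_split(self):
        X = np.random.default_rng(16).normal(size=(4, 12))
        res = hca(X)
        Z = ward_oracle(correlation_dissimilarity(X))
        # removing the final merge splits into its two child subtrees
        members = {i: {i} for i in range(4)}
        for idx, (a, b, _, _) in enumerate(Z):
            members[4 + idx] = members[int(a)] | members[int(b)]
        left = members[int(Z[-1, 0])]
        got = cut_clusters(res, 2)
        split = {i for i in range(4) if got[i] == got[min(left)]}
        assert split == left or split == (set(range(4)) - left)

    def test_k_out_of_range(self):
        X = np.random.default_rng(17).normal(size=(4, 10))
        with pytest.raises(Exception):
            cut_clusters(hca(X), 0)
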