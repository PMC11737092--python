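"""Diversity, Bray-Curtis, within-site similarity, PCA, PERMANOVA, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefpls import (bray_curtis, bray_curtis_matrix, pca, permanova,
                     permanova_pairwise, shannon, wilcoxon_rank_sum,
                     within_site_similarity, DistanceMatrix)
from reefpls.community import CommunityStatsError, euclidean_matrix, pairwise_wilcoxon

from conftest import toy_count_table


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([0, 7, 0]) == 0.0

    def test_uniform_closed_form(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_uniform_is_maximal(self, x):
        k = len(x)
        assert shannon(x) <= shannon(np.ones(k)) + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(CommunityStatsError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0], [0, 2]) == 1.0

    def test_closed_form(self):
        assert bray_curtis([2, 2], [2, 0]) == pytest.approx(1 / 3)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.integers(0, 50, (2, 8))
        if a.sum() == 0 and b.sum() == 0:
            return
        d = bray_curtis(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(b, a))

    def test_invariant_to_library_rescaling_of_proportions(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, (2, 10)).astype(float)
        props = counts / counts.sum(axis=1, keepdims=True)
        scaled = counts * np.array([[3.0], [17.0]])
        props2 = scaled / scaled.sum(axis=1, keepdims=True)
        assert bray_curtis(props[0], props[1]) == pytest.approx(
            bray_curtis(props2[0], props2[1]))


class TestWithinSiteSimilarity:
    def test_design_counts(self, default_dataset):
        # 48 sites x 4 replicates -> 6 pairs each -> 288 values
        values, summary = within_site_similarity(default_dataset.taxa_counts,
                                                 "genus")
        assert summary["n_values"] == 288
        assert (values.groupby("site").size() == 6).all()

    def test_single_site_pair_count(self, default_dataset):
        t = default_dataset.taxa_counts
        one_site = t.samples.index[t.samples["site"] == "R001"]
        values, summary = within_site_similarity(t.restrict_samples(one_site),
                                                 "genus")
        assert summary["n_values"] == 6

    def test_identical_replicates_give_similarity_one(self):
        t = toy_count_table([[5, 5, 2]] * 3, sites=["A"] * 3,
                            lineages={"genus": ["g0", "g1", "g2"]})
        values, _ = within_site_similarity(t, "genus")
        np.testing.assert_allclose(values["similarity"], 1.0)

    def test_go_coarser_than_genus_on_redundant_data(self, default_dataset):
        """Functional profiles vary less within a reef than taxonomic ones."""
        _, genus = within_site_similarity(default_dataset.taxa_counts, "genus")
        _, go3 = within_site_similarity(default_dataset.go_counts, "rank3")
        assert go3["median"] >= genus["median"]


class TestPca:
    def test_explained_variance_sums_to_one_at_full_rank(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(10, 4)))
        res = pca(x, n_components=4)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_diagonal_cloud_loading(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=200)
        x = pd.DataFrame({"a": t, "b": t + rng.normal(0, 1e-3, 200)})
        load = pca(x, n_components=1).loadings["PC1"].to_numpy()
        np.testing.assert_allclose(np.abs(load), 1 / np.sqrt(2), atol=1e-3)

    def test_duplicating_samples_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(size=(12, 5)))
        l1 = pca(x, n_components=2).loadings.to_numpy()
        l2 = pca(pd.concat([x, x]), n_components=2).loadings.to_numpy()
        np.testing.assert_allclose(np.abs(l1), np.abs(l2), atol=1e-9)


class TestPermanova:
    def _two_clouds(self, sep, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n, 3)),
                         rng.normal(sep, 1, (n, 3))])
        table = pd.DataFrame(pts, index=[f"i{k}" for k in range(2 * n)])
        groups = ["a"] * n + ["b"] * n
        return euclidean_matrix(table), pd.Series(groups, index=table.index)

    def test_separated_clouds_minimal_p(self):
        d, g = self._two_clouds(sep=50.0)
        res = permanova(d, g, n_perm=199, seed=1)
        assert res["p"] == pytest.approx(1 / 200)
        assert res["R2"] > 0.9

    def test_matches_skbio_pseudo_f(self):
        skbio_dist = pytest.importorskip("skbio").DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        d, g = self._two_clouds(sep=2.0, seed=7)
        ours = permanova(d, g, n_perm=99, seed=0)
        sk = sk_permanova(skbio_dist(d.values.to_numpy(), ids=list(d.ids)),
                          list(g), permutations=99)
        assert ours["F"] == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_pairwise_count_and_bonferroni(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(20, 3))
        table = pd.DataFrame(pts, index=[f"i{k}" for k in range(20)])
        groups = pd.Series([f"g{k % 4}" for k in range(20)], index=table.index)
        out = permanova_pairwise(euclidean_matrix(table), groups,
                                 n_perm=99, seed=2)
        assert len(out) == 6  # C(4,2)
        np.testing.assert_allclose(out["p_adj"],
                                   np.minimum(out["p"] * 6, 1.0))

    def test_rejects_singleton_group(self):
        d, g = self._two_clouds(sep=1.0, n=2)
        g.iloc[0] = "c"
        with pytest.raises(CommunityStatsError):
            permanova(d, g, n_perm=9)


class TestWilcoxon:
    def test_exact_enumeration_value(self):
        # all 3 low ranks vs all 3 high ranks: 2 of C(6,3)=20 splits as extreme
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 12))
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(
            wilcoxon_rank_sum(y, x)[1])

    def test_batched_holm_adjustment(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [2, 3, 4]}
        out = pairwise_wilcoxon(groups, adjust="holm")
        assert len(out) == 3
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(CommunityStatsError):
            wilcoxon_rank_sum([], [1.0])


class TestDistanceContainers:
    def test_bray_curtis_matrix_properties(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(rng.integers(0, 50, (6, 9)).astype(float) + 1)
        d = bray_curtis_matrix(table)
        a = d.values.to_numpy()
        assert np.allclose(a, a.T) and np.all(np.diag(a) == 0)
        assert a.max() <= 1.0

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(Exception):
            DistanceMatrix(values=bad, metric="euclidean")
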