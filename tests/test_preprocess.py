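"""Filtering rules, proportions, CLR, collapsing, env aggregation/scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefpls import (CLRTransformer, aggregate_env_medians, clr_transform,
                     collapse, filter_features, relative_abundance,
                     scale_env_for_heatmap, EnvTable)
from reefpls.preprocess import PreprocessError, impute_env_by_trip_median

from conftest import toy_count_table


class TestFilterFeatures:
    def test_rare_threshold_on_grand_total(self):
        # grand total 10,000,000 reads: 5 reads = 5e-7 < 1e-6 removed,
        # 15 reads = 1.5e-6 kept
        counts = np.array([[5, 15, 9_999_980], [0, 0, 0]])[:1]
        t = toy_count_table(counts)
        out, report = filter_features(t, min_rel_abundance=1e-6)
        assert list(out.feature_ids) == ["f1", "f2"]
        rare = report[report["rule"] == "5:rare"]
        assert list(rare["feature_id"]) == ["f0"]
        assert rare["value"].iloc[0] == pytest.approx(5e-7)

    def test_clean_table_is_identity(self):
        t = toy_count_table([[100, 200], [300, 400]])
        out, report = filter_features(t)
        assert out.counts.equals(t.counts)
        assert report.empty

    def test_class_rules_remove_regardless_of_abundance(self):
        t = toy_count_table(
            [[10, 1_000_000, 10, 10, 10]],
            annotation=["bacteria", "virus", "eukaryote", "domain_only",
                        "unannotated"],
        )
        out, report = filter_features(t, min_rel_abundance=0)
        assert list(out.feature_ids) == ["f0"]
        assert set(report["rule"]) == {"2:eukaryote", "3:virus",
                                       "4:domain-level-only", "1:non-annotated"}

    def test_emptying_filter_raises_with_rule_name(self):
        t = toy_count_table([[5, 5]], annotation=["virus", "virus"])
        with pytest.raises(PreprocessError, match="class filter"):
            filter_features(t)
        t2 = toy_count_table([[1, 1, 10_000_000]],
                             annotation=["bacteria", "bacteria", "eukaryote"])
        with pytest.raises(PreprocessError, match="5:rare"):
            filter_features(t2, min_rel_abundance=0.75)

    def test_abundance_denominator_excludes_removed_classes(self):
        # after dropping the dominant virus feature the small feature's share
        # clears the threshold
        t = toy_count_table([[2, 8, 9_999_990]],
                            annotation=["bacteria", "bacteria", "virus"])
        out, _ = filter_features(t, min_rel_abundance=1e-6)
        assert list(out.feature_ids) == ["f0", "f1"]


class TestRelativeAbundance:
    @pytest.mark.parametrize("row,expected", [
        ([2, 2], [0.5, 0.5]),
        ([1, 3], [0.25, 0.75]),
    ])
    def test_known_rows(self, row, expected):
        t = toy_count_table([row])
        np.testing.assert_allclose(relative_abundance(t).iloc[0], expected)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = toy_count_table(rng.integers(1, 100, (6, 10)))
        sums = relative_abundance(t).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_zero_sum_sample_named(self):
        t = toy_count_table([[1, 2], [0, 0]])
        with pytest.raises(PreprocessError, match="s1"):
            relative_abundance(t)


class TestClr:
    def test_equal_parts_map_to_zero(self):
        t = toy_count_table([[10, 10, 10, 10]])
        np.testing.assert_allclose(clr_transform(t, 1.0).values.iloc[0], 0.0)

    def test_known_value(self):
        # [1, 3] + 1 -> ln 2 - ln sqrt(8), ln 4 - ln sqrt(8)
        t = toy_count_table([[1, 3]])
        got = clr_transform(t, 1.0).values.iloc[0].to_numpy()
        np.testing.assert_allclose(got, [-0.34657359, 0.34657359], atol=1e-8)

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_zero(self, row):
        t = toy_count_table([row])
        assert abs(clr_transform(t).values.iloc[0].sum()) < 1e-9

    def test_scale_invariance_at_tiny_pseudocount(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 500, (4, 8))
        a = clr_transform(toy_count_table(x), pseudocount=1e-9).values
        b = clr_transform(toy_count_table(7 * x), pseudocount=1e-9).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(PreprocessError):
            clr_transform(toy_count_table([[1, 2]]), pseudocount=0.0)

    def test_sklearn_transformer_matches_function(self):
        x = np.array([[1, 3], [10, 10]])
        got = CLRTransformer(pseudocount=1.0).fit_transform(x)
        want = clr_transform(toy_count_table(x)).values.to_numpy()
        np.testing.assert_allclose(got, want)


class TestCollapse:
    def _table(self):
        return toy_count_table(
            [[3, 4, 5]],
            lineages={"family": ["famA", "famA", "famB"],
                      "genus": ["g0", "g1", "g2"]},
        )

    def test_family_sums_members(self):
        out = collapse(self._table(), "family")
        assert out.counts.loc["s0", "famA"] == 7
        assert out.counts.loc["s0", "famB"] == 5

    def test_native_level_is_identity(self):
        t = self._table()
        out = collapse(t, "genus")
        assert sorted(out.feature_ids) == ["g0", "g1", "g2"]
        assert out.counts.to_numpy().sum() == t.counts.to_numpy().sum()

    def test_grand_total_conserved(self):
        t = self._table()
        for level in ("family", "genus"):
            assert (collapse(t, level).counts.to_numpy().sum()
                    == t.counts.to_numpy().sum())

    def test_unknown_level_rejected(self):
        with pytest.raises(PreprocessError, match="phylum"):
            collapse(self._table(), "phylum")

    def test_unresolved_features_grouped_under_sentinel(self):
        t = toy_count_table(
            [[1, 2]], lineages={"family": ["famA", None], "genus": ["g0", "g1"]})
        with pytest.warns(UserWarning, match="unresolved"):
            out = collapse(t, "family")
        assert out.counts.loc["s0", "unresolved_family"] == 2

    def test_commutes_with_relative_abundance(self, small_dataset):
        t = small_dataset.taxa_counts
        left = relative_abundance(collapse(t, "family"))
        rel = relative_abundance(t)
        fam = t.features["family"]
        right = rel.T.groupby(fam.values).sum().T
        np.testing.assert_allclose(left.to_numpy(),
                                   right[left.columns].to_numpy(), atol=1e-12)


class TestEnvAggregation:
    def test_median_of_replicates(self):
        rep = pd.DataFrame({"trip": "T1", "site": "A",
                            "NO3": [1.0, 2.0, 10.0]})
        env = aggregate_env_medians(rep)
        assert env.values.loc["A", "NO3"] == 2.0

    def test_single_replicate_passes_through(self):
        rep = pd.DataFrame({"trip": "T1", "site": "A", "NO3": [3.5]})
        assert aggregate_env_medians(rep).values.loc["A", "NO3"] == 3.5

    def test_all_missing_cell_stays_masked(self):
        rep = pd.DataFrame({"trip": "T1", "site": "A",
                            "NO3": [np.nan, np.nan]})
        assert np.isnan(aggregate_env_medians(rep).values.loc["A", "NO3"])

    def test_partial_missing_ignored(self):
        rep = pd.DataFrame({"trip": "T1", "site": "A",
                            "NO3": [np.nan, 4.0, 6.0]})
        assert aggregate_env_medians(rep).values.loc["A", "NO3"] == 5.0


class TestScaleEnv:
    def _env(self, col):
        values = pd.DataFrame({"v": col},
                              index=[f"R{i}" for i in range(len(col))])
        trips = pd.Series("T1", index=values.index)
        return EnvTable(values=values, trips=trips)

    def test_known_scaling(self):
        out = scale_env_for_heatmap(self._env([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out["v"], [-1.0, 0.0, 1.0])

    def test_constant_variable_rejected(self):
        with pytest.raises(PreprocessError, match="'v'"):
            scale_env_for_heatmap(self._env([2.0, 2.0, 2.0]))

    def test_output_median_zero(self):
        rng = np.random.default_rng(2)
        out = scale_env_for_heatmap(self._env(list(rng.normal(5, 2, 11))))
        assert abs(out["v"].median()) < 1e-12

    def test_missing_cells_propagate(self):
        out = scale_env_for_heatmap(self._env([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(out["v"].iloc[1])

    def test_trip_median_imputation(self):
        values = pd.DataFrame({"v": [1.0, np.nan, 10.0, 12.0]},
                              index=["a", "b", "c", "d"])
        trips = pd.Series(["T1", "T1", "T2", "T2"], index=values.index)
        imp = impute_env_by_trip_median(EnvTable(values=values, trips=trips))
        assert imp.values.loc["b", "v"] == 1.0
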