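"""Hydrologic clustering: standardization, K-means diagnostics, k selection,
permutation importance, ANOVA/LSD letters, descriptor-emission correlations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from paddyghg.clustering import (
    anova_lsd,
    descriptor_emission_correlations,
    feature_importance,
    kmeans_fit,
    select_k,
    standardize,
)
from paddyghg.descriptors import DESCRIPTOR_NAMES


def _blobs(centers, n_per=20, sd=0.5, seed=0, cols=None):
    rng = np.random.default_rng(seed)
    rows = []
    for c in centers:
        rows.append(rng.normal(c, sd, size=(n_per, len(c))))
    X = np.vstack(rows)
    cols = cols or [f"A{i+1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols,
                        index=[f"f{i:03d}" for i in range(len(X))])


class TestStandardize:
    def test_two_point_column(self):
        X = pd.DataFrame({"A1": [0.0, 100.0], "A2": [1.0, 3.0]})
        Z, sc = standardize(X)
        np.testing.assert_allclose(Z["A1"], [-np.sqrt(0.5), np.sqrt(0.5)])
        assert sc.sd["A1"] == pytest.approx(100 / np.sqrt(2))

    def test_constant_column_zeroed_with_warning(self):
        X = pd.DataFrame({"A1": [1.0, 2.0, 3.0], "A2": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="A2"):
            Z, _ = standardize(X)
        assert (Z["A2"] == 0).all()

    def test_idempotent(self):
        X = _blobs([(0, 0), (5, 5)])
        Z1, _ = standardize(X)
        Z2, _ = standardize(Z1)
        np.testing.assert_allclose(Z1.values, Z2.values, atol=1e-12)

    def test_missing_values_named(self):
        X = pd.DataFrame({"A1": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            standardize(X)


class TestKmeans:
    def test_two_separated_blobs(self):
        X = _blobs([(0, 0), (10, 10)], n_per=30)
        Z, sc = standardize(X)
        m = kmeans_fit(Z, 2, scaling=sc, seed=0)
        assert m.pseudo_r2 > 0.9
        assert m.mean_silhouette > 0.6

    def test_k_equals_n_gives_perfect_fit(self):
        X = _blobs([(0, 0), (5, 5)], n_per=3, sd=0.3)
        Z, sc = standardize(X)
        assert kmeans_fit(Z, len(Z), scaling=sc).pseudo_r2 == pytest.approx(1.0)

    def test_k_one_explains_nothing(self):
        X = _blobs([(0, 0)], n_per=20)
        Z, sc = standardize(X)
        assert kmeans_fit(Z, 1, scaling=sc).pseudo_r2 == pytest.approx(0.0, abs=1e-9)

    def test_pseudo_r2_nondecreasing_in_k(self, dry_descriptors):
        Z, sc = standardize(dry_descriptors)
        r2 = [kmeans_fit(Z, k, restarts=20, scaling=sc, seed=0).pseudo_r2
              for k in range(1, 7)]
        assert all(a <= b + 1e-9 for a, b in zip(r2, r2[1:]))

    def test_labels_ordered_driest_to_wettest(self, dry_landscape, dry_descriptors):
        Z, sc = standardize(dry_descriptors)
        m = kmeans_fit(Z, 5, scaling=sc, seed=0)
        mean_a1 = dry_descriptors["A1"].groupby(m.assignments).mean()
        assert list(mean_a1.sort_values().index) == [1, 2, 3, 4, 5]

    def test_row_permutation_stability(self, dry_descriptors):
        Z, sc = standardize(dry_descriptors)
        base = kmeans_fit(Z, 5, restarts=20, scaling=sc, seed=0).assignments
        rng = np.random.default_rng(0)
        perm = Z.sample(frac=1.0, random_state=1)
        shuffled = kmeans_fit(perm, 5, restarts=20, scaling=sc, seed=0).assignments
        assert (shuffled.loc[base.index] == base).all()


class TestSelectK:
    def test_two_blobs_pick_two(self):
        X = _blobs([(0, 0, 0), (8, 8, 8)], n_per=25)
        Z, sc = standardize(X)
        k, _ = select_k(Z, range(2, 7), restarts=20, scaling=sc)
        assert k == 2

    def test_single_blob_ties_break_small(self):
        X = _blobs([(0.0, 0.0)], n_per=40, sd=1.0)
        Z, sc = standardize(X)
        k, sils = select_k(Z, range(2, 6), restarts=20, scaling=sc)
        # silhouette is nearly flat on structureless data; any feasible k can
        # edge ahead, but a clear preference for high k would be a bug
        assert k == sils.dropna().idxmax() or np.isnan(sils[k])

    @pytest.mark.parametrize("fixture", ["dry", "wet"])
    def test_five_archetype_recovery(self, fixture, request, dry_landscape,
                                     wet_landscape, dry_descriptors, wet_descriptors):
        land = dry_landscape if fixture == "dry" else wet_landscape
        X = dry_descriptors if fixture == "dry" else wet_descriptors
        Z, sc = standardize(X)
        k, _ = select_k(Z, scaling=sc, seed=0)
        assert k == 5
        m = kmeans_fit(Z, 5, scaling=sc, seed=0)
        ari = adjusted_rand_score(land.true_archetype[m.assignments.index],
                                  m.assignments)
        assert ari > 0.9

    def test_infeasible_range_raises(self):
        X = _blobs([(0, 0)], n_per=4)
        Z, sc = standardize(X)
        with pytest.raises(ValueError, match="no feasible k"):
            select_k(Z, [3, 4], restarts=5, scaling=sc, min_size=3)


class TestFeatureImportance:
    def test_constant_descriptor_unimportant(self):
        X = _blobs([(0, 0), (8, 8)], n_per=20)
        X["A3"] = 1.0
        with pytest.warns(UserWarning):
            Z, sc = standardize(X)
        m = kmeans_fit(Z, 2, scaling=sc)
        imps = feature_importance(m, Z, permutations=50, seed=0)
        assert imps["A3"] == 0.0

    def test_informative_dimension_dominates(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (60, 4)), columns=list("ABCD"))
        X.iloc[30:, 0] += 10  # only column A separates the groups
        Z, sc = standardize(X)
        m = kmeans_fit(Z, 2, scaling=sc)
        imps = feature_importance(m, Z, permutations=100, seed=0)
        assert imps.idxmax() == "A"

    def test_stable_across_permutation_seeds(self, dry_descriptors):
        Z, sc = standardize(dry_descriptors)
        m = kmeans_fit(Z, 5, restarts=20, scaling=sc, seed=0)
        a = feature_importance(m, Z, permutations=200, seed=1)
        b = feature_importance(m, Z, permutations=200, seed=2)
        assert (a - b).abs().max() < 0.02


class TestAnovaLsd:
    def test_identical_groups_share_letter(self):
        values = pd.Series([5.0] * 12)
        groups = pd.Series([1] * 4 + [2] * 4 + [3] * 4)
        res = anova_lsd(values, groups)
        assert set(res.letters) == {"a"}

    def test_far_apart_groups_differ(self):
        rng = np.random.default_rng(0)
        values = pd.Series(np.r_[rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
        groups = pd.Series([1] * 10 + [2] * 10)
        res = anova_lsd(values, groups)
        assert res.p_value < 1e-10
        assert set(res.letters[1]) & set(res.letters[2]) == set()

    def test_overlapping_middle_group_bridges(self):
        # deterministic fixture: identical within-group pattern (sd = 2) so
        # the pooled LSD half-width (~1.66) separates the 3.0 gap between
        # the extremes but not the 1.5 gaps to the middle group -> a / ab / b
        pattern = (np.arange(12) - 5.5) * 2 / np.std(np.arange(12) - 5.5, ddof=1)
        values = pd.Series(np.r_[pattern, 1.5 + pattern, 3.0 + pattern])
        groups = pd.Series([1] * 12 + [2] * 12 + [3] * 12)
        res = anova_lsd(values, groups)
        lo, mid, hi = res.letters[1], res.letters[2], res.letters[3]
        assert set(hi) & set(mid) and set(mid) & set(lo)
        assert set(hi) & set(lo) == set()

    def test_singleton_cluster_excluded(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 99.0])
        groups = pd.Series([1, 1, 2, 2, 3])
        with pytest.warns(UserWarning, match="single member"):
            res = anova_lsd(values, groups)
        assert 3 not in res.means.index

    def test_cluster_emissions_differ_on_landscape(self, dry_landscape,
                                                   dry_descriptors):
        Z, sc = standardize(dry_descriptors)
        m = kmeans_fit(Z, 5, restarts=20, scaling=sc, seed=0)
        emis = dry_landscape.emissions.set_index("field_id")["ch4_kg_ha"]
        res = anova_lsd(emis, m.assignments)
        assert res.p_value < 0.001
        # wettest and driest clusters must not share a letter
        assert set(res.letters[5]) & set(res.letters[1]) == set()


class TestCorrelations:
    def test_perfect_monotone_linear_relation(self):
        X = pd.DataFrame({"A1": np.arange(10.0)},
                         index=[f"f{i}" for i in range(10)])
        emis = pd.DataFrame({
            "field_id": X.index,
            "ch4_kg_ha": 3.0 * X["A1"].values + 1.0,
            "n2o_g_ha": np.ones(10),
        })
        out = descriptor_emission_correlations(X, emis)
        assert out.loc["A1", "ch4"] == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(out.loc["A1", "n2o"])  # constant gas -> undefined

    def test_constant_descriptor_reported_missing(self):
        X = pd.DataFrame({"A1": np.arange(5.0), "A2": np.ones(5)},
                         index=[f"f{i}" for i in range(5)])
        emis = pd.DataFrame({"field_id": X.index,
                             "ch4_kg_ha": np.arange(5.0),
                             "n2o_g_ha": np.arange(5.0)[::-1]})
        out = descriptor_emission_correlations(X, emis)
        assert np.isnan(out.loc["A2", "ch4"]) and out.loc["A2", "ch4"] != 0

    def test_too_few_matches_rejected(self):
        X = pd.DataFrame({"A1": [1.0, 2.0]}, index=["a", "b"])
        emis = pd.DataFrame({"field_id": ["a", "b"],
                             "ch4_kg_ha": [1.0, 2.0], "n2o_g_ha": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 matched"):
            descriptor_emission_correlations(X, emis)

    def test_flooding_beats_deep_drainage_for_ch4(self, dry_landscape,
                                                  dry_descriptors):
        # A1 is the surrogate's causal driver; B3 (a share of drained days
        # only) carries far weaker, composition-dependent signal
        out = descriptor_emission_correlations(dry_descriptors,
                                               dry_landscape.emissions)
        assert out.loc["A1", "ch4"] > 0.6
        assert out.loc["A1", "ch4"] > out.loc["B3", "ch4"] + 0.3
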