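import numpy as np
import pytest

import grain3d as g
from grain3d.analysis import (crossval_classify, error_metrics, feature_importance,
                              pearson_matrix, zscore)


class TestZscore:
    def test_three_value_column_hand_arithmetic(self):
        out = zscore(np.array([[1.0], [2.0], [3.0]]))
        # population sd = sqrt(2/3)
        np.testing.assert_allclose(out.values.ravel(),
                                   [-1.2247448714, 0.0, 1.2247448714], atol=1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        out = zscore(np.column_stack([np.arange(5.0), np.full(5, 7.0)]))
        assert out.zero_variance_columns == [1]
        assert np.all(out.values[:, 1] == 0.0)

    def test_columns_standardised(self):
        rng = np.random.default_rng(0)
        out = zscore(rng.uniform(5, 50, (200, 6)))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-9
        assert np.abs(out.values.std(axis=0) - 1).max() < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = zscore(rng.normal(3, 5, (100, 4))).values
        twice = zscore(once).values
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            zscore(np.ones((1, 3)))


class TestPearsonMatrix:
    def test_exact_linear_relationships(self):
        x = np.arange(10.0)
        r = pearson_matrix(np.column_stack([x, 2 * x + 1, -x]))
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        r = pearson_matrix(rng.standard_normal((1000, 5)))
        off = r[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_shape_symmetry_diagonal_and_range(self):
        rng = np.random.default_rng(3)
        r = pearson_matrix(rng.uniform(0, 1, (50, 7)))
        assert r.shape == (7, 7)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
        assert np.abs(r).max() <= 1.0

    def test_zero_variance_column_flagged_as_zero(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        r = pearson_matrix(X)
        assert r[0, 1] == 0.0 and r[1, 1] == 1.0

    def test_invariant_under_positive_affine_maps(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (300, 4))
        Y = X * [2.0, 5.0, 0.1, 7.0] + [1, -3, 10, 0]
        np.testing.assert_allclose(pearson_matrix(X), pearson_matrix(Y), atol=1e-12)


class TestErrorMetrics:
    def test_perfect_agreement(self):
        em = error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert em.mape_pct == 0.0 and em.rmse == 0.0 and em.r2 == 1.0

    def test_worked_example(self):
        em = error_metrics([10.0, 20.0], [11.0, 19.0])
        assert em.mape_pct == pytest.approx(7.5, abs=1e-12)
        assert em.rmse == pytest.approx(1.0, abs=1e-12)
        assert em.r2 == pytest.approx(0.96, abs=1e-12)

    def test_single_pair(self):
        em = error_metrics([10.0], [12.0])
        assert em.mape_pct == pytest.approx(20.0)
        assert em.rmse == pytest.approx(2.0)
        assert em.n == 1

    def test_zero_denominator_flagged(self):
        # all manual values equal the system mean -> denominator vanishes
        em = error_metrics([10.0, 10.0], [8.0, 12.0])
        assert not em.r2_defined
        assert np.isnan(em.r2)

    def test_zero_manual_value_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([0.0, 1.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([1.0, 2.0], [1.0])


def _separable(n_per=100, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, 25)), rng.normal(sep, 1, (n_per, 25))])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestCrossvalClassify:
    @pytest.mark.parametrize("method", ["cart", "rf", "svm", "nb", "xgboost"])
    def test_separable_clusters_near_perfect(self, method):
        X, y = _separable()
        rep = crossval_classify(X, y, method, seed=1)
        assert rep.accuracy_pct >= 99.0
        assert len(rep.fold_accuracies) == 10
        assert all(0 <= a <= 100 for a in rep.fold_accuracies)

    def test_bp_network_on_separable_clusters(self):
        X, y = _separable(n_per=50)
        rep = crossval_classify(X, y, "bp", seed=1)
        assert rep.accuracy_pct >= 99.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 25))
        y = rng.permutation(np.array(["a"] * 100 + ["b"] * 100))
        rep = crossval_classify(X, y, "cart", seed=2)
        assert 40.0 <= rep.accuracy_pct <= 60.0

    def test_deterministic_given_seed(self):
        df = g.make_trait_dataset(n_per_class=30, seed=3)
        X = zscore(df[list(g.TRAIT_NAMES)].to_numpy())
        y = df["label"].to_numpy()
        a = crossval_classify(X, y, "xgboost", seed=9)
        b = crossval_classify(X, y, "xgboost", seed=9)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        assert a.precision_pct == b.precision_pct
        assert a.importance == b.importance

    def test_single_class_rejected(self):
        X = np.random.default_rng(6).normal(0, 1, (30, 5))
        with pytest.raises(ValueError):
            crossval_classify(X, np.array(["a"] * 30), "cart", seed=0)

    def test_small_class_rejected(self):
        X = np.random.default_rng(7).normal(0, 1, (25, 5))
        y = np.array(["a"] * 20 + ["b"] * 5)
        with pytest.raises(ValueError):
            crossval_classify(X, y, "cart", seed=0)

    def test_unknown_method_rejected(self):
        X, y = _separable(20)
        with pytest.raises(ValueError):
            crossval_classify(X, y, "forest_of_doom", seed=0)


class TestFeatureImportance:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((200, 25))
        y = np.where(X[:, 2] > 0, "thick", "thin")  # column 2 = thickness stand-in
        names = [f"t{i}" for i in range(25)]
        names[2] = "thickness"
        rep = crossval_classify(X, y, "xgboost", seed=3, feature_names=names)
        ranked = feature_importance(rep)
        assert ranked[0][0] == "thickness"
        assert sum(w for _, w in ranked) == pytest.approx(1.0, abs=1e-6)
        assert all(w >= 0 for _, w in ranked)
        assert feature_importance(rep, threshold=0.04)[0][0] == "thickness"

    def test_pure_noise_has_no_dominant_feature_on_average(self):
        maxima = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((120, 25))
            y = np.array(["a", "b"] * 60)
            rep = crossval_classify(X, y, "rf", seed=seed)
            maxima.append(feature_importance(rep)[0][1])
        assert np.mean(maxima) < 3.0 / 25.0

    def test_method_without_importance_rejected(self):
        X, y = _separable(20)
        rep = crossval_classify(X, y, "svm", seed=0)
        with pytest.raises(ValueError):
            feature_importance(rep)

    def test_thickness_dominates_simulated_grain_table(self):
        df = g.make_trait_dataset(n_per_class=60, seed=4)
        X = zscore(df[list(g.TRAIT_NAMES)].to_numpy())
        rep = crossval_classify(X, df["label"].to_numpy(), "xgboost", seed=4,
                                feature_names=list(g.TRAIT_NAMES))
        top = feature_importance(rep)[0][0]
        thickness_family = {"thickness", "length_thickness_ratio",
                            "width_thickness_ratio", "surface_thickness_ratio",
                            "volume_thickness_ratio", "specific_surface_area"}
        assert top in thickness_family
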