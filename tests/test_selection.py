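"""Feature standardization, ranking methods, count search, cutoff,
correlation report."""

import numpy as np
import pytest

from crferad.selection import (
    SelectionConfig,
    apply_cutoff,
    choose_feature_count,
    correlation_cluster_report,
    rank_features,
    standardize_features,
)


class TestStandardize:
    def test_two_point_column(self):
        x = np.array([[2.0, 5.0], [4.0, 5.0]])
        with pytest.warns(UserWarning):
            std, scaler, keep = standardize_features(x)
        assert list(keep) == [0]
        assert np.allclose(std[:, 0], [-1.0, 1.0])

    def test_train_fitted_scaler_zero_means(self, rng):
        x = rng.normal(3, 2, size=(20, 50))
        std, scaler, keep = standardize_features(x)
        assert np.allclose(std.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(std.var(axis=0), 1, atol=1e-6)
        held_out = rng.normal(3, 2, size=(5, 50))
        assert scaler.transform(held_out[:, keep]).shape == (5, 50)


class TestRankFeatures:
    def test_label_copy_feature_dominates_anova(self, rng):
        y = rng.integers(0, 2, size=60)
        x = rng.normal(size=(60, 50))
        x[:, 17] = y  # exact copy of the class label
        order, scores = rank_features(x, y, "anova_f")
        assert order[0] == 17

    def test_anova_f_hand_computed(self):
        # groups {1,2,3} vs {4,5,6}: F = 13.5
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        from sklearn.feature_selection import f_classif

        f_stat, _ = f_classif(x, y)
        assert f_stat[0] == pytest.approx(13.5)
        order, scores = rank_features(x.repeat(2, axis=1), y, "anova_f")
        assert len(order) == 2 and scores.sum() == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 2, size=40)
        x = rng.normal(size=(40, 20))
        x[:, :3] += y[:, None]
        order1, _ = rank_features(x, y, "anova_f")
        perm = rng.permutation(40)
        order2, _ = rank_features(x[perm], y[perm], "anova_f")
        assert np.array_equal(order1, order2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_features(rng.normal(size=(10, 4)), np.zeros(10), "anova_f")

    @pytest.mark.parametrize("method", ["model_importance", "rfe"])
    def test_forest_methods_find_planted_features(self, method, rng):
        y = rng.integers(0, 2, size=120)
        x = rng.normal(size=(120, 30))
        x[:, :3] += 2.0 * y[:, None]
        order, scores = rank_features(x, y, method, SelectionConfig(seed=1))
        assert set(order[:5]) >= {0, 1, 2}
        assert scores.sum() == pytest.approx(1.0)


class TestChooseCount:
    def test_singleton_grid(self, rng):
        y = rng.integers(0, 2, size=40)
        x = rng.normal(size=(40, 12))
        x[:, 0] += 2 * y
        cfg = SelectionConfig(count_grid=(5,), seed=0, n_estimators=50)
        chosen, curve = choose_feature_count(x, y, cfg)
        assert chosen == 5 and set(curve) == {5}

    def test_plateau_at_informative_count(self, rng):
        y = rng.integers(0, 2, size=150)
        x = rng.normal(size=(150, 100))
        x[:, :10] += 1.5 * y[:, None]
        cfg = SelectionConfig(count_grid=(5, 10, 20, 40), seed=0, n_estimators=50)
        chosen, curve = choose_feature_count(x, y, cfg)
        assert chosen <= 20


class TestApplyCutoff:
    def test_cutoff_drops_tail(self):
        scores = np.array([0.5, 0.3, 0.15, 0.005, 0.045])
        order = np.argsort(-scores)
        res = apply_cutoff(order, scores, [f"f{i}" for i in range(5)],
                           SelectionConfig(importance_cutoff=0.01))
        assert res.selected_names == ["f0", "f1", "f2", "f4"]

    def test_max_keep_caps_at_thirty(self):
        scores = np.full(100, 1 / 100)
        order = np.arange(100)
        res = apply_cutoff(order, scores, [f"f{i}" for i in range(100)],
                           SelectionConfig(importance_cutoff=0.001))
        assert len(res.selected_names) == 30

    def test_cutoff_one_keeps_nothing(self):
        scores = np.array([0.6, 0.4])
        res = apply_cutoff(np.array([0, 1]), scores, ["a", "b"],
                           SelectionConfig(importance_cutoff=1.0))
        assert res.selected_names == []


class TestCorrelationReport:
    def test_duplicated_feature_merges_first(self, rng):
        base = rng.normal(size=(200, 3))
        x = np.column_stack([base, base[:, 0]])
        corr, names, order = correlation_cluster_report(x, ["a", "b", "c", "a2"])
        assert corr[0, 3] == pytest.approx(1.0)
        # the duplicated pair must be adjacent in the dendrogram leaf order
        assert abs(order.index(0) - order.index(3)) == 1

    def test_independent_features_low_offdiagonal(self, rng):
        x = rng.normal(size=(1000, 8))
        corr, _, _ = correlation_cluster_report(x, list("abcdefgh"))
        off = corr[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.11

    def test_anticorrelated_pair(self, rng):
        a = rng.normal(size=300)
        corr, _, _ = correlation_cluster_report(
            np.column_stack([a, -a, rng.normal(size=300)]), ["x", "negx", "z"]
        )
        assert corr[0, 1] == pytest.approx(-1.0)
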