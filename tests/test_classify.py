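"""Label encoding, SMOTE, grid-searched classifiers, evaluation, ROC."""

import numpy as np
import pytest

from crferad.classify import (
    ClassifierSpec,
    DEFAULT_GRIDS,
    encode_pathology,
    evaluate,
    fit_with_grid,
    roc_curves,
    smote_balance,
)
from crferad.phantom import CATEGORY_NAMES, PathologyLabel


class TestEncodePathology:
    def test_table_rows(self):
        assert encode_pathology(0, 0, 0) == 0
        assert CATEGORY_NAMES[0] == "Small-cell keratinizing squamous cell carcinoma"
        assert encode_pathology(1, 1, 0) == 6
        assert CATEGORY_NAMES[6] == "Large-cell non-keratinizing squamous cell carcinoma"

    def test_bijection_over_all_triples(self):
        cats = {
            encode_pathology(c, k, h)
            for c in (0, 1) for k in (0, 1) for h in (0, 1)
        }
        assert cats == set(range(8))
        for cat in range(8):
            lab = PathologyLabel.from_category(cat)
            assert encode_pathology(lab.cell_size, lab.keratinization, lab.histology) == cat

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            encode_pathology(2, 0, 0)


class TestSmote:
    def test_balances_to_majority(self, rng):
        x = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(5, 1, (10, 3))])
        y = np.array([0] * 50 + [1] * 10)
        xb, yb = smote_balance(x, y, seed=0)
        counts = dict(zip(*np.unique(yb, return_counts=True)))
        assert counts == {0: 50, 1: 50}
        # originals preserved verbatim
        assert np.array_equal(xb[:60], x)

    def test_already_balanced_noop(self, rng):
        x = rng.normal(size=(20, 4))
        y = np.array([0] * 10 + [1] * 10)
        xb, yb = smote_balance(x, y, seed=0)
        assert np.array_equal(xb, x) and np.array_equal(yb, y)

    def test_synthetic_rows_on_neighbor_segments(self, rng):
        x = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(8, 0.5, (5, 2))])
        y = np.array([0] * 40 + [1] * 5)
        xb, yb = smote_balance(x, y, seed=1)
        synth = xb[45:][yb[45:] == 1]
        minority = x[40:]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (synth >= lo - 1e-9).all() and (synth <= hi + 1e-9).all()

    def test_singleton_class_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="1"):
            smote_balance(x, y)


class TestFitWithGrid:
    def test_rf_grid_cardinality(self):
        g = DEFAULT_GRIDS["random_forest"]
        assert len(g["n_estimators"]) * len(g["max_depth"]) * len(g["min_samples_split"]) == 48

    def test_singleton_grid_returned(self, rng):
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] > 0).astype(int)
        spec = ClassifierSpec(grid={"n_estimators": [37]}, seed=0)
        _, best, _ = fit_with_grid(x, y, spec)
        assert best == {"n_estimators": 37}

    def test_separable_toy_perfect_cv(self, rng):
        x = np.vstack([rng.normal(-4, 0.3, (25, 2)), rng.normal(4, 0.3, (25, 2))])
        y = np.array([0] * 25 + [1] * 25)
        spec = ClassifierSpec(grid={"n_estimators": [20]}, seed=0)
        _, _, cv = fit_with_grid(x, y, spec)
        assert max(cv["mean_test_score"]) == 1.0

    @pytest.mark.parametrize("family", ["gradient_boosting", "svm", "logistic_regression"])
    def test_other_families_fit_and_predict(self, family, rng):
        x = np.vstack([rng.normal(-2, 1, (30, 3)), rng.normal(2, 1, (30, 3))])
        y = np.array([3] * 30 + [6] * 30)  # non-contiguous labels
        grid = {k: v[:1] for k, v in DEFAULT_GRIDS[family].items()}
        model, _, _ = fit_with_grid(x, y, ClassifierSpec(family=family, grid=grid, seed=0))
        pred = model.predict(x)
        assert set(pred) <= {3, 6}
        assert (pred == y).mean() > 0.9


class TestEvaluate:
    def _const_model(self, classes, preds):
        class M:
            classes_ = np.array(classes)

            def predict(self, x):
                return np.array(preds[: len(x)])

        return M()

    def test_binary_hand_confusion(self):
        # TP=8, FP=2, FN=4, TN=6 for class 1
        truth = np.array([1] * 12 + [0] * 8)
        preds = [1] * 8 + [0] * 4 + [1] * 2 + [0] * 6
        rep = evaluate(self._const_model([0, 1], preds), np.zeros((20, 1)), truth)
        pc = rep.per_class[1]
        assert pc["precision"] == pytest.approx(0.8)
        assert pc["recall"] == pytest.approx(2 / 3)
        assert pc["f1"] == pytest.approx(8 / 11)

    def test_perfect_predictions(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        rep = evaluate(self._const_model([0, 1, 2], list(truth)), np.zeros((6, 1)), truth)
        assert rep.accuracy == rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0
        assert np.trace(rep.confusion_matrix) == 6

    def test_f1_identity_on_random_confusions(self, rng):
        for _ in range(100):
            tp, fp, fn = rng.integers(0, 20, size=3)
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            harmonic = (2 * precision * recall / (precision + recall)
                        if precision + recall else 0.0)
            direct = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            assert harmonic == pytest.approx(direct)

    def test_class_absent_from_training_recall_zero(self):
        truth = np.array([6, 6, 7, 7])
        preds = [6, 6, 6, 6]  # model trained without class 7
        rep = evaluate(self._const_model([4, 6], preds), np.zeros((4, 1)), truth)
        assert rep.per_class[7]["recall"] == 0.0
        assert rep.confusion_matrix[rep.classes.index(7), rep.classes.index(7)] == 0

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            evaluate(self._const_model([0], []), np.zeros((0, 1)), np.array([]))


class TestRoc:
    class _ScoreModel:
        classes_ = np.array([0, 1])

        def __init__(self, scores):
            self._s = scores

        def predict_proba(self, x):
            return self._s[: len(x)]

    def test_perfect_scores_auc_one(self):
        y = np.array([0, 0, 1, 1])
        scores = np.column_stack([1 - y, y]).astype(float)
        out = roc_curves(self._ScoreModel(scores), np.zeros((4, 1)), y)
        assert out[1][2] == 1.0

    def test_sign_reversal_antisymmetry(self, rng):
        y = rng.integers(0, 2, size=200)
        s = rng.random(200)
        m1 = self._ScoreModel(np.column_stack([1 - s, s]))
        m2 = self._ScoreModel(np.column_stack([s, 1 - s]))
        a1 = roc_curves(m1, np.zeros((200, 1)), y)[1][2]
        a2 = roc_curves(m2, np.zeros((200, 1)), y)[1][2]
        assert a1 + a2 == pytest.approx(1.0)

    def test_label_independent_scores_auc_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        s = rng.random(2000)
        auc = roc_curves(self._ScoreModel(np.column_stack([1 - s, s])),
                         np.zeros((2000, 1)), y)[1][2]
        assert abs(auc - 0.5) < 0.05

    def test_single_class_truth_flagged_undefined(self, rng):
        y = np.ones(10, dtype=int)
        s = rng.random(10)
        out = roc_curves(self._ScoreModel(np.column_stack([1 - s, s])),
                         np.zeros((10, 1)), y)
        assert out[1] == (None, None, None)
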