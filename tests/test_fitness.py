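import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssdfs.fitness import (
    ConfusionCounts,
    FeatureMask,
    KnnConfig,
    MaskEvaluator,
    UndefinedMetricError,
    classification_error,
    evaluate_mask,
    exhaustive_oracle,
    knn_predict,
    precision_recall,
)
from ssdfs.tabular import LabeledTable, SplitPair


def _split(train_X, train_y, test_X, test_y):
    names = [f"f{j}" for j in range(np.asarray(train_X).shape[1])]
    return SplitPair(
        LabeledTable(np.asarray(train_X, float), train_y, names),
        LabeledTable(np.asarray(test_X, float), test_y, list(names)),
    )


class TestKnnPredict:
    def test_nearest_cluster_wins(self):
        split = _split(
            [[0, 0]] * 3 + [[10, 10]] * 3, [0, 0, 0, 1, 1, 1], [[9, 9]], [1]
        )
        pred = knn_predict(split.train, split.test.features,
                           FeatureMask([1, 1]), KnnConfig(k=1))
        assert pred.tolist() == [1]

    def test_constant_column_falls_back_to_majority(self):
        # all train rows equidistant under the constant feature;
        # stable tie-break keeps the first k rows -> majority of those
        split = _split(
            [[1.0, 0], [1.0, 1], [1.0, 2], [1.0, 3], [1.0, 4]],
            [0, 0, 0, 1, 1],
            [[1.0, 99]],
            [0],
        )
        pred = knn_predict(split.train, split.test.features,
                           FeatureMask([1, 0]), KnnConfig(k=5))
        assert pred.tolist() == [0]

    def test_train_on_train_is_exact_for_1nn(self, small_split):
        mask = FeatureMask([1] * small_split.train.n_features)
        pred = knn_predict(small_split.train, small_split.train.features,
                           mask, KnnConfig(k=1))
        assert (pred == small_split.train.labels).all()

    def test_empty_mask_and_oversized_k_rejected(self, small_split):
        with pytest.raises(ValueError, match="no features"):
            knn_predict(small_split.train, small_split.test.features,
                        FeatureMask([0] * small_split.train.n_features))
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(small_split.train, small_split.test.features,
                        FeatureMask([1] * small_split.train.n_features),
                        KnnConfig(k=1001))

    def test_agrees_with_sklearn_on_tie_free_data(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.standard_normal((60, 5))
        y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0).astype(int)
        Xt = rng.standard_normal((20, 5))
        split = _split(X, y, Xt, np.zeros(20, int))
        mask = FeatureMask([1, 1, 0, 1, 0])
        mine = knn_predict(split.train, Xt, mask, KnnConfig(k=5))
        ref = (
            KNeighborsClassifier(n_neighbors=5)
            .fit(X[:, mask.selected_indices], y)
            .predict(Xt[:, mask.selected_indices])
        )
        np.testing.assert_array_equal(mine, ref)


class TestMetrics:
    def test_error_from_counts(self):
        alpha, counts = classification_error([1, 1, 1, 0, 0, 0, 0, 1, 0, 0],
                                             [1, 1, 1, 0, 0, 0, 0, 0, 1, 0])
        assert counts == ConfusionCounts(TP=3, TN=5, FP=1, FN=1)
        assert alpha == pytest.approx(0.2)

    def test_perfect_and_inverted_predictions(self):
        y = [0, 1, 0, 1]
        assert classification_error(y, y)[0] == 0.0
        assert classification_error([1 - v for v in y], y)[0] == 1.0

    def test_precision_recall_arithmetic(self):
        prec, rec = precision_recall(ConfusionCounts(TP=3, TN=0, FP=2, FN=1))
        assert prec == pytest.approx(0.6)
        assert rec == pytest.approx(0.75)

    def test_zero_denominators_are_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            precision_recall(ConfusionCounts(TP=0, TN=5, FP=0, FN=2))
        with pytest.raises(UndefinedMetricError):
            precision_recall(ConfusionCounts(TP=0, TN=5, FP=2, FN=0))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_error([], [])


class TestEvaluateMask:
    def test_w_one_collapses_to_error(self, small_split):
        mask = FeatureMask([1] * small_split.train.n_features)
        fv = evaluate_mask(mask, small_split, w=1.0)
        assert fv.fitness == pytest.approx(fv.error_alpha, abs=1e-15)

    def test_empty_mask_worst_fitness(self, small_split):
        fv = evaluate_mask(FeatureMask([0] * small_split.train.n_features),
                           small_split)
        assert fv.fitness == 1.0
        assert fv.error_alpha is None

    def test_identity_holds_to_machine_precision(self, small_split):
        ev = MaskEvaluator(small_split, KnnConfig(k=5), w=0.2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = FeatureMask((rng.random(ev.d) < 0.5).astype(int))
            if mask.selected_count == 0:
                continue
            fv = ev(mask)
            expect = 0.2 * fv.error_alpha + 0.8 * mask.selected_count / ev.d
            assert abs(fv.fitness - expect) < 1e-12
            assert 0.0 <= fv.fitness <= 1.0

    def test_memoized_reevaluation_is_identical_and_free(self, small_split):
        ev = MaskEvaluator(small_split)
        mask = FeatureMask([1, 0] * (ev.d // 2))
        first = ev(mask)
        n = ev.n_evaluations
        assert ev(mask) is first
        assert ev.n_evaluations == n

    @settings(derandomize=True, max_examples=50)
    @given(alpha=st.floats(0, 1), s=st.integers(1, 128),
           w=st.floats(0.001, 0.999))
    def test_composite_monotonicity(self, alpha, s, w):
        d = 128
        fit = lambda a, k: w * a + (1 - w) * k / d
        if w < 1 and s < d:
            assert fit(alpha, s + 1) > fit(alpha, s)
        if w > 0 and alpha < 1:
            assert fit(min(alpha + 0.01, 1.0), s) > fit(alpha, s)


class TestExhaustiveOracle:
    def test_two_feature_constructed_optimum(self):
        # feature 0 separates perfectly; feature 1 is label-independent
        rng = np.random.default_rng(0)
        n = 40
        y = np.tile([0, 1], n // 2)
        X = np.column_stack([y * 4.0 + 0.1 * rng.standard_normal(n),
                             np.tile([0.0, 1.0, 1.0, 0.0], n // 4)])
        yt = np.tile([0, 1], 10)
        Xt = np.column_stack([yt * 4.0 + 0.1 * rng.standard_normal(20),
                              np.tile([1.0, 0.0], 10)])
        split = _split(X, y, Xt, yt)
        mask, fv = exhaustive_oracle(split, KnnConfig(k=1), w=0.2)
        assert mask.bits == (1, 0)
        assert fv.fitness == pytest.approx(0.4)  # 0.2*0 + 0.8*(1/2)

    def test_pure_noise_prefers_single_feature(self, rng):
        X = rng.standard_normal((100, 4))
        y = rng.integers(0, 2, 100)
        Xt = rng.standard_normal((30, 4))
        yt = rng.integers(0, 2, 30)
        split = _split(X, y, Xt, yt)
        mask, _ = exhaustive_oracle(split, KnnConfig(k=5), w=0.2)
        assert mask.selected_count == 1

    def test_single_feature_table(self):
        split = _split([[0.0], [1.0], [0.1], [0.9]], [0, 1, 0, 1],
                       [[0.05], [0.95]], [0, 1])
        mask, fv = exhaustive_oracle(split, KnnConfig(k=1), w=0.2)
        assert mask.bits == (1,)
        assert fv.fitness == pytest.approx(0.8)  # alpha 0, |s|=d=1

    def test_dimension_guard(self, rng):
        X = rng.standard_normal((10, 20))
        y = np.tile([0, 1], 5)
        split = _split(X, y, X, y)
        with pytest.raises(ValueError, match="too large"):
            exhaustive_oracle(split)


def test_feature_mask_helpers():
    m = FeatureMask.from_indices([0, 3], 5)
    assert m.bits == (1, 0, 0, 1, 0)
    assert m.selected_indices == [0, 3]
    assert m.selected_count == 2
    with pytest.raises(ValueError):
        FeatureMask([0, 2, 1])
    with pytest.raises(ValueError):
        KnnConfig(k=4)
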