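"""Metrics, balanced-test construction, CV, and wavelength importance."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings, strategies as st

from nirleaf import (GeneratorSpec, SelfTrainConfig, balance_test_set,
                     band_element_correlation, compute_metrics,
                     confusion_matrix, cross_validate, fit_base,
                     gini_importance, precision_recall, simulate_labeled_set,
                     summary_metrics)
from nirleaf.evaluate import importance_profile
from nirleaf.spectra_io import SpectrumMatrix


def brute_force_tally(y_true, y_pred, n_classes=5):
    """Independent per-sample TP/FP/FN tally (no confusion matrix)."""
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    counts = np.zeros(n_classes)
    for c in range(n_classes):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        counts[c] = sum(1 for t in y_true if t == c)
    alpha = counts / counts.sum()
    map_ = precision.mean()
    wap = float((alpha * precision).sum())
    wr = float((alpha * recall).sum())
    return precision, recall, map_, wap, wr


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(np.arange(5), [3, 1, 4, 2, 5])
        M = confusion_matrix(y, y)
        npt.assert_array_equal(np.diag(M), [3, 1, 4, 2, 5])
        assert M.sum() == np.trace(M)

    def test_hand_counted_example(self):
        M = confusion_matrix([0, 0, 1], [0, 1, 1])
        assert M[0, 0] == 1 and M[0, 1] == 1 and M[1, 1] == 1
        assert M.sum() == 3

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        M = confusion_matrix(y_true, y_pred)
        oracle = np.zeros((5, 5), dtype=int)
        for t, p in zip(y_true, y_pred):
            oracle[t, p] += 1
        npt.assert_array_equal(M, oracle)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 0])


class TestPrecisionRecall:
    def test_diagonal_matrix_all_ones(self):
        M = np.diag([2, 3, 4, 5, 6])
        p, r = precision_recall(M)
        npt.assert_allclose(p, 1.0)
        npt.assert_allclose(r, 1.0)

    def test_never_predicted_class_gets_zero_precision(self):
        M = np.zeros((5, 5), dtype=int)
        M[0, 1] = 3  # class 0 always predicted as 1; class 0 never predicted
        M[1, 1] = 2
        p, r = precision_recall(M)
        assert p[0] == 0.0
        assert r[0] == 0.0
        assert p[1] == pytest.approx(2 / 5)

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        p, r = precision_recall(confusion_matrix(y_true, y_pred))
        op, orc, *_ = brute_force_tally(y_true, y_pred)
        npt.assert_allclose(p, op)
        npt.assert_allclose(r, orc)


class TestSummaryMetrics:
    def test_map_is_plain_average(self):
        # per-class precisions 1.0, 0.5, 0.75, 0.25, 0.5 -> MAP 0.6
        M = np.zeros((5, 5), dtype=int)
        diag = [4, 2, 3, 1, 2]
        off = [0, 2, 1, 3, 2]
        for i in range(5):
            M[i, i] = diag[i]
            M[(i + 1) % 5, i] = off[i]
        p, _ = precision_recall(M)
        npt.assert_allclose(p, [1.0, 0.5, 0.75, 0.25, 0.5])
        map_, _, _ = summary_metrics(M)
        assert map_ == pytest.approx(0.6)

    def test_balanced_truth_makes_wap_equal_map(self):
        rng = np.random.default_rng(2)
        y_true = np.repeat(np.arange(5), 40)
        y_pred = rng.integers(0, 5, 200)
        map_, wap, _ = summary_metrics(confusion_matrix(y_true, y_pred))
        assert wap == pytest.approx(map_)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_wr_is_micro_accuracy_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        M = rng.integers(0, 10, (5, 5))
        if M.sum() == 0:
            M[0, 0] = 1
        _, _, wr = summary_metrics(M)
        assert wr == pytest.approx(np.trace(M) / M.sum())

    def test_full_report_matches_tally_oracle(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 5, 500)
        y_pred = rng.integers(0, 5, 500)
        rep = compute_metrics(y_true, y_pred)
        op, orc, omap, owap, owr = brute_force_tally(y_true, y_pred)
        npt.assert_allclose(rep.per_class_precision, op)
        npt.assert_allclose(rep.per_class_recall, orc)
        assert rep.map == pytest.approx(omap)
        assert rep.wap == pytest.approx(owap)
        assert rep.wr == pytest.approx(owr)
        assert rep.alpha.sum() == pytest.approx(1.0)
        npt.assert_array_equal(rep.confusion.sum(axis=1),
                               np.bincount(y_true, minlength=5))


class TestBalanceTestSet:
    def test_downsamples_to_min_count(self):
        gen = GeneratorSpec(class_counts=(16, 75, 87, 128, 44), seed=1)
        test = simulate_labeled_set(gen)
        balanced = balance_test_set(test, seed=0)
        npt.assert_array_equal(balanced.class_counts, [16] * 5)

    def test_already_balanced_keeps_counts(self, small_labeled):
        balanced = balance_test_set(small_labeled, seed=0)
        npt.assert_array_equal(balanced.class_counts,
                               small_labeled.class_counts)

    def test_deterministic(self, skewed_labeled):
        a = balance_test_set(skewed_labeled, seed=5)
        b = balance_test_set(skewed_labeled, seed=5)
        npt.assert_array_equal(a.spectra.values, b.spectra.values)

    def test_empty_class_rejected(self):
        gen = GeneratorSpec(class_counts=(0, 5, 5, 5, 5), seed=1)
        test = simulate_labeled_set(gen)
        with pytest.raises(ValueError):
            balance_test_set(test)

    def test_samples_drawn_without_replacement(self, skewed_labeled):
        balanced = balance_test_set(skewed_labeled, seed=2)
        # all rows are distinct rows of the original
        joined = {tuple(r) for r in skewed_labeled.spectra.values}
        assert all(tuple(r) in joined for r in balanced.spectra.values)
        assert len({tuple(r) for r in balanced.spectra.values}) == \
            len(balanced)


class TestCrossValidate:
    def test_memorising_classifier_scores_one(self):
        gen = GeneratorSpec(class_counts=(10,) * 5, effect_size=30.0,
                            noise_sd=0.002, scatter_sd=0.0, seed=4)
        L = simulate_labeled_set(gen)
        U = simulate_labeled_set(
            GeneratorSpec(class_counts=(10,) * 5, effect_size=30.0,
                          noise_sd=0.002, scatter_sd=0.0, seed=5)).spectra
        cfg = SelfTrainConfig(base="LDA", max_iter=1, labeled_sampler="none",
                              seed=0)
        mean_wap, folds = cross_validate(L, U, cfg, folds=5, seed=1)
        assert mean_wap == pytest.approx(1.0)

    def test_mean_equals_fold_average(self, small_labeled, unlabeled_pool):
        cfg = SelfTrainConfig(base="LDA", max_iter=1, labeled_sampler="none",
                              seed=0)
        mean_wap, folds = cross_validate(small_labeled, unlabeled_pool, cfg,
                                         folds=3, seed=2)
        assert mean_wap == pytest.approx(folds.mean())
        assert folds.size == 3

    def test_tiny_classes_trigger_refold(self):
        gen = GeneratorSpec(class_counts=(3, 10, 10, 10, 10), seed=6)
        L = simulate_labeled_set(gen)
        U = L.spectra
        cfg = SelfTrainConfig(base="LDA", max_iter=0, labeled_sampler="none",
                              seed=0)
        with pytest.warns(UserWarning, match="refold"):
            _, folds = cross_validate(L, U, cfg, folds=5, seed=3)
        assert folds.size == 3


class TestGiniImportance:
    def test_weighted_mode_matches_library_importances(self, small_labeled):
        model = fit_base("RFC", small_labeled.spectra, small_labeled.labels,
                         seed=1)
        npt.assert_allclose(gini_importance(model, "weighted"),
                            model.feature_importances_, atol=1e-12)

    def test_weighted_mode_nonnegative_and_normalised(self, small_labeled):
        model = fit_base("RFC", small_labeled.spectra, small_labeled.labels,
                         seed=2)
        g = gini_importance(model, "weighted")
        assert np.all(g >= 0)
        assert g.sum() == pytest.approx(1.0)

    def test_single_informative_band_dominates(self):
        rng = np.random.default_rng(3)
        X = rng.random((150, 20))
        y = (X[:, 7] > 0.5).astype(int)
        m = SpectrumMatrix(X, np.arange(20, dtype=float))
        model = fit_base("RFC", m, y, seed=3)
        g = gini_importance(model)
        assert int(np.argmax(g)) == 7

    def test_permutation_equivariance_under_band_reorder(self):
        """Relabelling the band index used at every split permutes the
        importance vector accordingly (computation-level equivariance)."""
        from types import SimpleNamespace
        rng = np.random.default_rng(4)

        def random_tree(n_features, feature_map=None):
            # a depth-2 stump family: root + two internal + four leaves
            feature = np.array([0, 3, 7, -2, -2, -2, -2])
            if feature_map is not None:
                feature = np.where(feature >= 0, feature_map[feature], -2)
            return SimpleNamespace(tree_=SimpleNamespace(
                children_left=np.array([1, 3, 5, -1, -1, -1, -1]),
                children_right=np.array([2, 4, 6, -1, -1, -1, -1]),
                feature=feature,
                impurity=np.array([0.5, 0.4, 0.3, 0.1, 0.0, 0.2, 0.0]),
                weighted_n_node_samples=np.array(
                    [100.0, 60, 40, 30, 30, 20, 20]),
            ))

        perm = rng.permutation(10)
        inv = np.argsort(perm)
        forest1 = SimpleNamespace(n_features_in_=10,
                                  estimators_=[random_tree(10)])
        forest2 = SimpleNamespace(n_features_in_=10,
                                  estimators_=[random_tree(10, inv)])
        g1 = gini_importance(forest1)
        g2 = gini_importance(forest2)
        npt.assert_allclose(g2, g1[perm], atol=1e-12)

    def test_literal_mode_runs_and_normalises(self, small_labeled):
        model = fit_base("RFC", small_labeled.spectra, small_labeled.labels,
                         seed=6)
        g = gini_importance(model, "literal")
        assert np.abs(g).sum() == pytest.approx(1.0)

    def test_auxiliary_forest_for_linear_model(self, small_labeled):
        lda = fit_base("LDA", small_labeled.spectra, small_labeled.labels)
        g = gini_importance(lda, X=small_labeled.spectra,
                            y=small_labeled.labels, seed=7)
        assert g.shape == (small_labeled.spectra.n_bands,)
        with pytest.raises(TypeError):
            gini_importance(lda, allow_auxiliary=False)


class TestBandElementCorrelation:
    def test_exact_linear_band(self):
        rng = np.random.default_rng(5)
        conc = rng.uniform(2.5, 4.0, 50)
        X = rng.random((50, 6))
        X[:, 2] = 2 * conc + 3
        X[:, 4] = -conc
        m = SpectrumMatrix(X, np.arange(6, dtype=float))
        r = band_element_correlation(m, conc)
        assert r[2] == pytest.approx(1.0)
        assert r[4] == pytest.approx(-1.0)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_random_band_near_zero(self):
        rng = np.random.default_rng(6)
        conc = rng.uniform(0, 1, 1000)
        m = SpectrumMatrix(rng.random((1000, 3)), np.arange(3, dtype=float))
        r = band_element_correlation(m, conc)
        assert np.all(np.abs(r) < 0.1)

    def test_constant_band_zero_with_warning(self):
        conc = np.linspace(0, 1, 10)
        X = np.random.default_rng(7).random((10, 3))
        X[:, 1] = 0.5
        m = SpectrumMatrix(X, np.arange(3, dtype=float))
        with pytest.warns(UserWarning, match="constant band"):
            r = band_element_correlation(m, conc)
        assert r[1] == 0.0

    def test_constant_concentration_rejected(self):
        m = SpectrumMatrix(np.random.default_rng(8).random((5, 3)),
                           np.arange(3, dtype=float))
        with pytest.raises(ValueError):
            band_element_correlation(m, np.ones(5))


class TestImportanceProfile:
    def test_top_bands_ranked_by_gini(self, small_labeled):
        model = fit_base("RFC", small_labeled.spectra, small_labeled.labels,
                         seed=8)
        prof = importance_profile(model, small_labeled.spectra,
                                  small_labeled.concentrations,
                                  y=small_labeled.labels, top=5)
        g = prof.gini
        assert list(prof.top_bands) == list(np.argsort(-g, kind="stable")[:5])
        assert prof.pearson_r is not None
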