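import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB

from serumftir import (
    ModelConfig,
    classification_metrics,
    discriminant_band_summary,
    equal_frequency_discretize,
    fcbf_select,
    gaussian_nb_train_predict,
    loocv_run,
    permutation_test,
    rank_top_k,
    reliability_and_brier,
    symmetric_uncertainty,
    variant_grid,
)
from serumftir.model_eval import CVResult, apply_cuts, fit_equal_frequency_cuts
from serumftir.preprocess import DEFAULT_PIPELINE

from oracles import naive_su, pair_count_auc


class TestDiscretize:
    def test_quantile_convention(self):
        codes, cuts = equal_frequency_discretize(np.arange(1.0, 9.0), n_bins=4)
        np.testing.assert_allclose(cuts, [2.5, 4.5, 6.5])
        assert codes.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_constant_feature_single_bin(self):
        codes, _ = equal_frequency_discretize(np.full(10, 3.3), n_bins=4)
        assert set(codes.tolist()) == {0}

    def test_boundary_codes(self):
        _, cuts = equal_frequency_discretize(np.arange(1.0, 9.0), n_bins=4)
        assert apply_cuts(np.array([-100.0]), cuts)[0] == 0
        assert apply_cuts(np.array([100.0]), cuts)[0] == 3

    def test_transform_reusable_on_unseen(self):
        fit = np.arange(1.0, 9.0)
        _, cuts = equal_frequency_discretize(fit, n_bins=4)
        unseen = apply_cuts(np.array([2.4, 2.6, 6.6]), cuts)
        assert unseen.tolist() == [0, 1, 3]

    def test_matrix_cuts_match_columnwise(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(20, 5))
        cuts = fit_equal_frequency_cuts(m, 4)
        codes = apply_cuts(m, cuts)
        for j in range(5):
            cj = fit_equal_frequency_cuts(m[:, j], 4)
            np.testing.assert_allclose(cuts[:, j], cj)
            np.testing.assert_array_equal(codes[:, j], apply_cuts(m[:, j], cj))


class TestSymmetricUncertainty:
    def test_identical_balanced_binary(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert symmetric_uncertainty(x, x) == pytest.approx(1.0)

    def test_independent_by_construction(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        assert symmetric_uncertainty(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_joint_counts(self):
        x = np.array([0] * 8 + [1] * 8)
        y = np.array([0] * 7 + [1] * 1 + [0] * 2 + [1] * 6)
        assert symmetric_uncertainty(x, y) == pytest.approx(
            naive_su(x, y), abs=1e-10
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            symmetric_uncertainty([0, 1], [0, 1, 0])

    def test_bounded_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, 30)
            y = rng.integers(0, 2, 30)
            su = symmetric_uncertainty(x, y)
            assert 0.0 <= su <= 1.0
            assert su == pytest.approx(naive_su(x, y), abs=1e-10)


class TestFCBF:
    def test_redundant_copy_pruned(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 12 + [1] * 12)
        f1 = y.copy()
        f2 = y.copy()          # exact copy of f1: redundant
        f3 = rng.integers(0, 4, 24)  # noise
        codes = np.column_stack([f1, f2, f3])
        selected, _ = fcbf_select(codes, y)
        assert selected.tolist() == [0]

    def test_single_informative_feature_kept(self):
        y = np.array([0, 0, 1, 1])
        selected, _ = fcbf_select(y[:, None], y)
        assert selected.tolist() == [0]

    def test_all_constant_empty_selection(self):
        codes = np.zeros((10, 3), dtype=int)
        y = np.array([0, 1] * 5)
        selected, _ = fcbf_select(codes, y)
        assert selected.size == 0

    def test_rank_top_k_ordering(self):
        y = np.array([0] * 6 + [1] * 6)
        perfect = y.copy()
        partial = np.array([0] * 5 + [1] * 7) % 2  # weakly informative
        noise = np.array([0, 1] * 6)
        codes = np.column_stack([noise, partial, perfect])
        top, su = rank_top_k(codes, y, 2)
        assert top[0] == 2
        assert su[2] == pytest.approx(1.0)


class TestGaussianNB:
    def test_symmetric_midpoint(self):
        train = np.array([[-1.0], [-1.1], [-0.9], [1.0], [1.1], [0.9]])
        y = np.array([0, 0, 0, 1, 1, 1])
        probs = gaussian_nb_train_predict(train, y, np.array([[0.0]]))
        assert probs[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_far_point_confident(self):
        rng = np.random.default_rng(0)
        train = np.concatenate([rng.normal(0, 1, (20, 1)), rng.normal(20, 1, (20, 1))])
        y = np.array([0] * 20 + [1] * 20)
        probs = gaussian_nb_train_predict(train, y, np.array([[20.0]]))
        assert probs[0, 1] > 0.999

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(30, 6))
        y = rng.integers(0, 2, 30)
        while len(set(y)) < 2:
            y = rng.integers(0, 2, 30)
        probs = gaussian_nb_train_predict(train, y, rng.normal(size=(10, 6)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_one_class_training_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            gaussian_nb_train_predict(
                np.ones((3, 2)), np.zeros(3, dtype=int), np.ones((1, 2))
            )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(40, 5))
        y = np.array([0, 1] * 20)
        test = rng.normal(size=(15, 5))
        ours = gaussian_nb_train_predict(train, y, test)
        theirs = GaussianNB().fit(train, y).predict_proba(test)
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestMetrics:
    def test_perfect_separation(self):
        m = classification_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["auc"] == 1.0
        assert m["accuracy"] == 1.0
        assert m["f1"] == 1.0

    def test_pair_counting_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        m = classification_metrics(scores, labels)
        assert m["auc"] == pytest.approx(0.75)
        assert m["auc"] == pytest.approx(pair_count_auc(scores, labels))

    def test_all_equal_scores_auc_half(self):
        m = classification_metrics([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert m["auc"] == pytest.approx(0.5)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=20)
        labels = np.array([0, 1] * 10)
        perm = rng.permutation(20)
        a = classification_metrics(scores, labels)
        b = classification_metrics(scores[perm], labels[perm])
        for key in ("auc", "accuracy", "f1", "precision", "recall", "specificity"):
            assert a[key] == pytest.approx(b[key])

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            classification_metrics([0.1, 0.9], [1, 1])


class TestLOOCV:
    def test_one_prediction_per_sample(self, default_cohort):
        sset, _ = default_cohort
        cv = loocv_run(sset, DEFAULT_PIPELINE, ModelConfig())
        assert cv.oof_prob.shape == (24,)
        assert np.all((cv.oof_prob >= 0) & (cv.oof_prob <= 1))
        assert len(cv.fold_selected) == 24

    def test_strong_effect_clearly_above_chance(self, default_cohort):
        """Single-seed smoke check; the distributional power claim
        (median AUC over 20 seeds) is exercised in the acceptance suite."""
        sset, _ = default_cohort
        cv = loocv_run(sset, DEFAULT_PIPELINE, ModelConfig())
        assert cv.metrics["auc"] >= 0.8

    def test_unlabeled_set_rejected(self, default_cohort):
        sset, _ = default_cohort
        with pytest.raises(ValueError, match="label"):
            loocv_run(sset.without_labels(), DEFAULT_PIPELINE, ModelConfig())

    def test_selector_none_uses_all_features(self, tiny_set):
        cv = loocv_run(tiny_set, None, ModelConfig(selector="none", n_bins=2))
        assert all(sel.size == tiny_set.n_points for sel in cv.fold_selected)


class TestPermutation:
    def test_deterministic_under_seed(self, default_cohort):
        sset, _ = default_cohort
        a = permutation_test(sset, DEFAULT_PIPELINE, ModelConfig(), 3, seed=5)
        b = permutation_test(sset, DEFAULT_PIPELINE, ModelConfig(), 3, seed=5)
        np.testing.assert_array_equal(a.perm_loocv_auc, b.perm_loocv_auc)
        np.testing.assert_array_equal(a.perm_train_auc, b.perm_train_auc)

    def test_zero_permutations_rejected(self, default_cohort):
        sset, _ = default_cohort
        with pytest.raises(ValueError):
            permutation_test(sset, DEFAULT_PIPELINE, ModelConfig(), 0)


class TestReliabilityBrier:
    def test_uninformative_half_probabilities(self):
        _, brier = reliability_and_brier([0.5] * 10, [0, 1] * 5, n_bins=5)
        assert brier == pytest.approx(0.25)

    def test_perfect_probabilities(self):
        _, brier = reliability_and_brier(
            [0.0, 1.0, 0.0, 1.0, 1.0], [0, 1, 0, 1, 1], n_bins=2
        )
        assert brier == 0.0

    def test_hand_computation(self):
        _, brier = reliability_and_brier([0.8, 0.4], [1, 0], n_bins=2)
        assert brier == pytest.approx(0.10)

    def test_bin_table_monotone_fields(self, default_cohort):
        sset, _ = default_cohort
        cv = loocv_run(sset, DEFAULT_PIPELINE, ModelConfig())
        table, brier = reliability_and_brier(cv.oof_prob, cv.labels)
        assert 0.0 <= brier <= 1.0
        assert table["n"].sum() == 24
        assert table["mean_predicted"].is_monotonic_increasing


class TestBandSummary:
    def _cv(self, grid, selections, sus, n_folds=None):
        n_folds = n_folds or len(selections)
        return CVResult(
            sample_ids=[f"s{i}" for i in range(n_folds)],
            labels=np.array([0, 1] * (n_folds // 2 + 1))[:n_folds],
            oof_prob=np.full(n_folds, 0.5),
            fold_selected=[np.asarray(s, dtype=int) for s in selections],
            fold_su=[np.asarray(s, dtype=float) for s in sus],
            wavenumbers=np.asarray(grid, dtype=float),
            metrics={},
            train_metrics={},
        )

    def test_always_selected_feature_tops_report(self):
        grid = [900.0, 902.0, 1500.0]
        sels = [[0, 2]] * 3 + [[0]]
        sus = [[0.9, 0.3]] * 3 + [[0.9]]
        df = discriminant_band_summary(self._cv(grid, sels, sus))
        assert df.iloc[0]["low_cm1"] == 900.0
        assert df.iloc[0]["selection_frequency"] == 1.0

    def test_adjacent_points_merge_into_one_band(self):
        grid = [946.0, 948.0, 2000.0]
        df = discriminant_band_summary(self._cv(grid, [[0, 1]], [[0.5, 0.4]]))
        assert len(df) == 1
        assert (df.iloc[0]["low_cm1"], df.iloc[0]["high_cm1"]) == (946.0, 948.0)

    def test_gap_beyond_two_steps_splits_bands(self):
        grid = [946.0, 948.0, 956.0]
        df = discriminant_band_summary(self._cv(grid, [[0, 2]], [[0.5, 0.4]]))
        assert len(df) == 2

    def test_empty_selection_empty_report(self):
        df = discriminant_band_summary(self._cv([900.0, 902.0], [[]], [[]]))
        assert df.empty


class TestVariantGrid:
    def test_schema_and_determinism(self, default_cohort):
        sset, _ = default_cohort
        g = variant_grid(sset, ["raw", "raw"], ModelConfig())
        assert list(g.columns) == [
            "variant", "auc", "accuracy", "f1", "precision", "recall", "specificity",
        ]
        assert g.iloc[0, 1:].tolist() == g.iloc[1, 1:].tolist()

    def test_unknown_variant_errors(self, default_cohort):
        sset, _ = default_cohort
        with pytest.raises(ValueError, match="valid names"):
            variant_grid(sset, ["bogus"], ModelConfig())
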