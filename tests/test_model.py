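"""Classifier protocols: folds, cross-validation, grid search, jackknife."""

import numpy as np
import pytest

import sixma as sx
from sixma.model import mean_report

FAST_TREES = sx.ClassifierSpec(family="extratrees", n_trees=30, seed=1)


def separable_matrix(n_per_class=25, seed=0):
    """Labeled features where one column perfectly separates the classes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.random((n, 5))
    labels = [sx.POSITIVE] * n_per_class + [sx.NEGATIVE] * n_per_class
    values[:n_per_class, 0] += 2.0  # clean margin on feature 0
    return sx.FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(5)],
        values=values,
        labels=labels,
    )


class TestMakeFolds:
    def test_stratified_sizes(self):
        labels = [sx.POSITIVE] * 50 + [sx.NEGATIVE] * 50
        folds = sx.make_folds(labels, n_folds=5, seed=1)
        y = np.array([1] * 50 + [0] * 50)
        for fold in range(5):
            mask = folds == fold
            assert mask.sum() == 20
            assert y[mask].sum() == 10

    def test_deterministic_and_seed_sensitivity(self):
        labels = [sx.POSITIVE] * 30 + [sx.NEGATIVE] * 30
        a = sx.make_folds(labels, 5, seed=1)
        b = sx.make_folds(labels, 5, seed=1)
        c = sx.make_folds(labels, 5, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_class_smaller_than_fold_count_errors(self):
        labels = [sx.POSITIVE] * 3 + [sx.NEGATIVE] * 10
        with pytest.raises(ValueError, match="fewer than 5"):
            sx.make_folds(labels, 5, seed=1)


class TestCrossValidate:
    def test_separable_data_reaches_auc_one(self):
        fm = separable_matrix()
        folds = sx.make_folds(fm.labels, 5, seed=1)
        result = sx.cross_validate(fm, FAST_TREES, folds)
        assert result.mean["auc"] == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(11)
        n = 400
        values = rng.random((n, 10))
        labels = [sx.POSITIVE] * (n // 2) + [sx.NEGATIVE] * (n // 2)
        fm = sx.FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            feature_names=[f"f{j}" for j in range(10)],
            values=values,
            labels=labels,
        )
        folds = sx.make_folds(fm.labels, 5, seed=1)
        result = sx.cross_validate(fm, FAST_TREES, folds)
        assert 0.42 <= result.mean["auc"] <= 0.58

    def test_deterministic_for_fixed_seeds(self, small_features):
        folds = sx.make_folds(small_features.labels, 5, seed=1)
        r1 = sx.cross_validate(small_features, FAST_TREES, folds)
        r2 = sx.cross_validate(small_features, FAST_TREES, folds)
        assert r1.mean == r2.mean
        for a, b in zip(r1.per_fold, r2.per_fold):
            assert a.scalars() == b.scalars()

    def test_mean_equals_independent_fold_mean(self, small_features):
        folds = sx.make_folds(small_features.labels, 4, seed=3)
        result = sx.cross_validate(small_features, FAST_TREES, folds)
        recomputed = {
            key: np.mean([r.scalars()[key] for r in result.per_fold])
            for key in result.mean
        }
        for key, value in result.mean.items():
            assert value == pytest.approx(recomputed[key], abs=1e-15)
        assert result.mean == mean_report(result.per_fold)

    def test_fold_assignment_not_mutated_across_families(self, small_features):
        folds = sx.make_folds(small_features.labels, 4, seed=1)
        original = folds.copy()
        for family in ("extratrees", "random_forest", "svm"):
            spec = sx.ClassifierSpec(family=family, n_trees=10, seed=1)
            sx.cross_validate(small_features, spec, folds)
        assert np.array_equal(folds, original)

    def test_unlabeled_matrix_rejected(self, small_features):
        bare = sx.FeatureMatrix(
            sample_ids=small_features.sample_ids,
            feature_names=small_features.feature_names,
            values=small_features.values,
        )
        with pytest.raises(ValueError, match="no labels"):
            sx.cross_validate(bare, FAST_TREES, np.zeros(bare.n_samples, dtype=int))


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, small_features):
        folds = sx.make_folds(small_features.labels, 3, seed=1)
        best_c, best_gamma, table = sx.grid_search_svm(
            small_features, folds, c_grid=[0.98], gamma_grid=[0.01]
        )
        assert (best_c, best_gamma) == (0.98, 0.01)
        assert len(table) == 1

    def test_exhaustive_table_and_winner(self, small_features):
        folds = sx.make_folds(small_features.labels, 3, seed=1)
        c_grid, gamma_grid = [0.1, 1.0, 10.0], [0.001, 0.1]
        best_c, best_gamma, table = sx.grid_search_svm(
            small_features, folds, c_grid=c_grid, gamma_grid=gamma_grid
        )
        assert len(table) == len(c_grid) * len(gamma_grid)
        top = table.loc[table["mean_auc"].idxmax()]
        assert top["mean_auc"] == table["mean_auc"].max()
        assert best_c in c_grid and best_gamma in gamma_grid
        # tie-break: no cell with the same AUC and smaller C/gamma
        ties = table[table["mean_auc"] == table["mean_auc"].max()]
        assert best_c == ties["C"].min()

    def test_empty_grid_rejected(self, small_features):
        folds = sx.make_folds(small_features.labels, 3, seed=1)
        with pytest.raises(ValueError):
            sx.grid_search_svm(small_features, folds, c_grid=[], gamma_grid=[0.1])


class TestFitPredict:
    def test_memorization_limit_on_training_data(self):
        fm = separable_matrix()
        model = sx.fit(fm, FAST_TREES)
        scores = sx.predict_scores(model, fm)
        report = sx.evaluate_scores(fm.labels, scores)
        assert report.acc == 1.0

    def test_same_seed_identical_predictions(self, small_features):
        m1 = sx.fit(small_features, FAST_TREES)
        m2 = sx.fit(small_features, FAST_TREES)
        s1 = sx.predict_scores(m1, small_features)
        s2 = sx.predict_scores(m2, small_features)
        np.testing.assert_array_equal(s1, s2)

    def test_scores_in_unit_interval_all_families(self, small_features):
        for family in ("extratrees", "random_forest", "adaboost", "svm"):
            spec = sx.ClassifierSpec(family=family, n_trees=10, seed=1)
            model = sx.fit(small_features, spec)
            scores = sx.predict_scores(model, small_features)
            assert np.all((scores >= 0) & (scores <= 1)), family

    def test_unknown_family_is_configuration_error(self):
        with pytest.raises(ValueError, match="unknown classifier family"):
            sx.ClassifierSpec(family="deep_net")

    def test_reordered_columns_rejected_not_mispredicted(self, small_features):
        model = sx.fit(small_features, FAST_TREES)
        perm = list(range(small_features.n_features))
        perm[0], perm[1] = perm[1], perm[0]
        shuffled = sx.FeatureMatrix(
            sample_ids=small_features.sample_ids,
            feature_names=[small_features.feature_names[i] for i in perm],
            values=small_features.values[:, perm],
            labels=small_features.labels,
        )
        with pytest.raises(ValueError, match="mismatch at column 0"):
            sx.predict_scores(model, shuffled)

    def test_wrong_feature_count_rejected(self, small_features):
        model = sx.fit(small_features, FAST_TREES)
        truncated = sx.FeatureMatrix(
            sample_ids=small_features.sample_ids,
            feature_names=small_features.feature_names[:-1],
            values=small_features.values[:, :-1],
            labels=small_features.labels,
        )
        with pytest.raises(ValueError, match="feature count mismatch"):
            sx.predict_scores(model, truncated)

    def test_single_class_training_rejected(self):
        fm = sx.FeatureMatrix(
            sample_ids=["a", "b"],
            feature_names=["f0"],
            values=np.array([[0.0], [1.0]]),
            labels=[sx.POSITIVE, sx.POSITIVE],
        )
        with pytest.raises(ValueError, match="both classes"):
            sx.fit(fm, FAST_TREES)


class TestJackknife:
    def test_pooled_predictions_cover_every_sample(self):
        fm = separable_matrix(n_per_class=6)
        report = sx.jackknife(fm, FAST_TREES)
        # pooled over all n: a perfect separable set stays perfect
        assert report.acc == 1.0
        assert len(report.roc_points) >= 2

    def test_two_runs_agree_exactly(self):
        fm = separable_matrix(n_per_class=5, seed=2)
        r1 = sx.jackknife(fm, FAST_TREES)
        r2 = sx.jackknife(fm, FAST_TREES)
        assert r1.scalars() == r2.scalars()

    def test_minimum_size_enforced(self):
        fm = sx.FeatureMatrix(
            sample_ids=["a", "b"],
            feature_names=["f0"],
            values=np.array([[0.0], [1.0]]),
            labels=[sx.POSITIVE, sx.NEGATIVE],
        )
        with pytest.raises(ValueError, match="at least 3"):
            sx.jackknife(fm, FAST_TREES)


class TestBaselinePreset:
    def test_block_sizes_and_spec(self, small_dataset):
        features, spec = sx.baseline_idna6ma_pseknc(small_dataset)
        assert features.n_features == 41 + 123 == 164
        assert spec.family == "svm"
        assert spec.svm_c == 0.336 and spec.svm_gamma == 0.02

    def test_runs_through_cross_validate(self, small_dataset):
        features, spec = sx.baseline_idna6ma_pseknc(small_dataset)
        folds = sx.make_folds(features.labels, 4, seed=1)
        result = sx.cross_validate(features, spec, folds)
        assert set(result.mean) >= {"sn", "sp", "acc", "mcc", "auc", "ap", "f1"}
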