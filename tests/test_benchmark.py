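"""Grouped resampling, rebalancing, dummy baseline and tuning."""

import numpy as np
import pandas as pd
import pytest

from periopred.benchmark import (
    BenchmarkConfig,
    PriorDummyClassifier,
    benchmark_grid,
    dummy_baseline,
    grouped_cv_folds,
    grouped_split,
    rebalance_training,
    smote_resample,
    tune_and_train,
)
from periopred.imputation import impute_dataset
from periopred.labeling import build_task_dataset


@pytest.fixture(scope="module")
def closure_task(small_cohort):
    ds, _ = impute_dataset(small_cohort)
    return build_task_dataset(ds, "closure")


class TestGroupedSplit:
    def test_fraction_and_disjointness(self, closure_task):
        plan = grouped_split(closure_task, test_fraction=0.2, seed=1)
        n = closure_task.features.shape[0]
        patients = set(closure_task.groups)
        assert len(plan.test_patients) == round(0.2 * len(patients))
        assert not set(plan.train_patients) & set(plan.test_patients)
        assert set(plan.train_patients) | set(plan.test_patients) == patients

    def test_deterministic_under_seed(self, closure_task):
        a = grouped_split(closure_task, seed=7)
        b = grouped_split(closure_task, seed=7)
        assert a == b
        assert a != grouped_split(closure_task, seed=8)

    def test_single_patient_errors(self, closure_task):
        import copy
        td = copy.copy(closure_task)
        mask = closure_task.groups == closure_task.groups[0]
        td.groups = closure_task.groups[mask]
        td.features = closure_task.features[mask]
        with pytest.raises(ValueError):
            grouped_split(td)


class TestCvFolds:
    def test_balanced_folds(self):
        patients = [f"p{i}" for i in range(20)]
        folds = grouped_cv_folds(patients, k=10, seed=0)
        sizes = pd.Series(folds).value_counts()
        assert set(folds) == set(patients)
        assert (sizes == 2).all()

    def test_union_and_disjoint(self):
        patients = [f"p{i}" for i in range(23)]
        folds = grouped_cv_folds(patients, k=10, seed=1)
        sizes = pd.Series(folds).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert len(folds) == 23  # each patient exactly one fold

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            grouped_cv_folds(["a", "b"], k=10)
        with pytest.raises(ValueError):
            grouped_cv_folds(list("abcdefghij"), k=1)


class TestRebalance:
    def _data(self, n0=90, n1=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n0 + n1, 3))
        y = np.array([0] * n0 + [1] * n1)
        return X, y

    def test_downsample_equalizes(self):
        X, y = self._data()
        Xr, yr = rebalance_training(X, y, "downsample", seed=1)
        assert (np.bincount(yr) == [10, 10]).all()

    def test_upsample_equalizes(self):
        X, y = self._data()
        Xr, yr = rebalance_training(X, y, "upsample", seed=1)
        assert (np.bincount(yr) == [90, 90]).all()

    def test_none_identity(self):
        X, y = self._data()
        Xr, yr = rebalance_training(X, y, "none")
        assert Xr is X and yr is y

    def test_smote_equal_counts_and_interpolation(self):
        X, y = self._data(n0=80, n1=20)
        Xr, yr = rebalance_training(X, y, "smote", seed=2)
        assert (np.bincount(yr) == [80, 80]).all()
        # synthetic points lie within the minority bounding box
        minority = X[y == 1]
        synth = Xr[len(X):]
        assert (synth >= minority.min(axis=0) - 1e-9).all()
        assert (synth <= minority.max(axis=0) + 1e-9).all()

    def test_smote_small_class_falls_back_with_warning(self):
        X, y = self._data(n0=50, n1=4)
        with pytest.warns(UserWarning, match="falling back"):
            Xr, yr = smote_resample(X, y, k_neighbors=5)
        assert (np.bincount(yr) == [50, 50]).all()

    def test_unknown_strategy(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            rebalance_training(X, y, "adasyn")


class TestDummy:
    def test_binary_prior_and_majority(self):
        y = np.array([0] * 62 + [1] * 38)
        model = dummy_baseline(y)
        proba = model.predict_proba(np.zeros((5, 2)))
        assert proba.shape == (5, 2)
        np.testing.assert_allclose(proba, [[0.62, 0.38]] * 5)
        assert (model.predict(np.zeros((5, 2))) == 0).all()

    def test_multiclass_prior(self):
        y = np.array([1] * 87 + [2] * 10 + [3] * 3)
        model = dummy_baseline(y)
        np.testing.assert_allclose(model.prior_, [0.87, 0.10, 0.03])
        assert model.majority_ == 1

    def test_tie_breaks_to_lowest_class(self):
        model = dummy_baseline(np.array([2, 1, 1, 2]))
        assert model.majority_ == 1


class TestTuning:
    def test_seeded_random_search_deterministic(self, closure_task):
        cfg = BenchmarkConfig(learner="logistic", tuning_criterion="f1",
                              search_budget=3, seed=5)
        a = tune_and_train(closure_task, cfg)
        b = tune_and_train(closure_task, cfg)
        assert a.best_params_ == b.best_params_
        assert a.best_score_ == b.best_score_
        assert len(a.trace_) == 3

    def test_budget_zero_defaults_with_warning(self, closure_task):
        cfg = BenchmarkConfig(learner="random_forest", tuning_criterion="f1",
                              search_budget=0, seed=0)
        with pytest.warns(UserWarning, match="default"):
            clf = tune_and_train(closure_task, cfg)
        assert clf.best_params_ == {}

    def test_dummy_learner_needs_no_tuning(self, closure_task):
        cfg = BenchmarkConfig(learner="dummy", tuning_criterion="f1", seed=0)
        clf = tune_and_train(closure_task, cfg)
        proba = clf.predict_proba(closure_task.features.head(5))
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (proba == proba[0]).all()  # identical vector everywhere

    def test_criterion_task_compatibility(self, closure_task):
        cfg = BenchmarkConfig(learner="logistic", tuning_criterion="f1_macro")
        with pytest.raises(ValueError, match="3-class"):
            tune_and_train(closure_task, cfg)

    def test_predict_proba_contract(self, closure_task):
        cfg = BenchmarkConfig(learner="logistic", tuning_criterion="brier",
                              search_budget=2, seed=1)
        clf = tune_and_train(closure_task, cfg)
        X = closure_task.features.head(20)
        proba = clf.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        # permuting rows permutes outputs identically
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(clf.predict_proba(X.iloc[perm]), proba[perm])

    def test_schema_mismatch_lists_columns(self, closure_task):
        cfg = BenchmarkConfig(learner="dummy", tuning_criterion="f1")
        clf = tune_and_train(closure_task, cfg)
        bad = closure_task.features.drop(columns=["ppd_t0"])
        with pytest.raises(ValueError, match="ppd_t0"):
            clf.predict_proba(bad)

    def test_bayesian_search_runs_and_is_deterministic(self, closure_task):
        cfg = BenchmarkConfig(learner="logistic", tuning_criterion="f1",
                              search="bayesian", search_budget=5, seed=2)
        a = tune_and_train(closure_task, cfg)
        b = tune_and_train(closure_task, cfg)
        assert a.best_params_ == b.best_params_
        assert len(a.trace_) == 5


def test_patient_leakage_property_many_seeds(closure_task):
    for seed in range(50):
        plan = grouped_split(closure_task, seed=seed)
        assert not set(plan.train_patients) & set(plan.test_patients)
        folds = grouped_cv_folds(plan.train_patients, k=5, seed=seed)
        by_fold = pd.Series(folds)
        for f in range(5):
            inside = set(by_fold[by_fold == f].index)
            outside = set(by_fold[by_fold != f].index)
            assert not inside & outside


def test_benchmark_grid_enumeration():
    grid = benchmark_grid(learners=("dummy", "logistic"),
                          criteria=("f1",), encodings=("one_hot",))
    assert len(grid) == 2 * 1 * 4 * 1
    # the full printed grid is reconstructed from the benchmark axes
    full = benchmark_grid(criteria=("f1", "brier"), seed=0)
    assert len(full) == 5 * 2 * 4 * 2
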