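"""CV harness: normalization, metrics, fold plans, weighting, leakage."""

import numpy as np
import pytest

from dynsig import (
    balanced_accuracy,
    build_representation,
    confound_cv,
    make_fold_plan,
    mixed_sigmoid_apply,
    mixed_sigmoid_fit,
    run_repeated_cv,
)
from dynsig.cv import evaluate_on_plan
from dynsig.representations import RepresentationMatrix


def _rep(X, y, tag="toy"):
    return RepresentationMatrix(
        tag=tag,
        X=np.asarray(X, float),
        y=np.asarray(y),
        column_provenance=[("univariate", f"c{i}", "x") for i in range(X.shape[1])],
        subjects=[f"s{i}" for i in range(X.shape[0])],
    )


class TestMixedSigmoid:
    def test_median_maps_to_half_before_rescale(self):
        train = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        params = mixed_sigmoid_fit(train)
        pre = 1.0 / (1.0 + np.exp(-(3.0 - params.center) / params.scale))
        assert pre == pytest.approx(0.5)

    def test_constant_column_flagged_half(self):
        train = np.full((5, 1), 2.0)
        params = mixed_sigmoid_fit(train)
        assert params.constant[0]
        out = mixed_sigmoid_apply(params, np.array([[7.0], [2.0]]))
        assert np.all(out == 0.5)

    def test_outlier_contained_against_hand_computed_table(self):
        train = np.array([1.0, 2, 3, 4, 5, 100])[:, None]
        params = mixed_sigmoid_fit(train)
        # hand evaluation: median 3.5, IQR = 4.75 - 2.25 = 2.5, scale = 2.5/1.35
        med, scale = 3.5, 2.5 / 1.35
        g = 1 / (1 + np.exp(-(train[:, 0] - med) / scale))
        expected = (g - g.min()) / (g.max() - g.min())
        out = mixed_sigmoid_apply(params, train)[:, 0]
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        assert out.max() <= 1.0  # the outlier 100 lands inside [0, 1]
        # z-scoring would put the outlier at > 2 SDs, sigmoid keeps it bounded
        z = (100 - train.mean()) / train.std(ddof=1)
        assert z > 2

    def test_train_spans_unit_interval_test_may_exceed(self):
        train = np.linspace(0, 1, 10)[:, None]
        params = mixed_sigmoid_fit(train)
        tr = mixed_sigmoid_apply(params, train)
        assert tr.min() == pytest.approx(0) and tr.max() == pytest.approx(1)
        te = mixed_sigmoid_apply(params, np.array([[5.0]]))
        assert te[0, 0] > 1  # no clipping


class TestBalancedAccuracy:
    def test_perfect_and_majority(self):
        y = np.array([0, 0, 0, 1, 1])
        assert balanced_accuracy(y, y) == 100.0
        assert balanced_accuracy(y, np.zeros(5, int)) == 50.0

    def test_confusion_matrix_formula(self):
        # TP=3 FN=1 TN=2 FP=2 -> (0.75 + 0.5)/2 = 62.5%
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        assert balanced_accuracy(y_true, y_pred) == 62.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.zeros(4, int), np.zeros(4, int))


class TestFoldPlan:
    def test_100_metrics_at_10x10(self):
        y = np.array([0] * 20 + [1] * 20)
        plan = make_fold_plan(y, k=10, repeats=10, seed=1)
        assert plan.n_folds == 100
        # within each repeat the test folds partition the subjects
        for rep in range(10):
            test_union = np.concatenate(
                [te for _, te in plan.folds[rep * 10 : (rep + 1) * 10]]
            )
            assert sorted(test_union) == list(range(40))

    def test_stratification_balance(self):
        y = np.array([0] * 25 + [1] * 15)
        plan = make_fold_plan(y, k=5, repeats=1, seed=0)
        for _, te in plan.folds:
            assert abs(np.mean(y[te]) - 15 / 40) <= 1 / len(te) + 1e-9

    def test_reproducible_from_seed(self):
        y = np.array([0] * 12 + [1] * 12)
        a = make_fold_plan(y, k=4, repeats=2, seed=9)
        b = make_fold_plan(y, k=4, repeats=2, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.folds, b.folds):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_infeasible_stratification_reports_class_size(self):
        y = np.array([0] * 30 + [1] * 5)
        with pytest.raises(ValueError, match="5"):
            make_fold_plan(y, k=10, repeats=1)


class TestRepeatedCV:
    def test_separable_data_perfect_scores(self, rng):
        y = np.array([0] * 15 + [1] * 15)
        X = rng.standard_normal((30, 5))
        X[y == 1, 0] += 20.0
        ev = run_repeated_cv(_rep(X, y), k=5, repeats=2, seed=0)
        assert ev.mean_ba == 100.0
        assert np.nanmean(ev.aucs) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        """Averaged over label shuffles, out-of-sample accuracy is chance;
        any single dataset draw can deviate by several points."""
        y = np.array([0] * 30 + [1] * 30)
        X = rng.standard_normal((60, 10))
        perm_rng = np.random.default_rng(99)
        means = []
        for i in range(20):
            y_perm = perm_rng.permutation(y)
            ev = run_repeated_cv(_rep(X, y_perm), k=10, repeats=1, seed=i)
            means.append(ev.mean_ba)
        assert len(ev.balanced_accuracies) == 10
        assert abs(np.mean(means) - 50) < 3

    def test_shared_fold_plans_across_models(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        ev1 = run_repeated_cv(_rep(rng.standard_normal((20, 3)), y), k=5, repeats=2, seed=7)
        ev2 = run_repeated_cv(_rep(rng.standard_normal((20, 3)), y), k=5, repeats=2, seed=7)
        for (tr1, te1), (tr2, te2) in zip(ev1.plan.folds, ev2.plan.folds):
            assert np.array_equal(te1, te2)

    def test_balanced_weights_match_unweighted(self, rng):
        from sklearn.svm import SVC

        y = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 4)) + y[:, None]
        w = SVC(kernel="linear", C=1).fit(X, y).decision_function(X)
        weights = np.full(20, 20 / (2 * 10.0))  # inverse-probability = 1 here
        w2 = SVC(kernel="linear", C=1).fit(X, y, sample_weight=weights).decision_function(X)
        np.testing.assert_allclose(w, w2, atol=1e-8)

    def test_no_leakage_from_test_rows(self, rng):
        """Perturbing test-fold values never changes fitted normalization."""
        y = np.array([0] * 10 + [1] * 10)
        X = rng.standard_normal((20, 4))
        plan = make_fold_plan(y, k=5, repeats=1, seed=3)
        train_idx, test_idx = plan.folds[0]
        params_a = mixed_sigmoid_fit(X[train_idx])
        X_mut = X.copy()
        X_mut[test_idx] += 100.0
        params_b = mixed_sigmoid_fit(X_mut[train_idx])
        np.testing.assert_array_equal(params_a.center, params_b.center)
        np.testing.assert_array_equal(params_a.scale, params_b.scale)
        # imputation medians likewise depend on training rows only
        from dynsig.cv import _impute_train_medians

        X_nan = X.copy()
        X_nan[train_idx[0], 0] = np.nan
        tr_a, _ = _impute_train_medians(X_nan[train_idx], X[test_idx])
        tr_b, _ = _impute_train_medians(X_nan[train_idx], X_mut[test_idx])
        np.testing.assert_array_equal(tr_a, tr_b)

    def test_missing_values_imputed_in_fold(self, rng):
        y = np.array([0] * 12 + [1] * 12)
        X = rng.standard_normal((24, 3))
        X[::5, 1] = np.nan
        ev = run_repeated_cv(_rep(X, y), k=4, repeats=1, seed=0)
        assert np.all(np.isfinite(ev.balanced_accuracies))


class TestConfoundCV:
    def test_uninformative_covariate_near_chance(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        age = rng.normal(30, 5, 40)
        ev = confound_cv(age, y, k=5, repeats=2, seed=1)
        assert abs(ev.mean_ba - 50) < 15

    def test_perfectly_separating_covariate(self):
        y = np.array([0] * 20 + [1] * 20)
        sex = y.astype(float)  # encodes the group exactly
        ev = confound_cv(sex, y, k=5, repeats=2, seed=1)
        assert ev.mean_ba == 100.0

    def test_concatenation_dimension(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        rep = _rep(rng.standard_normal((20, 6)), y)
        cov = rng.standard_normal((20, 2))
        ev = confound_cv(cov, y, k=5, repeats=1, seed=0, representation=rep)
        assert ev.model_tag.endswith("+confounds")
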