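import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import gaitfall as gf
from gaitfall.classify import DEFAULT_GRIDS, LABEL_ORDER, feature_matrix
from gaitfall.exceptions import ParameterError, RegistryError


@pytest.fixture(scope="module")
def table():
    return gf.simulate_feature_table(gf.PopulationParams(seed=5))


@pytest.fixture(scope="module")
def balanced(table):
    return gf.smote_oversample(table, gf.SmoteParams(seed=5))


class TestSmote:
    def test_balances_to_parity_with_synthetic_rows_appended(self, table, balanced):
        assert len(balanced) == 88
        assert balanced.label.value_counts().to_dict() == {"faller": 44, "non_faller": 44}
        assert (balanced.provenance == "smote").sum() == 23

    def test_original_rows_preserved_bit_exactly(self, table, balanced):
        X0, _ = feature_matrix(table)
        Xb, _ = feature_matrix(balanced)
        assert np.array_equal(X0.to_numpy(), Xb.to_numpy()[: len(table)])

    def test_already_balanced_input_unchanged(self):
        t = gf.simulate_feature_table(gf.PopulationParams.null(20, seed=1))
        out = gf.smote_oversample(t, gf.SmoteParams(seed=1))
        assert len(out) == len(t)

    def test_synthetic_points_lie_on_minority_segments(self, table, balanced):
        Xmin, _ = feature_matrix(table[table.label == "non_faller"])
        Xmin = Xmin.to_numpy()
        Xs, _ = feature_matrix(balanced[balanced.provenance == "smote"])
        for p in Xs.to_numpy():
            # distance from p to the nearest segment between two minority rows
            best = np.inf
            for i in range(len(Xmin)):
                for j in range(len(Xmin)):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    t = np.clip(np.dot(p - Xmin[i], d) / np.dot(d, d), 0, 1)
                    best = min(best, np.linalg.norm(p - (Xmin[i] + t * d)))
            assert best < 1e-9

    def test_k_too_large_for_minority(self, table):
        small = pd.concat([table[table.label == "faller"],
                           table[table.label == "non_faller"].head(4)])
        with pytest.raises(ParameterError):
            gf.smote_oversample(small.reset_index(drop=True), gf.SmoteParams(k_neighbors=5))


class TestStandardScale:
    def test_fitted_output_has_zero_mean_unit_sd(self, table):
        scaled, _ = gf.standard_scale(table)
        X, _ = feature_matrix(scaled)
        np.testing.assert_allclose(X.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(X.std(ddof=0), 1, atol=1e-9)

    def test_hand_computed_three_row_fixture(self):
        train = pd.DataFrame({
            "average_stride_time": [1.0, 1.2, 1.4],
            "average_step_time": [0.4, 0.5, 0.6],
            "average_stance_time": [0.6, 0.7, 0.8],
            "cadence": [100.0, 110.0, 120.0],
            "label": ["faller", "non_faller", "faller"],
        })
        scaled, params = gf.standard_scale(train)
        # mu = 1.2, s = sqrt(2/75) for stride; by hand: (1.0-1.2)/0.1633 = -1.2247
        assert scaled.loc[0, "average_stride_time"] == pytest.approx(-1.224744871)
        shifted = train.copy()
        shifted["average_stride_time"] += 0.2
        out, _ = gf.standard_scale(shifted, params)
        np.testing.assert_allclose(
            out["average_stride_time"],
            scaled["average_stride_time"] + 0.2 / params.s["average_stride_time"],
            atol=1e-12)

    def test_single_value_at_mean_maps_to_zero(self, table):
        _, params = gf.standard_scale(table)
        one = table.head(1).copy()
        for c in params.mu.index:
            one[c] = params.mu[c]
        out, _ = gf.standard_scale(one, params)
        np.testing.assert_allclose(feature_matrix(out)[0].to_numpy(), 0, atol=1e-12)

    def test_zero_variance_column_named(self, table):
        t = table.copy()
        t["cadence"] = 100.0
        with pytest.raises(ParameterError, match="cadence"):
            gf.standard_scale(t)

    def test_no_test_leakage_into_scaler(self, table, balanced):
        train, test = gf.stratified_split(balanced, seed=0)
        _, params = gf.standard_scale(train)
        perturbed = test.copy()
        perturbed[gf.PER_FOOT_COLUMNS[:-1]] *= 3.0
        _, params2 = gf.standard_scale(train)  # refit after "seeing" new test
        pd.testing.assert_series_equal(params.mu, params2.mu)
        out_a, _ = gf.standard_scale(test, params)
        out_b, _ = gf.standard_scale(perturbed, params)
        assert not out_a[gf.PER_FOOT_COLUMNS[:-1]].equals(out_b[gf.PER_FOOT_COLUMNS[:-1]])


class TestStratifiedSplit:
    def test_protocol_counts_on_balanced_table(self, balanced):
        train, test = gf.stratified_split(balanced, 0.70, seed=0)
        assert (len(train), len(test)) == (61, 27)
        assert test.label.value_counts().to_dict() == {"faller": 14, "non_faller": 13}

    def test_partition_is_disjoint_and_complete(self, balanced):
        train, test = gf.stratified_split(balanced, 0.70, seed=3)
        ids = sorted(train.subject_id) + sorted(test.subject_id)
        assert sorted(ids) == sorted(balanced.subject_id)
        assert set(train.subject_id).isdisjoint(test.subject_id)

    def test_reproducible_under_fixed_seed(self, balanced):
        t1 = gf.stratified_split(balanced, seed=11)
        t2 = gf.stratified_split(balanced, seed=11)
        pd.testing.assert_frame_equal(t1[0], t2[0])
        pd.testing.assert_frame_equal(t1[1], t2[1])

    def test_class_proportions_within_one_row(self, table):
        train, test = gf.stratified_split(table, seed=1)
        p_global = (table.label == "faller").mean()
        for part in (train, test):
            expected = p_global * len(part)
            assert abs((part.label == "faller").sum() - expected) <= 1

    def test_tiny_class_rejected(self, table):
        bad = pd.concat([table[table.label == "faller"],
                         table[table.label == "non_faller"].head(1)])
        with pytest.raises(ParameterError):
            gf.stratified_split(bad.reset_index(drop=True))


class TestModels:
    def test_registry_has_twelve_models(self):
        assert len(gf.MODEL_NAMES) == 12
        assert {"svm", "decision_tree", "random_forest", "lightgbm", "xgboost",
                "adaboost", "knn", "voting", "naive_bayes", "mlp",
                "bagging"} < set(gf.MODEL_NAMES)

    def test_unknown_model_rejected(self, table):
        with pytest.raises(RegistryError):
            gf.fit_model(table, "perceptron_tower")

    def test_grid_of_size_one_equals_direct_fit(self, balanced):
        train, test = gf.stratified_split(balanced, seed=2)
        a = gf.evaluate(gf.fit_model(train, "decision_tree", {"max_depth": [3]}, seed=2), test)
        from sklearn.tree import DecisionTreeClassifier

        direct = DecisionTreeClassifier(max_depth=3, random_state=2)
        X, y = feature_matrix(train)
        direct.fit(X, (y == "faller").astype(int))
        Xt, yt = feature_matrix(test)
        acc = ((direct.predict(Xt) == 1) == (yt == "faller")).mean()
        assert a.accuracy == pytest.approx(acc)

    def test_best_grid_score_is_the_maximum(self, balanced):
        train, _ = gf.stratified_split(balanced, seed=2)
        clf = gf.fit_model(train, "knn", {"n_neighbors": [1, 3, 5, 9]}, seed=2)
        assert clf.best_cv_score_ == pytest.approx(
            max(clf.cv_results_["mean_test_score"]))

    def test_tree_fits_separable_data_perfectly(self):
        t = gf.simulate_feature_table(gf.PopulationParams(seed=9))
        t2 = t.copy()
        # force perfect separation on one feature
        t2.loc[t2.label == "faller", "cadence"] += 1000.0
        clf = gf.fit_model(t2, "decision_tree", seed=9)
        assert gf.evaluate(clf, t2).accuracy == 1.0

    def test_estimator_is_sklearn_compatible(self, balanced):
        clf = gf.FallRiskClassifier(model="knn", param_grid={"n_neighbors": [3]})
        assert clone(clf).get_params()["model"] == "knn"
        X, y = feature_matrix(balanced)
        clf.fit(X, y)
        assert set(clf.predict(X)) <= set(LABEL_ORDER)
        assert list(clf.classes_) == LABEL_ORDER
        assert clf.score(X, y) > 0.5


class TestEvaluate:
    def test_accuracy_and_confusion_consistency(self, balanced):
        train, test = gf.stratified_split(balanced, seed=4)
        result = gf.evaluate(gf.fit_model(train, "naive_bayes", seed=4), test)
        cm = result.confusion_matrix
        assert cm.sum() == len(test)
        assert result.accuracy == pytest.approx(np.trace(cm) / cm.sum())
        # brute-force recount
        clf = gf.fit_model(train, "naive_bayes", seed=4)
        X, y = feature_matrix(test)
        manual = float(np.mean(clf.predict(X) == y.to_numpy()))
        assert result.accuracy == pytest.approx(manual)

    def test_perfect_and_constant_predictors(self, balanced):
        train, test = gf.stratified_split(balanced, seed=4)

        class Stub:
            def __init__(self, labels):
                self._labels = labels
                self.model = "stub"
                self.best_params_ = {}
                self.feature_importances_ = None
                self.feature_names_in_ = np.array(gf.PER_FOOT_COLUMNS[:-1])

            def predict(self, X):
                return self._labels(len(X))

        perfect = Stub(lambda n: test.label.to_numpy())
        res = gf.evaluate(perfect, test)
        assert res.accuracy == 1.0
        assert res.confusion_matrix[0, 1] == res.confusion_matrix[1, 0] == 0

        constant = Stub(lambda n: np.array(["faller"] * n))
        res = gf.evaluate(constant, test)
        assert res.accuracy == pytest.approx((test.label == "faller").mean())

    def test_importances_exposed_for_tree_models(self, balanced):
        train, test = gf.stratified_split(balanced, seed=4)
        res = gf.evaluate(gf.fit_model(train, "lightgbm", {"num_leaves": [7]}, seed=4), test)
        assert set(res.importances) == set(gf.PER_FOOT_COLUMNS[:-1])


class TestRunExperiment:
    def test_single_model_single_ablation(self, table):
        spec = gf.ExperimentSpec(models=["knn"], ablations=["full"], seed=0)
        res = gf.run_experiment(table, spec)
        assert res.accuracy.shape == (1, 1)
        assert 0.0 <= res.accuracy.loc["full", "knn"] <= 1.0

    def test_none_equals_no_smote_plus_no_scaling(self, table):
        spec = gf.ExperimentSpec(models=["decision_tree", "naive_bayes"],
                                 ablations=["none"], seed=7)
        res_none = gf.run_experiment(table, spec)
        # manual composition: split only, no balancing, no scaling
        train, test = gf.stratified_split(table, 0.70, seed=7)
        for name in spec.models:
            manual = gf.evaluate(gf.fit_model(train, name, seed=7), test)
            assert res_none.accuracy.loc["none", name] == pytest.approx(manual.accuracy)

    def test_smote_after_split_keeps_test_free_of_synthetic_rows(self, table):
        spec = gf.ExperimentSpec(models=["knn"], ablations=["full"],
                                 smote_after_split=True, seed=0)
        res = gf.run_experiment(table, spec)  # should run without error
        # and the test set size comes from the 65-row table: ceil(0.3*65)=20
        assert res.details[("full", "knn")].confusion_matrix.sum() == 20

    def test_averaged_schema_experiment(self, table):
        avg = gf.to_averaged_schema(table)
        spec = gf.ExperimentSpec(schema="averaged", models=["naive_bayes"],
                                 ablations=["full", "none"], seed=1)
        res = gf.run_experiment(avg, spec)
        assert res.accuracy.notna().all().all()
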