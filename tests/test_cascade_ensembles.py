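import numpy as np
import pandas as pd
import pytest

from cardiolos.cascade_ensembles import (
    ArchitectureError,
    CascadeSpec,
    augment_features,
    fit_avg_vote,
    fit_cascade,
    fit_parallel_cascade,
    fit_sequential_cascade,
    resolve_columns,
)
from cardiolos.learners import LearnerSpec, build_estimator
from cardiolos.transforms import inverse_log_transform, log_transform

RF = LearnerSpec("rf_regressor", "FS-1", {"n_estimators": 30}, seed=1)
RF2 = LearnerSpec("rf_regressor", "FS-2", {"n_estimators": 30}, seed=2)
GB = LearnerSpec("xgb_regressor", "FS-1",
                 {"n_estimators": 40, "max_depth": 3}, seed=3)
ANN = LearnerSpec("ann_regressor", "FS-9",
                  {"hidden1": 8, "hidden2": 8, "epochs": 10,
                   "batch_size": 64}, seed=4)
CLF = LearnerSpec("rf_classifier", "FS-1", {"n_estimators": 30}, seed=5)


class TestSpecValidation:
    def test_avg_vote_needs_two_regressors(self):
        with pytest.raises(ArchitectureError):
            CascadeSpec("avg_vote", (RF,))

    def test_avg_vote_rejects_classifier(self):
        with pytest.raises(ArchitectureError):
            CascadeSpec("avg_vote", (RF, GB), classifier=CLF)

    @pytest.mark.parametrize("arch,n", [("seq2", 2), ("seq3", 1),
                                        ("parallel", 3)])
    def test_wrong_regressor_counts(self, arch, n):
        with pytest.raises(ArchitectureError):
            CascadeSpec(arch, tuple([RF] * n), classifier=CLF)

    def test_sequential_needs_classifier(self):
        with pytest.raises(ArchitectureError):
            CascadeSpec("seq2", (RF,))

    def test_unknown_architecture(self):
        with pytest.raises(ArchitectureError):
            CascadeSpec("stacking", (RF,))

    def test_single_architecture(self):
        spec = CascadeSpec("single", (RF,))
        assert spec.architecture == "single"


class TestAugment:
    def test_empty_meta_identity(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        out = augment_features(X, pd.DataFrame(index=X.index))
        pd.testing.assert_frame_equal(out, X)

    def test_width_addition(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 10)),
                         columns=[f"c{i}" for i in range(10)])
        meta = pd.DataFrame(rng.normal(size=(5, 4)),
                            columns=[f"P{i}" for i in range(4)])
        out = augment_features(X, meta)
        assert out.shape[1] == 14
        assert list(out.columns[:10]) == list(X.columns)

    def test_original_values_preserved(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        meta = pd.DataFrame({"m": np.arange(6.0)})
        out = augment_features(X, meta)
        np.testing.assert_array_equal(out[list("abc")].values, X.values)

    def test_row_mismatch_raises(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="row count"):
            augment_features(X, pd.DataFrame({"m": [1.0]}))


def test_resolve_columns_inherits_parent():
    cols = ["x", "t=b", "t=c", "y"]
    pm = {"x": "x", "t=b": "t", "t=c": "t", "y": "y"}
    assert resolve_columns(cols, ["t", "y"], pm) == ["t=b", "t=c", "y"]
    with pytest.raises(ValueError):
        resolve_columns(cols, ["absent"], pm)


class TestAvgVote:
    def test_mean_is_exact(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, GB, ANN))
        fitted = fit_avg_vote(X, y, spec, registry, pre.parent_map)
        preds = [fitted.components[f"regressor_{i}"].predict(
            X[fitted.inventories[f"regressor_{i}"]].values) for i in range(3)]
        np.testing.assert_array_equal(fitted.predict(X),
                                      np.mean(preds, axis=0))

    def test_three_component_hand_example(self):
        class Const:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        X = pd.DataFrame({"a": [0.0, 1.0]})
        spec = CascadeSpec("avg_vote", (RF, GB, ANN))
        from cardiolos.cascade_ensembles import FittedCascade
        fitted = FittedCascade(spec=spec, input_columns=["a"])
        for i, v in enumerate((0.1, 0.2, 0.6)):
            fitted.components[f"regressor_{i}"] = Const(v)
            fitted.inventories[f"regressor_{i}"] = ["a"]
        np.testing.assert_allclose(fitted.predict(X), [0.3, 0.3])

    def test_identical_components_mean_is_component(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, RF))
        fitted = fit_avg_vote(X, y, spec, registry, pre.parent_map)
        single = fitted.components["regressor_0"].predict(
            X[fitted.inventories["regressor_0"]].values)
        np.testing.assert_allclose(fitted.predict(X), single)

    def test_bounded_by_component_extremes(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, GB, ANN))
        fitted = fit_avg_vote(X, y, spec, registry, pre.parent_map)
        preds = np.array([fitted.components[f"regressor_{i}"].predict(
            X[fitted.inventories[f"regressor_{i}"]].values) for i in range(3)])
        final = fitted.predict(X)
        assert np.all(final >= preds.min(axis=0) - 1e-12)
        assert np.all(final <= preds.max(axis=0) + 1e-12)


class TestSequentialCascades:
    def test_seq2_matches_manual_composition(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("seq2", (RF,), classifier=CLF)
        fitted = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)

        # independent hand-wired pipeline under the same seeds
        clf_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                   pre.parent_map)
        clf = build_estimator(CLF)
        clf.fit(X[clf_cols].values, bundle.los_category)
        proba = pd.DataFrame(
            clf.predict_proba(X[clf_cols].values),
            columns=[f"CLS-PROBA-{c}" for c in clf.classes_], index=X.index)
        reg_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                   pre.parent_map)
        X_aug = pd.concat([X[reg_cols], proba], axis=1)
        reg = build_estimator(RF)
        reg.fit(X_aug.values, np.asarray(y))
        manual = reg.predict(X_aug.values)

        np.testing.assert_array_equal(fitted.predict(X), manual)

    def test_seq3_matches_manual_composition(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("seq3", (RF, RF2), classifier=CLF)
        fitted = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)

        clf_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                   pre.parent_map)
        clf = build_estimator(CLF)
        clf.fit(X[clf_cols].values, bundle.los_category)
        proba = pd.DataFrame(
            clf.predict_proba(X[clf_cols].values),
            columns=[f"CLS-PROBA-{c}" for c in clf.classes_], index=X.index)
        r0_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                  pre.parent_map)
        X0 = pd.concat([X[r0_cols], proba], axis=1)
        reg0 = build_estimator(RF)
        reg0.fit(X0.values, np.asarray(y))
        r0_hat = reg0.predict(X0.values)
        r1_cols = resolve_columns(X.columns, registry.features("FS-2"),
                                  pre.parent_map)
        X1 = pd.concat(
            [X[r1_cols], pd.DataFrame({"REG1-PRED": r0_hat}, index=X.index)],
            axis=1)
        reg1 = build_estimator(RF2)
        reg1.fit(X1.values, np.asarray(y))
        manual = reg1.predict(X1.values)

        np.testing.assert_array_equal(fitted.predict(X), manual)

    def test_seq3_regressor2_width_is_subset_plus_one(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("seq3", (RF, RF2), classifier=CLF)
        fitted = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)
        d = len(fitted.inventories["regressor_1_base"])
        assert fitted.components["regressor_1"].n_features_in_ == d + 1

    def test_seq2_determinism(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("seq2", (RF,), classifier=CLF)
        p1 = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map).predict(X)
        p2 = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_probability_columns_valid(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("seq2", (RF,), classifier=CLF)
        fitted = fit_sequential_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)
        proba = fitted.components["classifier"].predict_proba(
            X[fitted.inventories["classifier"]].values)
        assert proba.shape[1] == 4
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert fitted.class_order == [0, 1, 2, 3]


class TestParallelCascade:
    def test_matches_manual_composition(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("parallel", (RF, RF2), classifier=CLF)
        fitted = fit_parallel_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)

        clf_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                   pre.parent_map)
        clf = build_estimator(CLF)
        clf.fit(X[clf_cols].values, bundle.los_category)
        proba = pd.DataFrame(
            clf.predict_proba(X[clf_cols].values),
            columns=[f"CLS-PROBA-{c}" for c in clf.classes_], index=X.index)
        r0_cols = resolve_columns(X.columns, registry.features("FS-1"),
                                  pre.parent_map)
        reg0 = build_estimator(RF)
        reg0.fit(X[r0_cols].values, np.asarray(y))
        r0_hat = reg0.predict(X[r0_cols].values)
        r1_cols = resolve_columns(X.columns, registry.features("FS-2"),
                                  pre.parent_map)
        X1 = pd.concat(
            [X[r1_cols], proba,
             pd.DataFrame({"REG1-PRED": r0_hat}, index=X.index)], axis=1)
        reg1 = build_estimator(RF2)
        reg1.fit(X1.values, np.asarray(y))
        manual = reg1.predict(X1.values)

        np.testing.assert_array_equal(fitted.predict(X), manual)

    def test_regressor2_width_is_d_plus_five(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("parallel", (RF, RF2), classifier=CLF)
        fitted = fit_parallel_cascade(
            X, y, bundle.los_category, spec, registry, pre.parent_map)
        d = len(fitted.inventories["regressor_1_base"])
        assert fitted.components["regressor_1"].n_features_in_ == d + 5


class TestPredictContract:
    def test_row_counts(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, GB))
        fitted = fit_cascade(X, y, bundle.los_category, spec, registry,
                             pre.parent_map)
        assert len(fitted.predict(X.head(17))) == 17

    def test_inventory_mismatch_named(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, GB))
        fitted = fit_cascade(X, y, bundle.los_category, spec, registry,
                             pre.parent_map)
        with pytest.raises(ValueError, match="missing"):
            fitted.predict(X.drop(columns=[X.columns[0]]))

    def test_back_transform_inverse_identity(self):
        y = np.array([0.0, 1.0, 7.0, 30.0])
        z = log_transform(y)
        lo, hi = z.min(), z.max()
        scaled = (z - lo) / (hi - lo)
        restored = inverse_log_transform(scaled * (hi - lo) + lo)
        np.testing.assert_allclose(restored, y, atol=1e-10)

    def test_predict_days_back_transform(self, model_data):
        X, y, bundle, registry, pre = model_data
        spec = CascadeSpec("avg_vote", (RF, GB))
        fitted = fit_cascade(X, y, bundle.los_category, spec, registry,
                             pre.parent_map)
        days = fitted.predict_days(X, target_scaler=pre.target_range_)
        assert np.all(days >= 0)
        manual = inverse_log_transform(
            fitted.predict(X) * (pre.target_range_[1] - pre.target_range_[0])
            + pre.target_range_[0])
        np.testing.assert_allclose(days, manual, atol=1e-12)


def test_cross_fit_mode_changes_training_meta(model_data):
    X, y, bundle, registry, pre = model_data
    spec = CascadeSpec("seq2", (RF,), classifier=CLF)
    in_sample = fit_sequential_cascade(
        X, y, bundle.los_category, spec, registry, pre.parent_map,
        cross_fit=False).predict(X)
    oof = fit_sequential_cascade(
        X, y, bundle.los_category, spec, registry, pre.parent_map,
        cross_fit=True).predict(X)
    assert not np.array_equal(in_sample, oof)
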