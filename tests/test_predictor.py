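import dataclasses

import numpy as np
import pandas as pd
import pytest

from istpdose import CohortConfig, SvrConfig, generate_cohort
from istpdose.cohort import SUV_LINKS
from istpdose.predictor import (
    build_design,
    build_feature_matrix,
    kfold_validate,
    mape,
    optimize_hyperparameters,
    predict_teff,
    train_svr,
)


@pytest.fixture(scope="module")
def linked_cohort():
    """Deterministic link (no SUV noise, no measurement noise): features
    determine T_eff exactly through suv = a + b*ln(T_eff)."""
    cfg = CohortConfig(n_patients=40, seed=9, noise_cv=0.0, link_noise_scale=0.0)
    return generate_cohort(cfg)


def targets_of(cohort):
    return cohort.truth[["patient_id", "cycle", "organ", "teff_hours"]]


class TestFeatureMatrix:
    def test_shape_and_alignment(self, linked_cohort):
        X, y, keys = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        assert len(X) == len(y) == len(keys) == len(linked_cohort.features)
        assert X.shape[1] == len(X.columns)
        assert (y > 0).all()

    def test_duplicated_patient_cycle_rejected(self, linked_cohort):
        rows = pd.concat(
            [linked_cohort.features, linked_cohort.features.iloc[[0]]],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="duplicated"):
            build_feature_matrix(rows, "liver", targets_of(linked_cohort))

    def test_all_missing_mandatory_column_rejected(self, linked_cohort):
        rows = linked_cohort.features.copy()
        rows["ldh"] = np.nan
        with pytest.raises(ValueError, match="ldh"):
            build_design(rows)

    def test_unknown_condition_category_rejected(self, linked_cohort):
        rows = linked_cohort.features.copy()
        rows.loc[rows.index[0], "organ_condition_class"] = "transplanted"
        with pytest.raises(ValueError, match="transplanted"):
            build_design(rows)

    def test_missing_values_are_imputed_with_training_median(self, linked_cohort):
        rows = linked_cohort.features.copy()
        rows.loc[rows.index[0], "psa_ng_ml"] = np.nan
        X = build_design(rows)
        model = train_svr(X, np.full(len(X), 20.0), SvrConfig(epsilon=0.5))
        imputer = model.pipeline.named_steps["impute"]
        col = list(X.columns).index("psa_ng_ml")
        assert imputer.statistics_[col] == pytest.approx(
            X["psa_ng_ml"].median()
        )


class TestTrainSvr:
    def test_constant_target_flat_fit(self, linked_cohort):
        X = build_design(linked_cohort.features)
        y = np.full(len(X), 20.0)
        model = train_svr(X, y, SvrConfig(C=10.0, epsilon=0.5))
        assert np.allclose(model.predict(X), 20.0, atol=0.5)

    def test_row_permutation_invariance(self, linked_cohort):
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        model_a = train_svr(X, y, SvrConfig())
        perm = np.random.default_rng(0).permutation(len(X))
        model_b = train_svr(X.iloc[perm], y.iloc[perm], SvrConfig())
        assert np.allclose(model_a.predict(X), model_b.predict(X), atol=1e-8)

    def test_zero_variance_column_dropped_and_logged(self, linked_cohort):
        X = build_design(linked_cohort.features).copy()
        X["constant"] = 1.0
        model = train_svr(X, np.linspace(10, 30, len(X)), SvrConfig())
        assert "constant" in model.dropped_columns_

    def test_predictions_clamped_at_floor(self, linked_cohort):
        X = build_design(linked_cohort.features)
        model = train_svr(X, np.full(len(X), 1.0) + 1e-6, SvrConfig(epsilon=0.0))
        assert (model.predict(X) >= model.min_teff_hours).all()

    def test_strong_single_feature_link_fits_well(self, linked_cohort):
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        model = train_svr(X, y, SvrConfig(C=100.0, epsilon=0.1))
        assert mape(np.asarray(y), model.predict(X)) < 10.0


class TestHyperparameterSearch:
    def test_singleton_grid_returned_unchanged(self, linked_cohort):
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        only = SvrConfig(C=3.0, epsilon=0.7, gamma=0.05)
        assert optimize_hyperparameters(X, y, grid=[only]) == only

    def test_argmin_contract_and_determinism(self, linked_cohort):
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        grid = [SvrConfig(C=c, epsilon=e) for c in (1.0, 100.0) for e in (0.1, 2.0)]
        pick1 = optimize_hyperparameters(X, y, grid=grid, seed=4)
        pick2 = optimize_hyperparameters(X, y, grid=grid, seed=4)
        assert pick1 == pick2
        assert pick1 in grid

    def test_empty_grid_rejected(self, linked_cohort):
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        with pytest.raises(ValueError):
            optimize_hyperparameters(X, y, grid=[])


class TestKfoldValidate:
    def test_fold_mape_definition(self):
        # predictions {12, 8} against truths {10, 10}: fold MAPE = 20%
        assert mape(np.array([10.0, 10.0]), np.array([12.0, 8.0])) == pytest.approx(20.0)

    def test_oracle_predictor_zero_error(self, linked_cohort):
        """A predictor inverting the noise-free SUV link reproduces T_eff
        exactly, so every fold's ME is 0."""
        a, b, _ = SUV_LINKS["liver"]

        class Oracle:
            def predict(self, X):
                return np.exp((X["suv_mean_liver"].to_numpy() - a) / b)

        report = kfold_validate(
            linked_cohort.features,
            targets_of(linked_cohort),
            "liver",
            k=10,
            seed=0,
            predictor_factory=lambda X, y: Oracle(),
        )
        assert report.me_mean_percent == pytest.approx(0.0, abs=1e-9)
        assert all(me == pytest.approx(0.0, abs=1e-9) for me in report.fold_me_percent)

    def test_partition_properties(self, linked_cohort):
        report = kfold_validate(
            linked_cohort.features,
            targets_of(linked_cohort),
            "liver",
            k=10,
            seed=0,
            fixed_config=SvrConfig(),
        )
        folds = report.predictions["fold"]
        sizes = folds.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert (folds >= 0).all()
        assert len(report.fold_me_percent) == 10

    def test_too_few_rows_suggests_smaller_k(self, linked_cohort):
        with pytest.raises(ValueError, match="smaller k"):
            kfold_validate(
                linked_cohort.features.head(5),
                targets_of(linked_cohort),
                "liver",
                k=10,
            )

    def test_by_patient_grouping_keeps_patients_whole(self, linked_cohort):
        report = kfold_validate(
            linked_cohort.features,
            targets_of(linked_cohort),
            "liver",
            k=5,
            grouping="by_patient",
            seed=0,
            fixed_config=SvrConfig(),
        )
        per_patient_folds = report.predictions.groupby("patient_id")["fold"].nunique()
        assert (per_patient_folds == 1).all()

    def test_bitwise_reproducibility(self, linked_cohort):
        kw = dict(k=5, seed=3, fixed_config=SvrConfig())
        r1 = kfold_validate(linked_cohort.features, targets_of(linked_cohort), "spleen", **kw)
        r2 = kfold_validate(linked_cohort.features, targets_of(linked_cohort), "spleen", **kw)
        assert r1.fold_me_percent == r2.fold_me_percent
        assert r1.predictions.equals(r2.predictions)

    def test_scaler_fitted_on_training_fold_only(self, linked_cohort):
        """Leakage audit: the pipeline's scaler statistics equal the training
        rows' statistics, not those of the pooled data."""
        X, y, _ = build_feature_matrix(
            linked_cohort.features, "liver", targets_of(linked_cohort)
        )
        train = X.iloc[: len(X) // 2]
        model = train_svr(train, y.iloc[: len(X) // 2], SvrConfig())
        imputed = model.pipeline.named_steps["impute"].transform(train)
        kept = model.pipeline.named_steps["zero_var"].get_support()
        expected_means = np.nanmean(imputed[:, kept], axis=0)
        np.testing.assert_allclose(
            model.pipeline.named_steps["scale"].mean_, expected_means, rtol=1e-10
        )
        # and they differ from the full-data means (so pooling would change them)
        full_means = np.nanmean(
            model.pipeline.named_steps["impute"].transform(X)[:, kept], axis=0
        )
        assert not np.allclose(model.pipeline.named_steps["scale"].mean_, full_means)


@pytest.fixture(scope="module")
def models(linked_cohort):
    X, y, _ = build_feature_matrix(
        linked_cohort.features, "liver", targets_of(linked_cohort)
    )
    return {"liver": train_svr(X, y, SvrConfig())}


class TestPredictTeff:

    def test_first_cycle_only_substitutes_cycle1_features(self, models, linked_cohort):
        """Predictions for every cycle come from the patient's cycle-1
        pretherapy features; only the cycle index keeps its true value."""
        preds, excluded = predict_teff(models, linked_cohort.features, "first_cycle_only")
        assert excluded == []
        rows = linked_cohort.features.sort_values(["patient_id", "cycle"]).reset_index(drop=True)
        c1 = rows[rows["cycle"] == 1].set_index("patient_id")
        expected_rows = c1.loc[rows["patient_id"]].reset_index()
        expected_rows["cycle"] = rows["cycle"].to_numpy()
        expected = models["liver"].predict(build_design(expected_rows))
        got = preds[preds["organ"] == "liver"].sort_values(["patient_id", "cycle"])
        assert np.allclose(got["teff_pred_hours"].to_numpy(), expected)

    def test_patient_missing_cycle1_excluded(self, models, linked_cohort):
        rows = linked_cohort.features
        victim = rows.loc[rows["cycle"] > 1, "patient_id"].iloc[0]
        trimmed = rows[~((rows["patient_id"] == victim) & (rows["cycle"] == 1))]
        preds, excluded = predict_teff(models, trimmed, "first_cycle_only")
        assert victim in excluded
        assert victim not in set(preds["patient_id"])

    def test_per_cycle_single_row(self, models, linked_cohort):
        one = linked_cohort.features.iloc[[0]]
        preds, _ = predict_teff(models, one, "per_cycle")
        assert len(preds) == 1

    def test_unknown_mode_rejected(self, models, linked_cohort):
        with pytest.raises(ValueError):
            predict_teff(models, linked_cohort.features, "last_cycle_only")
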