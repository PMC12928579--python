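"""Preparation pipeline: cleaning, missingness filter, imputation,
min-max scaling, sensitive binarization, stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from fairaudit import (PipelineError, SensitiveSpec, binarize_sensitive,
                       clean, default_sensitive_specs, drop_high_missingness,
                       exclude_sensitive_from_features, impute,
                       minmax_normalize, prepare, split)
from fairaudit.cohort import ROLE_LEAK
from fairaudit.preprocess import NormalizationParams, SplitPlan


class TestClean:
    def test_exact_duplicates_removed_first_kept(self):
        cohort = make_cohort({"x": [1.0, 1.0, 2.0]}, [1, 1, 0])
        out = clean(cohort)
        assert len(out.df) == 2
        assert out.meta["clean_log"]["duplicates_removed"] == 1
        assert list(out.df["x"]) == [1.0, 2.0]

    @pytest.mark.parametrize("raw, expected", [
        ("3.5", 3.5), ("  7 ", 7.0), ("1e2", 100.0),
        ("N/A", None), ("abc", None), ("", None),
    ])
    def test_text_coercion_table(self, raw, expected):
        cohort = make_cohort({"x": pd.Series([raw, "1"], dtype=object)},
                             [1, 0])
        out = clean(cohort)
        value = out.df["x"].iloc[0]
        if expected is None:
            assert pd.isna(value)
        else:
            assert value == expected

    def test_idempotent(self):
        cohort = make_cohort({"x": [1.0, 1.0, 2.0]}, [1, 1, 0])
        once = clean(cohort)
        twice = clean(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestMissingnessFilter:
    def _cohort_with_missingness(self, fracs):
        n = 10
        cols = {}
        for i, f in enumerate(fracs):
            x = np.arange(n, dtype=float)
            x[:int(round(f * n))] = np.nan
            cols[f"f{i}"] = x
        return make_cohort(cols, np.tile([0, 1], n // 2))

    def test_strictly_greater_than_threshold_dropped(self):
        """Features at {0,10,20,30,40,50}% missing: four survive at 30%."""
        cohort = self._cohort_with_missingness([0, .1, .2, .3, .4, .5])
        out = drop_high_missingness(cohort, threshold=0.30)
        assert out.clinical_columns == ["f0", "f1", "f2", "f3"]
        assert out.meta["missingness_log"]["dropped"] == ["f4", "f5"]

    def test_boundary_feature_retained(self):
        cohort = self._cohort_with_missingness([0.3])
        out = drop_high_missingness(cohort, threshold=0.30)
        assert out.clinical_columns == ["f0"]

    def test_threshold_one_is_vacuous(self):
        cohort = self._cohort_with_missingness([0.5, 0.9])
        out = drop_high_missingness(cohort, threshold=1.0)
        assert out.clinical_columns == ["f0", "f1"]

    def test_all_features_dropped_is_error(self):
        cohort = self._cohort_with_missingness([0.9, 0.8])
        with pytest.raises(PipelineError):
            drop_high_missingness(cohort, threshold=0.30)

    def test_sensitive_and_label_never_dropped(self):
        cohort = self._cohort_with_missingness([0.9, 0.0])
        out = drop_high_missingness(cohort)
        assert set(out.df.columns) >= {"age", "gender", "race", "diagnosis"}


class TestImpute:
    def test_median_fill(self):
        cohort = make_cohort({"x": [1.0, 2.0, np.nan, 4.0]}, [0, 1, 0, 1])
        out = impute(cohort)
        assert out.df["x"].iloc[2] == 2.0

    def test_no_missing_is_identity(self):
        cohort = make_cohort({"x": [1.0, 2.0, 3.0, 4.0]}, [0, 1, 0, 1])
        out = impute(cohort)
        pd.testing.assert_frame_equal(out.df, cohort.df)

    def test_mode_fill_with_smallest_tie(self):
        cohort = make_cohort({"x": [1.0, 2.0, 3.0, 4.0]}, [0, 1, 0, 1],
                             race=["B", "A", "B", None])
        cohort.df.loc[3, "race"] = np.nan
        out = impute(cohort)
        # A and B tie at 1... B has 2; mode is B. Build a real tie:
        cohort2 = make_cohort({"x": [1.0, 2.0, 3.0, 4.0]}, [0, 1, 0, 1],
                              race=["B", "A", None, None])
        cohort2.df.loc[2, "race"] = np.nan
        cohort2.df.loc[3, "race"] = np.nan
        out2 = impute(cohort2)
        assert out.df["race"].iloc[3] == "B"
        assert (out2.df["race"].iloc[2:] == "A").all()  # tie -> smallest

    def test_fit_on_train_rows_only(self):
        """Test-row values never influence the imputation statistic."""
        cohort = make_cohort({"x": [1.0, 3.0, np.nan, 100.0]}, [0, 1, 0, 1])
        out = impute(cohort, train_index=np.array([0, 1]))
        assert out.df["x"].iloc[2] == 2.0  # median of {1, 3}, not of {1,3,100}

    def test_unobserved_feature_is_error(self):
        cohort = make_cohort({"x": [np.nan, np.nan, 1.0]}, [0, 1, 0])
        with pytest.raises(PipelineError, match="'x'"):
            impute(cohort, train_index=np.array([0, 1]))


class TestMinMaxNormalize:
    def test_printed_formula_arithmetic(self):
        """y' = (y - ymin)/(ymax - ymin) * (d - c) + c; 3 in [2,6] -> 0.25."""
        cohort = make_cohort({"x": [2.0, 3.0, 6.0]}, [0, 1, 0])
        out, params = minmax_normalize(cohort)
        assert list(out.df["x"]) == [0.0, 0.25, 1.0]
        assert params.y_min["x"] == 2.0 and params.y_max["x"] == 6.0

    def test_custom_interval(self):
        cohort = make_cohort({"x": [2.0, 3.0, 6.0]}, [0, 1, 0])
        out, _ = minmax_normalize(cohort, feature_range=(-1.0, 1.0))
        assert list(out.df["x"]) == [-1.0, -0.5, 1.0]

    def test_constant_feature_maps_to_c(self):
        cohort = make_cohort({"x": [5.0, 5.0, 5.0]}, [0, 1, 0])
        out, _ = minmax_normalize(cohort)
        assert (out.df["x"] == 0.0).all()
        assert out.meta["normalize_log"]["constant_features"] == ["x"]

    def test_test_rows_clipped_into_interval(self):
        cohort = make_cohort({"x": [0.0, 10.0, -5.0, 20.0]}, [0, 1, 0, 1])
        out, _ = minmax_normalize(cohort, train_index=np.array([0, 1]))
        assert out.df["x"].between(0, 1).all()
        assert out.meta["normalize_log"]["clipped_cells"] == 2

    def test_idempotent_on_own_output(self):
        cohort = make_cohort({"x": [2.0, 3.0, 6.0]}, [0, 1, 0])
        once, _ = minmax_normalize(cohort)
        twice, _ = minmax_normalize(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestBinarizeSensitive:
    def test_age_cut_at_60(self):
        cohort = make_cohort({"x": [0.0, 1.0]}, [0, 1], age=[64.2, 43.0])
        out = binarize_sensitive(cohort)
        # privileged = under 60
        assert list(out.df["grp_age"]) == [0, 1]

    def test_race_white_privileged(self):
        cohort = make_cohort({"x": [0.0, 1.0]}, [0, 1],
                             race=["White", "Non-White"])
        out = binarize_sensitive(cohort)
        assert list(out.df["grp_race"]) == [1, 0]

    def test_gender_passthrough(self):
        cohort = make_cohort({"x": [0.0, 1.0]}, [0, 1], gender=[1, 0])
        out = binarize_sensitive(cohort)
        assert list(out.df["grp_gender"]) == [1, 0]

    def test_missing_raw_value_is_error(self):
        cohort = make_cohort({"x": [0.0, 1.0]}, [0, 1])
        cohort.df.loc[0, "age"] = np.nan
        with pytest.raises(Exception, match="age"):
            binarize_sensitive(cohort)


class TestFeatureView:
    def test_sensitive_columns_excluded(self, small_cohort):
        cohort = binarize_sensitive(small_cohort)
        X = exclude_sensitive_from_features(cohort)
        assert set(X.columns) == {"f1", "f2", "f3"}

    def test_leak_column_retained(self, small_cohort):
        cohort = small_cohort.copy()
        cohort.df["leak_s"] = 0
        cohort.roles["leak_s"] = ROLE_LEAK
        X = exclude_sensitive_from_features(cohort)
        assert "leak_s" in X.columns

    def test_view_round_trips_through_csv(self, small_cohort, tmp_path):
        X = exclude_sensitive_from_features(small_cohort)
        path = tmp_path / "x.csv"
        X.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns) == list(X.columns)


class TestSplit:
    def _cohort(self, n=1000, rate=0.6, seed=0):
        rng = np.random.default_rng(seed)
        label = np.zeros(n, dtype=int)
        label[:int(rate * n)] = 1
        rng.shuffle(label)
        return make_cohort({"x": rng.normal(size=n)}, label)

    def test_stratified_20_percent_holdout(self):
        plan = split(self._cohort(), seed=0)
        assert len(plan.test_idx) == 200
        y = self._cohort().label
        assert abs(int(y[plan.test_idx].sum()) - 120) <= 1

    def test_same_seed_identical_plan(self):
        cohort = self._cohort()
        a, b = split(cohort, seed=4), split(cohort, seed=4)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.fold_of, b.fold_of)

    def test_train_test_disjoint_exhaustive(self):
        cohort = self._cohort(n=500)
        plan = split(cohort, seed=1)
        merged = np.sort(np.concatenate([plan.train_idx, plan.test_idx]))
        assert np.array_equal(merged, np.arange(500))

    def test_folds_partition_training_rows(self):
        plan = split(self._cohort(), seed=2)
        seen = np.concatenate([val for _, val in plan.folds()])
        assert np.array_equal(np.sort(seen), plan.train_idx)

    def test_fold_class_proportions_within_one_sample(self):
        cohort = self._cohort()
        plan = split(cohort, seed=3)
        y = cohort.label
        for _, val in plan.folds():
            expected = 0.6 * len(val)
            assert abs(y[val].sum() - expected) <= 1

    def test_tiny_class_is_error(self):
        cohort = make_cohort({"x": np.arange(12.0)},
                             [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(PipelineError):
            split(cohort, seed=0)

    def test_plan_json_round_trip(self, tmp_path):
        plan = split(self._cohort(n=200), seed=5)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = SplitPlan.from_json(path)
        assert np.array_equal(back.train_idx, plan.train_idx)
        assert np.array_equal(back.fold_of, plan.fold_of)


class TestPrepare:
    def test_full_pipeline_outputs(self, default_cohort):
        cohort, plan, params = prepare(default_cohort, seed=0)
        X = exclude_sensitive_from_features(cohort)
        assert not X.isna().any().any()
        assert X.to_numpy().min() >= 0 and X.to_numpy().max() <= 1
        assert {"grp_age", "grp_gender", "grp_race"} <= set(cohort.df.columns)
        # training rows hit [0, 1] exactly per feature
        train_X = X.iloc[plan.train_idx]
        assert np.allclose(train_X.min(), 0) and np.allclose(train_X.max(), 1)

    def test_normalization_params_json_round_trip(self, small_cohort,
                                                  tmp_path):
        _, _, params = prepare(small_cohort, seed=1)
        path = tmp_path / "norm.json"
        params.to_json(path)
        back = NormalizationParams.from_json(path)
        assert back.y_min == params.y_min and back.y_max == params.y_max
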