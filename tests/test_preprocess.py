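"""Split, winsorization, one-hot encoding and forest imputation."""

import numpy as np
import pandas as pd
import pytest

from ieto_automl import preprocess, schema, simulate


def _quantile_oracle(values, q):
    """Sort-based linear-interpolation quantile, coded independently."""
    xs = sorted(values)
    pos = q * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


class TestSplit:
    def test_cohort_sized_split_matches_published_counts(self):
        table = pd.DataFrame({"x": np.arange(1879), schema.OUTCOME: 0})
        res = preprocess.split(table, seed=0)
        assert (len(res.train), len(res.test)) == (1503, 376)

    def test_small_split_floor(self):
        table = pd.DataFrame({"x": range(10), schema.OUTCOME: 0})
        res = preprocess.split(table, 0.8, seed=1)
        assert (len(res.train), len(res.test)) == (8, 2)

    def test_same_seed_identical_membership_and_disjoint(self):
        table = pd.DataFrame({"x": range(100), schema.OUTCOME: [0, 1] * 50})
        r1 = preprocess.split(table, seed=7)
        r2 = preprocess.split(table, seed=7)
        assert r1.train["x"].tolist() == r2.train["x"].tolist()
        assert set(r1.train["x"]) | set(r1.test["x"]) == set(range(100))
        assert not set(r1.train["x"]) & set(r1.test["x"])

    def test_stratified_split_preserves_prevalence(self):
        table = pd.DataFrame({"x": range(200), schema.OUTCOME: [0] * 150 + [1] * 50})
        res = preprocess.split(table, seed=3, stratify=True)
        assert len(res.train) == 160
        assert res.train[schema.OUTCOME].mean() == pytest.approx(0.25, abs=0.02)

    def test_bad_fraction_rejected(self):
        table = pd.DataFrame({"x": range(10), schema.OUTCOME: 0})
        with pytest.raises(ValueError):
            preprocess.split(table, 1.2)


class TestRectifyOutliers:
    def test_clean_data_unchanged(self, rng):
        table = pd.DataFrame({"age": rng.uniform(40, 50, 100)})
        out, report = preprocess.rectify_outliers(table, continuous=("age",))
        assert np.allclose(out["age"], table["age"])
        assert report["age"] == 0

    def test_extreme_value_clipped_exactly_to_fence(self):
        vals = list(np.linspace(1, 10, 50))
        q1, q3 = _quantile_oracle(vals, 0.25), _quantile_oracle(vals, 0.75)
        upper = q3 + 1.5 * (q3 - q1)
        train = pd.DataFrame({"age": vals})
        test = pd.DataFrame({"age": [10 * upper]})
        out, report = preprocess.rectify_outliers(train, test, continuous=("age",))
        assert out["age"].iloc[0] == pytest.approx(upper)
        assert report["age"] == 1

    def test_fences_match_sort_based_quantile_oracle(self, rng):
        vals = rng.normal(size=201)
        lo, hi = preprocess._tukey_fences(pd.Series(vals))
        q1, q3 = _quantile_oracle(vals, 0.25), _quantile_oracle(vals, 0.75)
        assert lo == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert hi == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_winsorization_idempotent(self, rng):
        train = pd.DataFrame({"age": np.concatenate([rng.normal(size=100), [40.0]])})
        once, _ = preprocess.rectify_outliers(train, continuous=("age",))
        twice, report = preprocess.rectify_outliers(train, once, continuous=("age",))
        assert np.allclose(once["age"], twice["age"])

    def test_constant_variable_untouched(self):
        train = pd.DataFrame({"age": [5.0] * 20})
        out, report = preprocess.rectify_outliers(train, continuous=("age",))
        assert (out["age"] == 5.0).all()
        assert report["age"] == 0


class TestOneHot:
    def test_two_level_variable_single_column(self):
        train = pd.DataFrame({"gender": [0, 1, 0, 1]})
        frame, names = preprocess.one_hot(train, categorical=("gender",))
        assert names == ["gender"]
        assert frame["gender"].tolist() == [0.0, 1.0, 0.0, 1.0]

    def test_three_level_variable_expands_and_sums_to_one(self):
        train = pd.DataFrame({"region": ["a", "b", "c", "a"]})
        frame, names = preprocess.one_hot(train, categorical=("region",))
        assert names == ["region=a", "region=b", "region=c"]
        assert np.allclose(frame.sum(axis=1), 1.0)

    def test_column_count_from_schema_widths(self):
        train = pd.DataFrame(
            {"b": [0, 1, 0], "m": ["x", "y", "z"], "cont": [1.0, 2.0, 3.0]}
        )
        _, names = preprocess.one_hot(train, categorical=("b", "m"))
        assert len(names) == 1 + 3 + 1

    def test_unseen_category_all_zero_with_warning(self):
        train = pd.DataFrame({"m": ["x", "y", "z"]})
        test = pd.DataFrame({"m": ["w", "x", "x"]})
        with pytest.warns(UserWarning, match="unseen"):
            frame, _ = preprocess.one_hot(train, test, categorical=("m",))
        assert frame.iloc[0].sum() == 0.0

    def test_vocabulary_from_train_only(self):
        """No information leak: apply-time data cannot change the encoding."""
        train = pd.DataFrame({"m": ["x", "y", "w"]})
        test = pd.DataFrame({"m": ["z", "z", "z"]})
        with pytest.warns(UserWarning):
            frame, names = preprocess.one_hot(train, test, categorical=("m",))
        assert names == ["m=w", "m=x", "m=y"]
        assert frame.to_numpy().sum() == 0.0


class TestRfImpute:
    def test_complete_table_identity(self, small_cohort):
        table = small_cohort.table.head(100)
        out, diag = preprocess.rf_impute(table, seed=0, m=2)
        pd.testing.assert_frame_equal(out, table)

    def test_no_missing_after_and_observed_untouched(self, small_cohort):
        table = simulate.inject_missing(small_cohort.table.head(200), rate=0.05,
                                        per_variable_cap=0.08, seed=1)
        out, _ = preprocess.rf_impute(table, seed=0, m=2)
        assert not out.isna().any().any()
        observed = ~table.isna()
        for col in table.columns:
            obs = observed[col]
            assert np.array_equal(out.loc[obs, col].to_numpy(),
                                  table.loc[obs, col].to_numpy())

    def test_beats_median_fill_on_masked_continuous_cells(self):
        """MCAR-masked ages recovered better by the forest than by the median.

        Uses the correlated generator so age carries signal through chronic
        disease and the outcome; with fully independent covariates nothing
        can beat the median.
        """
        table = simulate.generate(
            simulate.GeneratorConfig(n=500, seed=3, correlated=True)
        ).table
        truth = table["age"].to_numpy().copy()
        rng = np.random.default_rng(5)
        mask = rng.random(len(table)) < 0.05
        table.loc[mask, "age"] = np.nan
        out, _ = preprocess.rf_impute(table, seed=0, m=3)
        rf_rmse = np.sqrt(np.mean((out.loc[mask, "age"] - truth[mask]) ** 2))
        med_rmse = np.sqrt(np.mean((table["age"].median() - truth[mask]) ** 2))
        assert rf_rmse <= med_rmse

    def test_all_missing_variable_rejected(self):
        table = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="a"):
            preprocess.rf_impute(table, kinds={"a": "continuous", "b": "continuous"})


class TestPreprocessModel:
    def test_fences_learned_from_train_only(self, small_cohort):
        table = small_cohort.table
        model = preprocess.PreprocessModel().fit(table.head(400))
        fences_before = dict(model.fences)
        perturbed = table.tail(200).copy()
        perturbed["age"] = 1e6
        model.transform(perturbed)
        assert model.fences == fences_before

    def test_transform_idempotent_on_train(self, small_cohort):
        table = small_cohort.table.head(300)
        model = preprocess.PreprocessModel().fit(table)
        X1, names = model.transform(table)
        X2, _ = model.transform(table)
        assert np.array_equal(X1, X2)
        assert X1.shape == (300, len(names))
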