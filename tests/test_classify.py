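import numpy as np
import pandas as pd
import pytest

from wingbeat.classify import (
    BalancedRandomForestClassifier,
    _per_class_metrics,
    evaluate,
    importance,
    impute_median,
    leave_one_species_out,
    scaled_sample_sizes,
    split_train_validation,
    subtask_classify,
)
from wingbeat.features import FEATURE_COLUMNS


def feature_frame(X, y):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS[: X.shape[1]])
    df["species"] = y
    return df


class TestSplit:
    def test_70_30_counts(self, gaussian_species_table):
        df = gaussian_species_table.head(100)
        train, valid = split_train_validation(df, 0.7, seed=1)
        assert (len(train), len(valid)) == (70, 30)
        assert set(train.index).isdisjoint(valid.index)

    def test_same_seed_same_partition(self, gaussian_species_table):
        a = split_train_validation(gaussian_species_table, seed=5)
        b = split_train_validation(gaussian_species_table, seed=5)
        assert a[0].index.equals(b[0].index)

    def test_full_fraction_warns_empty_validation(self, gaussian_species_table):
        with pytest.warns(UserWarning, match="empty validation"):
            _, valid = split_train_validation(gaussian_species_table, 1.0, seed=0)
        assert len(valid) == 0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            split_train_validation(pd.DataFrame())


class TestImputation:
    def test_training_median_fills_training(self):
        tr = feature_frame(np.array([[1.0], [2.0], [np.nan], [3.0]]), ["a"] * 4)
        va = feature_frame(np.array([[np.nan]]), ["a"])
        tr2, va2 = impute_median(tr, va)
        assert tr2.iloc[2, 0] == 2.0

    def test_validation_never_uses_its_own_median(self):
        col = FEATURE_COLUMNS[0]
        tr = feature_frame(np.array([[5.0], [5.0], [5.0]]), ["a"] * 3)
        va = feature_frame(np.array([[9.0], [9.0], [np.nan]]), ["a"] * 3)
        _, va2 = impute_median(tr, va)
        assert va2[col].iloc[2] == 5.0  # training median, not 9

    def test_no_missing_is_identity(self, gaussian_species_table):
        tr, va = split_train_validation(gaussian_species_table, seed=2)
        tr2, va2 = impute_median(tr, va)
        pd.testing.assert_frame_equal(tr, tr2)
        pd.testing.assert_frame_equal(va, va2)

    def test_entirely_missing_feature_dropped(self):
        tr = feature_frame(np.full((3, 2), np.nan), ["a"] * 3)
        tr.iloc[:, 1] = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning, match="dropped"):
            tr2 = impute_median(tr)
        assert FEATURE_COLUMNS[0] not in tr2.columns


class TestBalancedForest:
    def test_every_bootstrap_has_configured_class_counts(self, rng):
        X = rng.normal(0, 1, (90, 5))
        y = np.array(["a"] * 50 + ["b"] * 30 + ["c"] * 10)
        sizes = {"a": 12, "b": 7, "c": 5}
        m = BalancedRandomForestClassifier(50, 3, sizes, random_state=0).fit(X, y)
        for boot in m.estimators_samples_:
            lab, counts = np.unique(y[boot], return_counts=True)
            assert dict(zip(lab, counts)) == sizes

    def test_separable_classes_low_oob_error(self, rng):
        n = 200
        X = np.vstack([rng.normal(0, 1, (n, 10)), rng.normal(8, 1, (n, 10))])  # d' >> 6
        y = np.array(["a"] * n + ["b"] * n)
        m = BalancedRandomForestClassifier(200, "sqrt", {"a": 50, "b": 50}, 1).fit(X, y)
        assert m.oob_error_ < 0.05

    def test_permuted_labels_score_at_chance(self, rng):
        k = 4
        X = rng.normal(0, 1, (1000, 8))
        y = rng.permutation(np.repeat([f"c{i}" for i in range(k)], 250))
        m = BalancedRandomForestClassifier(200, "sqrt", None, 3).fit(X, y)
        assert m.oob_error_ == pytest.approx(1 - 1 / k, abs=0.05)

    def test_single_class_and_unknown_class_errors(self, rng):
        X = rng.normal(0, 1, (20, 3))
        with pytest.raises(ValueError, match="two classes"):
            BalancedRandomForestClassifier(5).fit(X, ["a"] * 20)
        with pytest.raises(ValueError, match="sample size"):
            BalancedRandomForestClassifier(5, 2, {"a": 3}).fit(X, ["a"] * 10 + ["b"] * 10)

    def test_missing_values_rejected(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            BalancedRandomForestClassifier(5).fit(X, ["a"] * 10 + ["b"] * 10)

    def test_probabilities_sum_to_one(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = np.array(["a", "b", "c"] * 20)
        m = BalancedRandomForestClassifier(30, 2, None, 0).fit(X, y)
        np.testing.assert_allclose(m.predict_proba(X).sum(axis=1), 1.0)

    def test_oob_and_validation_error_agree(self, rng):
        # moderately separable 3-class problem, n >= 1000
        n = 400
        X = np.vstack([rng.normal(2 * i, 2, (n, 6)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], n)
        df = feature_frame(X, y)
        train, valid = split_train_validation(df, 0.7, seed=0)
        cols = list(df.columns[:6])
        m = BalancedRandomForestClassifier(300, "sqrt", None, 1).fit(
            train[cols], train["species"].to_numpy()
        )
        rep = evaluate(m, valid, feature_columns=cols)
        assert abs(m.oob_error_ - (1 - rep.accuracy)) < 0.05


class TestMetrics:
    def test_perfect_predictions(self):
        conf = pd.DataFrame([[5, 0], [0, 7]], index=["a", "b"], columns=["a", "b"])
        m = _per_class_metrics(conf)
        assert (m["TPR"] == 1).all() and (m["TNR"] == 1).all()
        assert (m["wAcc"] == 1).all() and (m["clErr"] == 0).all()

    def test_constant_predictor(self):
        conf = pd.DataFrame([[10, 0], [6, 0]], index=["a", "b"], columns=["a", "b"])
        m = _per_class_metrics(conf)
        assert m.loc["a", "TPR"] == 1 and m.loc["a", "TNR"] == 0
        assert m.loc["a", "wAcc"] == 0.5
        assert m.loc["b", "clErr"] == 1

    def test_confusion_rows_sum_to_class_counts(self, gaussian_species_table):
        df = gaussian_species_table
        train, valid = split_train_validation(df, 0.7, seed=4)
        cols = FEATURE_COLUMNS
        m = BalancedRandomForestClassifier(60, 10, None, 0).fit(
            train[cols], train["species"].to_numpy()
        )
        rep = evaluate(m, valid)
        counts = valid["species"].value_counts()
        for c in counts.index:
            assert rep.confusion.loc[c].sum() == counts[c]

    def test_unknown_validation_class_flagged(self, gaussian_species_table):
        df = gaussian_species_table
        train = df[df["species"] != "sp_c"]
        valid = df[df["species"] == "sp_c"]
        m = BalancedRandomForestClassifier(40, 10, None, 0).fit(
            train[FEATURE_COLUMNS], train["species"].to_numpy()
        )
        with pytest.warns(UserWarning, match="absent"):
            rep = evaluate(m, valid)
        assert rep.confusion.loc["sp_c"].sum() == len(valid)
        assert rep.confusion.loc["sp_c", "sp_c"] == 0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    n = 150
    X = rng.normal(0, 1, (2 * n, 6))
    y = np.array(["a"] * n + ["b"] * n)
    X[:n, 0] += 6.0  # feature 0 alone determines the class
    m = BalancedRandomForestClassifier(120, 2, None, 0).fit(X, y)
    return m, X, y


class TestImportance:
    def test_determining_feature_ranked_first(self, fitted):
        m, X, y = fitted
        table = importance(m, X, y, seed=1)
        assert table.mda["overall"].idxmax() == "feature_0"
        assert table.gini.idxmax() == "feature_0"

    def test_noise_feature_near_zero(self, fitted):
        m, X, y = fitted
        reps = [importance(m, X, y, seed=s).mda.loc["feature_3", "overall"] for s in range(5)]
        assert abs(np.mean(reps)) < 3 * (np.std(reps) + 1e-6)

    def test_overall_is_mean_of_per_class(self, fitted):
        m, X, y = fitted
        table = importance(m, X, y, seed=0)
        np.testing.assert_allclose(
            table.mda["overall"], table.mda[["a", "b"]].mean(axis=1), atol=1e-12
        )


class TestProtocols:
    def test_loso_allocation_sums_to_one(self, gaussian_species_table):
        allocation, max_prob, model = leave_one_species_out(
            gaussian_species_table, "sp_b", n_estimators=80, seed=0
        )
        assert allocation.sum() == pytest.approx(1.0)
        assert "sp_b" not in model.classes_
        assert (max_prob > 0).all()

    def test_loso_twin_class_absorbed_by_its_source(self):
        rng = np.random.default_rng(3)
        frames = []
        for name, shift in (("a", 0.0), ("b", 10.0), ("c", 0.0)):  # c duplicates a
            X = rng.normal(shift, 1, (80, 52))
            df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
            df["species"] = name
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        allocation, _, _ = leave_one_species_out(table, "c", n_estimators=150, seed=1)
        assert allocation["a"] > 0.8

    def test_misclassified_have_lower_confidence(self, separable_features):
        report, _, _ = subtask_classify(
            separable_features, "all-species", n_estimators=300, seed=2
        )
        valid_truth = separable_features.loc[report.class_probabilities.index, "species"]
        pred = report.class_probabilities.idxmax(axis=1)
        correct = pred == valid_truth
        assert 0 < correct.sum() < len(correct)
        diff = (report.max_class_probability[correct].median()
                - report.max_class_probability[~correct].median())
        assert diff > 0

    def test_subtask_relabelling(self, study_corpus):
        features, _ = study_corpus
        report, imp, model = subtask_classify(features, "aphid-vs-beetle",
                                              n_estimators=150, seed=0)
        assert set(model.classes_) == {"Hemiptera", "Coleoptera"}
        report2, _, model2 = subtask_classify(features, "within-beetles",
                                              n_estimators=150, seed=0)
        assert set(model2.classes_) == {"P_chrysocephala", "B_aeneus"}
        with pytest.raises(ValueError, match="unknown task"):
            subtask_classify(features, "within-flies")

    def test_scaled_sample_sizes_never_exceed_class_counts(self):
        y = ["D_platanoidis"] * 40 + ["A_fabae"] * 5 + ["other_sp"] * 9
        sizes = scaled_sample_sizes(y)
        assert sizes["D_platanoidis"] <= 40
        assert 1 <= sizes["A_fabae"] <= 5
        assert sizes["other_sp"] == round(0.6 * 9)
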