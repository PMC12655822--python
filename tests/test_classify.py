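import numpy as np
import pandas as pd
import pytest

from serscyto import (
    MARKERS,
    PopulationConfig,
    evaluate,
    f1_from_pre_rec,
    predict_population,
    repeat_training,
    simulate_cell_population,
    split_train_test,
    train_forest,
)
from serscyto.classify import report_from_predictions


@pytest.fixture(scope="module")
def small_population():
    return simulate_cell_population(PopulationConfig(n_per_line=100, seed=0))


class TestSplit:
    def test_stratified_70_30(self, small_population):
        train, test = split_train_test(small_population, 0.7, seed=0)
        assert len(train) == 210 and len(test) == 90
        for label, group in train.groupby("label"):
            assert len(group) == 70

    def test_partition_is_disjoint_and_exhaustive(self, small_population):
        train, test = split_train_test(small_population, 0.7, seed=1)
        ids = set(train.cell_id) | set(test.cell_id)
        assert len(ids) == len(small_population)
        assert not set(train.cell_id) & set(test.cell_id)

    def test_same_seed_same_partition(self, small_population):
        a = split_train_test(small_population, 0.7, seed=3)[0]
        b = split_train_test(small_population, 0.7, seed=3)[0]
        assert list(a.cell_id) == list(b.cell_id)

    def test_full_train_fraction_warns(self, small_population):
        with pytest.warns(UserWarning, match="empty test"):
            train, test = split_train_test(small_population, 1.0, seed=0)
        assert len(test) == 0 and len(train) == len(small_population)

    def test_empty_table_is_error(self, small_population):
        with pytest.raises(ValueError, match="empty"):
            split_train_test(small_population.iloc[0:0], seed=0)


class TestTrainForest:
    def test_separable_lines_fit_training_set_perfectly(self, small_population):
        model = train_forest(small_population, seed=0)
        pred = model.predict(small_population[list(MARKERS)].to_numpy())
        assert (pred == small_population.label.to_numpy()).mean() == 1.0

    def test_single_class_is_error(self, small_population):
        with pytest.raises(ValueError, match="2 classes"):
            train_forest(small_population[small_population.label == "MCF7"])

    def test_contradictory_duplicates_tolerated(self):
        frame = pd.DataFrame(
            [
                {"cell_id": "a", "label": "MCF7", **{m: 0.2 for m in MARKERS}},
                {"cell_id": "b", "label": "SKBR3", **{m: 0.2 for m in MARKERS}},
            ]
        )
        model = train_forest(frame, seed=0)
        report = evaluate(model, frame)
        assert report.accuracy < 1.0  # irreducible error

    def test_same_seed_same_predictions(self, small_population):
        probe = small_population[list(MARKERS)].to_numpy()[:20]
        a = train_forest(small_population, seed=9).predict(probe)
        b = train_forest(small_population, seed=9).predict(probe)
        assert np.array_equal(a, b)


class TestF1:
    def test_perfect(self):
        assert f1_from_pre_rec(1.0, 1.0) == 1.0

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.99])
    def test_harmonic_mean_of_equals(self, p):
        assert f1_from_pre_rec(p, p) == pytest.approx(p)

    def test_printed_formula_value(self):
        assert f1_from_pre_rec(0.8, 0.6) == pytest.approx(24 / 35)  # 0.6857142857

    def test_zero_sum(self):
        assert f1_from_pre_rec(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            f1_from_pre_rec(*bad)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.repeat(["MCF7", "MM231", "SKBR3"], 10)
        report = report_from_predictions(y, y, ("MCF7", "MM231", "SKBR3"))
        assert np.allclose(report.confusion_fractions, np.eye(3))
        assert report.macro_f1 == 1.0 and report.accuracy == 1.0

    def test_all_one_class_gives_chance_accuracy(self):
        y = np.repeat(["MCF7", "MM231", "SKBR3"], 10)
        pred = np.repeat("MCF7", 30)
        report = report_from_predictions(y, pred, ("MCF7", "MM231", "SKBR3"))
        assert report.accuracy == pytest.approx(1 / 3)

    def test_hand_arithmetic_through_formulas(self):
        # class A: TP=9, FP=1, FN=3 -> PRE=0.9, REC=0.75, F1=0.81818...
        y_true = ["A"] * 12 + ["B"] * 10
        y_pred = ["A"] * 9 + ["B"] * 3 + ["A"] * 1 + ["B"] * 9
        report = report_from_predictions(np.array(y_true), np.array(y_pred), ("A", "B"))
        assert report.precision["A"] == pytest.approx(0.9)
        assert report.recall["A"] == pytest.approx(0.75)
        assert report.f1["A"] == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_confusion_count_rows_equal_class_sizes(self, small_population):
        train, test = split_train_test(small_population, 0.7, seed=0)
        report = evaluate(train_forest(train, seed=0), test)
        counts = report.confusion_counts.sum(axis=1)
        sizes = test.groupby("label").size().reindex(report.classes).to_numpy()
        assert np.array_equal(counts, sizes)
        assert np.allclose(report.confusion_fractions.sum(axis=1), 1.0)

    def test_unknown_test_label_is_error(self, small_population):
        train, test = split_train_test(small_population, 0.7, seed=0)
        model = train_forest(train, seed=0)
        test = test.copy()
        test.loc[test.index[0], "label"] = "unknown"
        with pytest.raises(ValueError, match="never saw"):
            evaluate(model, test)

    def test_empty_test_set_is_error(self, small_population):
        model = train_forest(small_population, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, small_population.iloc[0:0])


class TestRepeatTraining:
    def test_single_iteration_equals_one_run(self, small_population):
        result = repeat_training(small_population, n_iterations=1, seed=7)
        seeds = np.random.default_rng(7).integers(0, 2**31 - 1, size=(1, 2))
        train, test = split_train_test(small_population, 0.7, seed=int(seeds[0, 0]))
        report = evaluate(train_forest(train, seed=int(seeds[0, 1])), test)
        assert result.mean_macro_f1 == pytest.approx(report.macro_f1)

    def test_label_permutation_gives_chance_level(self):
        frame = simulate_cell_population(PopulationConfig(n_per_line=300, seed=2))
        rng = np.random.default_rng(0)
        frame = frame.assign(label=rng.permutation(frame.label.to_numpy()))
        result = repeat_training(frame, n_iterations=10, seed=0)
        assert abs(result.mean_macro_f1 - 1 / 3) < 0.05
        assert abs(result.mean_accuracy - 1 / 3) < 0.05

    def test_deterministic_under_top_level_seed(self, small_population):
        a = repeat_training(small_population, n_iterations=3, seed=11)
        b = repeat_training(small_population, n_iterations=3, seed=11)
        assert a.mean_macro_f1 == b.mean_macro_f1
        assert a.mean_accuracy == b.mean_accuracy


class TestPredictPopulation:
    def test_counts_conserve_population_size(self, small_population):
        model = train_forest(small_population, seed=0)
        fresh = simulate_cell_population(PopulationConfig(n_per_line=30, seed=9))
        summary = predict_population(model, fresh)
        assert sum(summary.counts.values()) == summary.n_total == 90

    def test_single_line_population_mostly_recognised(self, small_population):
        model = train_forest(small_population, seed=0)
        fresh = simulate_cell_population(PopulationConfig(n_per_line=200, seed=3))
        mm231 = fresh[fresh.label == "MM231"]
        summary = predict_population(model, mm231)
        assert summary.counts["MM231"] / summary.n_total >= 0.95

    def test_feature_dimension_mismatch_is_error(self, small_population):
        model = train_forest(small_population, seed=0)
        import sklearn.ensemble

        bad_model = sklearn.ensemble.RandomForestClassifier(n_estimators=5, random_state=0)
        bad_model.fit(small_population[list(MARKERS)[:3]].to_numpy(), small_population.label)
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict_population(bad_model, small_population)
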