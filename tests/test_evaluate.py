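import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

from linablate import (
    BenchmarkPlan,
    BenchmarkRecord,
    HyperparameterGrid,
    TrainConfig,
    accuracy,
    balanced_accuracy,
    confusion_table,
    naive_baseline,
    read_results,
    run_benchmark,
    run_pretraining_comparison,
    simulate_study_structured,
    write_results,
    zero_one_scale,
)
from linablate import SimulationConfig, StudyEffectConfig
from conftest import make_study_matrix

FAST = TrainConfig(max_epochs=8)


class TestBalancedAccuracy:
    def test_imbalanced_worked_example(self):
        """9 of class A, 1 of class B; 8 A correct, the B wrong:
        accuracy 0.8 but balanced accuracy (8/9 + 0)/2 = 4/9."""
        truth = np.array(["A"] * 9 + ["B"])
        pred = np.array(["A"] * 8 + ["B", "A"])
        assert accuracy(truth, pred) == pytest.approx(0.8)
        assert balanced_accuracy(truth, pred) == pytest.approx(4 / 9)

    def test_perfect_predictions(self):
        truth = np.array([0, 1, 2, 1])
        assert balanced_accuracy(truth, truth) == 1.0

    def test_constant_predictor_is_half_for_binary(self):
        truth = np.array([0] * 7 + [1] * 3)
        assert balanced_accuracy(truth, np.zeros(10, dtype=int)) == 0.5

    def test_matches_sklearn_on_random_multiclass(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            truth = rng.integers(0, 4, size=50)
            pred = rng.integers(0, 4, size=50)
            assert balanced_accuracy(truth, pred) == pytest.approx(
                balanced_accuracy_score(truth, pred)
            )

    def test_invariant_to_duplicating_a_class(self):
        truth = np.array([0, 0, 1, 1, 1])
        pred = np.array([0, 1, 1, 0, 1])
        dup_truth = np.concatenate([truth, truth[truth == 1]])
        dup_pred = np.concatenate([pred, pred[truth == 1]])
        assert balanced_accuracy(dup_truth, dup_pred) == pytest.approx(
            balanced_accuracy(truth, pred)
        )

    def test_equals_accuracy_when_classes_balanced(self):
        rng = np.random.default_rng(1)
        truth = np.tile([0, 1], 20)
        pred = rng.integers(0, 2, size=40)
        assert balanced_accuracy(truth, pred) == pytest.approx(accuracy(truth, pred))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            balanced_accuracy(np.array([]), np.array([]))


class TestNaiveBaseline:
    def test_binary_any_imbalance_is_half(self):
        assert naive_baseline(np.array(["A"] * 99 + ["B"])) == 0.5

    def test_three_classes_one_third(self):
        assert naive_baseline(np.array([0, 0, 1, 2])) == pytest.approx(1 / 3)

    def test_single_class_degenerates_to_one(self):
        assert naive_baseline(np.array(["A", "A"])) == 1.0


def test_confusion_table_totals():
    table = confusion_table(["A", "A", "B"], ["A", "B", "B"])
    assert table.total() == 3
    assert table.counts.shape == (2, 2)
    np.testing.assert_array_equal(table.counts, [[1, 1], [0, 1]])


class TestRunBenchmark:
    def test_factorial_record_count(self):
        m = make_study_matrix(n_samples=40, n_genes=6, n_studies=4, seed=1)
        plan = BenchmarkPlan(k=2, split_mode="study", seeds=(0,), fractions=(1.0,))
        records, failures = run_benchmark(m, ["logreg", "linear_svm"], plan, train_config=FAST)
        assert failures == []
        assert len(records) == 4  # 1 seed x 1 fraction x 2 folds x 2 models

    def test_records_carry_modes_and_classes(self):
        m = make_study_matrix(n_samples=40, n_genes=6, n_studies=4, seed=2)
        plan = BenchmarkPlan(k=2, split_mode="study", seeds=(0,))
        records, _ = run_benchmark(m, ["logreg"], plan, ablation_mode="per_split",
                                   train_config=FAST)
        for r in records:
            assert r.ablation_mode == "per_split"
            assert r.split_mode == "study"
            assert r.evaluated_classes == "A|B"
            assert 0.0 <= r.balanced_accuracy <= 1.0

    def test_resume_skips_completed_cells(self):
        m = make_study_matrix(n_samples=40, n_genes=6, n_studies=4, seed=3)
        plan = BenchmarkPlan(k=2, split_mode="study", seeds=(0,))
        first, _ = run_benchmark(m, ["logreg"], plan, train_config=FAST)
        resumed, _ = run_benchmark(m, ["logreg", "linear_svm"], plan, train_config=FAST,
                                   resume_records=first)
        assert len(resumed) == 4
        assert sum(r.model_kind == "logreg" for r in resumed) == 2

    def test_unknown_ablation_mode_rejected(self):
        m = make_study_matrix()
        with pytest.raises(ValueError, match="ablation"):
            run_benchmark(m, ["logreg"], BenchmarkPlan(k=2, seeds=(0,)), ablation_mode="bogus")

    def test_subsampling_learning_curve_non_decreasing(self):
        """With nested subsampling, more training data must not hurt the
        mean balanced accuracy by more than the noise tolerance."""
        sim = SimulationConfig(200, n_linear_features=10, n_nonlinear_features=10, seed=21)
        study = StudyEffectConfig(n_studies=8, study_shift_sd=0.0,
                                  label_study_association=0.0, seed=21)
        data = zero_one_scale(simulate_study_structured(sim, study))
        plan = BenchmarkPlan(k=2, split_mode="study", seeds=(0, 1), fractions=(0.15, 1.0))
        records, failures = run_benchmark(data, ["logreg"], plan)
        assert failures == []
        by_fraction = {
            f: np.mean([r.balanced_accuracy for r in records if r.subset_fraction == f])
            for f in (0.15, 1.0)
        }
        assert by_fraction[1.0] >= by_fraction[0.15] - 0.05


def test_pretraining_comparison_counts_and_regimes():
    sim = SimulationConfig(120, n_linear_features=8, seed=31)
    study = StudyEffectConfig(n_studies=6, study_shift_sd=0.5,
                              label_study_association=0.0, seed=31)
    data = zero_one_scale(simulate_study_structured(sim, study))
    records = run_pretraining_comparison(data, ["logreg"], seeds=(0, 1), train_config=FAST)
    assert len(records) == 4  # 2 seeds x 1 model x 2 regimes
    assert {r.regime for r in records} == {"standard", "pretrained"}


class TestResultsIO:
    def _records(self):
        return [
            BenchmarkRecord("logreg", 0, 1, 0.5, "per_split", "study",
                            0.875, 0.9, 80, 20, "A|B"),
            BenchmarkRecord("mlp3", 2, 0, 1.0, "none", "sample",
                            1 / 3, 0.25, 64, 16, "A|B|C", regime="pretrained"),
        ]

    def test_round_trip_preserves_records(self, tmp_path):
        path = tmp_path / "results.tsv"
        write_results(self._records(), path)
        assert read_results(path) == self._records()

    def test_empty_records_round_trip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_results([], path)
        assert read_results(path) == []

    def test_unknown_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_results(self._records(), path)
        lines = path.read_text().splitlines()
        lines[1] = lines[1] + "\tmystery"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="mystery"):
            read_results(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_results(self._records(), path)
        lines = path.read_text().splitlines()
        lines[3] = lines[3].replace("1/3", "x").replace("0.333", "x")
        fields = lines[3].split("\t")
        fields[7] = "not-a-number"
        lines[3] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 4"):
            read_results(path)

    def test_missing_schema_line_rejected(self, tmp_path):
        path = tmp_path / "noschema.tsv"
        path.write_text("model_kind\tseed\n")
        with pytest.raises(ValueError, match="schema"):
            read_results(path)
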