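import shutil
import subprocess

import numpy as np
import pytest

from linablate import (
    LabeledExpressionMatrix,
    fit_removal_model,
    remove_linear_signal,
    remove_signal_full_dataset,
    remove_signal_per_split,
)


def _matrix(values, labels, **kwargs):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, p = values.shape
    return LabeledExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(p)],
        class_labels=labels,
        **kwargs,
    )


def _oracle_removal(values, labels):
    """Independent per-gene OLS on an explicit sum-to-zero design matrix,
    solved through the normal equations; subtract fitted class component."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    L = len(levels)
    idx = np.array([list(levels).index(l) for l in labels])
    X = np.zeros((len(labels), L))  # intercept + L-1 contrasts
    X[:, 0] = 1.0
    for c in range(L - 1):
        X[idx == c, c + 1] = 1.0
        X[idx == L - 1, c + 1] = -1.0
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted_effect = (X @ beta) - beta[0]  # class component, intercept kept
    return values - fitted_effect


class TestClosedFormExamples:
    def test_balanced_two_group(self):
        model = fit_removal_model(_matrix([1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"]))
        assert model.intercept[0] == pytest.approx(2.0)
        assert model.effects[:, 0] == pytest.approx([-1.0, 1.0])

    def test_unbalanced_intercept_is_mean_of_class_means(self):
        # intercept 2 = (1 + 3)/2, not the grand mean 1.5
        model = fit_removal_model(_matrix([1.0, 1.0, 1.0, 3.0], ["A", "A", "A", "B"]))
        assert model.intercept[0] == pytest.approx(2.0)
        assert model.effects[:, 0] == pytest.approx([-1.0, 1.0])

    def test_equal_class_means_give_zero_effects(self):
        m = _matrix([2.0, 4.0, 4.0, 2.0], ["A", "A", "B", "B"])
        model = fit_removal_model(m)
        np.testing.assert_allclose(model.effects, 0.0, atol=1e-12)
        np.testing.assert_allclose(remove_linear_signal(m).values, m.values)

    def test_removal_equalizes_the_worked_example(self):
        out = remove_linear_signal(_matrix([1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"]))
        np.testing.assert_allclose(out.values.ravel(), [2.0, 2.0, 2.0, 2.0])


def _random_instance(rng):
    n = int(rng.integers(8, 21))
    p = int(rng.integers(2, 6))
    L = int(rng.integers(2, 5))
    labels = rng.choice([f"c{i}" for i in range(L)], size=n)
    while len(np.unique(labels)) < 2:
        labels = rng.choice([f"c{i}" for i in range(L)], size=n)
    return _matrix(rng.normal(scale=3.0, size=(n, p)), labels)


def test_matches_normal_equations_oracle_on_200_instances():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(200):
        m = _random_instance(rng)
        ours = remove_linear_signal(m).values
        reference = _oracle_removal(m.values, m.class_labels)
        worst = max(worst, float(np.abs(ours - reference).max()))
    assert worst < 1e-10


def test_equal_class_means_postcondition():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = _random_instance(rng)
        out = remove_linear_signal(m)
        means = np.stack(
            [out.values[out.class_labels == lvl].mean(axis=0) for lvl in np.unique(out.class_labels)]
        )
        assert np.abs(means - means[0]).max() < 1e-8


def test_removal_is_idempotent():
    rng = np.random.default_rng(8)
    m = _random_instance(rng)
    once = remove_linear_signal(m)
    twice = remove_linear_signal(once)
    assert np.abs(twice.values - once.values).max() < 1e-8


def test_within_class_deviations_unchanged():
    rng = np.random.default_rng(9)
    m = _random_instance(rng)
    out = remove_linear_signal(m)
    for lvl in np.unique(m.class_labels):
        rows = m.class_labels == lvl
        before = m.values[rows] - m.values[rows].mean(axis=0)
        after = out.values[rows] - out.values[rows].mean(axis=0)
        np.testing.assert_allclose(after, before, atol=1e-12)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="two class"):
        fit_removal_model(_matrix([1.0, 2.0], ["A", "A"]))


class TestPerSplit:
    def test_each_side_satisfies_equal_means_independently(self):
        rng = np.random.default_rng(10)
        tr = _matrix(rng.normal(size=(12, 3)), ["A", "B"] * 6)
        va = _matrix(rng.normal(size=(8, 3)), ["A", "B"] * 4)
        out_tr, out_va = remove_signal_per_split(tr, va)
        for out in (out_tr, out_va):
            means = np.stack(
                [out.values[out.class_labels == l].mean(axis=0) for l in ("A", "B")]
            )
            assert np.abs(means[0] - means[1]).max() < 1e-8

    def test_validation_output_independent_of_train(self):
        rng = np.random.default_rng(11)
        va = _matrix(rng.normal(size=(8, 3)), ["A", "B"] * 4)
        tr1 = _matrix(rng.normal(size=(12, 3)), ["A", "B"] * 6)
        tr2 = _matrix(rng.normal(size=(12, 3)) + 100.0, ["A", "B"] * 6)
        _, va1 = remove_signal_per_split(tr1, va)
        _, va2 = remove_signal_per_split(tr2, va)
        np.testing.assert_array_equal(va1.values, va2.values)

    def test_absent_class_names_set_and_class(self):
        tr = _matrix([1.0, 2.0, 3.0, 4.0], ["A", "B", "A", "B"])
        va = _matrix([1.0, 2.0], ["A", "A"])
        with pytest.raises(ValueError, match="'B' is absent from the validation"):
            remove_signal_per_split(tr, va)


def test_full_dataset_mode_flagged_leaky():
    m = _matrix([1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"])
    out = remove_signal_full_dataset(m)
    assert out.notes["ablation_mode"] == "full_dataset"
    assert out.notes["leaky"] is True


def test_pooled_removal_makes_split_deviations_anti_proportional():
    """After a pooled fit, a train/validation split's class-mean deviations
    cancel exactly: val_diff = -(n_train/n_val) * train_diff per gene. This
    is the mechanism behind the induced-signal failure mode."""
    rng = np.random.default_rng(12)
    m = _matrix(rng.normal(size=(40, 5)), ["A", "B"] * 20)
    out = remove_signal_full_dataset(m)
    tr, va = np.arange(32), np.arange(32, 40)
    y = out.class_labels

    def diff(rows):
        sub, lab = out.values[rows], y[rows]
        return sub[lab == "A"].mean(axis=0) - sub[lab == "B"].mean(axis=0)

    np.testing.assert_allclose(diff(va), -(32 / 8) * diff(tr), rtol=1e-8)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agrees_with_limma_removeBatchEffect(tmp_path):
    """Cross-check the removal against limma's removeBatchEffect on a small
    random two-class matrix (limma expects genes x samples)."""
    rng = np.random.default_rng(13)
    values = rng.normal(size=(8, 4))
    labels = ["A", "A", "A", "B", "B", "B", "A", "B"]
    m = _matrix(values, labels)
    np.savetxt(tmp_path / "mat.tsv", values.T, delimiter="\t")  # genes x samples
    (tmp_path / "labels.txt").write_text("\n".join(labels) + "\n")
    script = tmp_path / "run.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        x <- as.matrix(read.table(file.path("%s", "mat.tsv"), sep="\\t"))
        batch <- readLines(file.path("%s", "labels.txt"))
        out <- removeBatchEffect(x, batch = batch)
        write.table(out, file.path("%s", "out.tsv"), sep="\\t",
                    row.names = FALSE, col.names = FALSE)
        """
        % (tmp_path, tmp_path, tmp_path)
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    reference = np.loadtxt(tmp_path / "out.tsv", delimiter="\t").T
    ours = remove_linear_signal(m).values
    # removeBatchEffect keeps a different intercept convention; compare after
    # centering each gene, which removes the per-gene constant
    np.testing.assert_allclose(
        ours - ours.mean(axis=0), reference - reference.mean(axis=0), atol=1e-6
    )
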