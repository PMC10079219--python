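import numpy as np
import pytest

from linablate import LabeledExpressionMatrix, SimulationConfig, simulate_two_signal


@pytest.fixture
def tiny_matrix() -> LabeledExpressionMatrix:
    """4 samples x 3 genes with two balanced classes and two studies."""
    return LabeledExpressionMatrix(
        values=np.array([[1.0, 5.0, 2.0], [1.0, 3.0, 2.0], [3.0, 1.0, 2.0], [3.0, 3.0, 2.0]]),
        sample_ids=["s1", "s2", "s3", "s4"],
        gene_ids=["gA", "gB", "gC"],
        class_labels=["A", "A", "B", "B"],
        study_ids=["st1", "st1", "st2", "st2"],
        donor_ids=["d1", "d2", "d3", "d4"],
    )


@pytest.fixture(scope="session")
def small_two_signal() -> LabeledExpressionMatrix:
    """300 samples, 20 linear + 20 non-linear features."""
    return simulate_two_signal(
        SimulationConfig(n_samples=300, n_linear_features=20, n_nonlinear_features=20, seed=7)
    )


def make_study_matrix(n_samples=60, n_genes=8, n_studies=4, seed=0):
    """Noise matrix with balanced classes and round-robin study labels."""
    rng = np.random.default_rng(seed)
    return LabeledExpressionMatrix(
        values=rng.normal(size=(n_samples, n_genes)),
        sample_ids=[f"s{i}" for i in range(n_samples)],
        gene_ids=[f"g{j}" for j in range(n_genes)],
        class_labels=np.tile(["A", "B"], (n_samples + 1) // 2)[:n_samples],
        study_ids=[f"study{i % n_studies}" for i in range(n_samples)],
        donor_ids=[f"d{i // 2}" for i in range(n_samples)],
    )
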