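"""Canned simulation experiments at desk scale.

Each function composes the package's generators, preprocessing, ablation,
splitting and model suite into one named experiment and returns summary
balanced accuracies. The default problem sizes are the package's study
conditions: large enough for stable chance bands, small enough that the
whole battery runs on one CPU core in minutes; the canonical full-size
simulation is 1,000 samples x 5,000 features, and these experiments keep
its structure (and, where it matters, its feature-to-sample ratio) at
reduced width. All randomness derives from the single ``root_seed``.

Every dataset is zero-one scaled before modeling, mirroring the standard
expression preprocessing the model suite expects; the linear kinds select
(learning rate, weight decay) by nested cross-validation over the default
grid, while the networks use the protocol defaults (see docs/methods.md
for why).
"""

from __future__ import annotations

import numpy as np

from .ablation import remove_linear_signal, remove_signal_full_dataset
from .evaluate import (
    BenchmarkPlan,
    balanced_accuracy,
    run_ablation_comparison,
    run_benchmark,
)
from .models import MODEL_KINDS, HyperparameterGrid, TrainConfig
from .preprocess import zero_one_scale
from .rng import substream_seed
from .simulate import (
    SimulationConfig,
    StudyEffectConfig,
    simulate_linear_only,
    simulate_noise,
    simulate_study_structured,
    simulate_two_signal,
)
from .splits import subsample_training

__all__ = [
    "two_signal_ablation",
    "linear_only_control",
    "noise_control",
    "induced_signal_failure",
    "leakage_comparison",
    "benchmark_grid_sweep",
]

LINEAR_KINDS = ("logreg", "linear_svm")
_GRID = HyperparameterGrid()


def _holdout_seeds(root_seed: int, n: int) -> tuple:
    """Per-repeat seeds derived from the root so nothing is pinned across runs."""
    return tuple(substream_seed(root_seed, f"repeat/{i}") for i in range(n))


def _mean_by_mode_kind(records) -> dict:
    acc: dict = {}
    for r in records:
        acc.setdefault((r.ablation_mode, r.model_kind), []).append(r.balanced_accuracy)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def _mean_by(records, key) -> dict:
    acc: dict = {}
    for r in records:
        acc.setdefault(key(r), []).append(r.balanced_accuracy)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def two_signal_ablation(
    root_seed: int = 0,
    n_samples: int = 500,
    n_linear: int = 250,
    n_nonlinear: int = 250,
    n_holdouts: int = 3,
) -> dict:
    """Before/after per-split ablation on the two-signal simulation.

    Returns mean validation balanced accuracy per (ablation mode, model)
    over ``n_holdouts`` stratified 80/20 splits. Expected outcome: every
    model above 0.9 before ablation; afterwards the linear models at
    chance while both networks stay above 0.9 (the non-linear block's
    symmetric +/-shift mixture survives per-gene mean equalization).
    """
    config = SimulationConfig(
        n_samples, n_linear_features=n_linear, n_nonlinear_features=n_nonlinear,
        seed=substream_seed(root_seed, "two_signal/data"),
    )
    data = zero_one_scale(simulate_two_signal(config))
    records = run_ablation_comparison(
        data, list(MODEL_KINDS), seeds=_holdout_seeds(root_seed, n_holdouts),
        ablation_modes=("none", "per_split"),
        grid=_GRID, grid_kinds=LINEAR_KINDS, train_config=TrainConfig(),
    )
    return _mean_by_mode_kind(records)


def linear_only_control(
    root_seed: int = 0, n_samples: int = 800, n_linear: int = 250, n_holdouts: int = 2
) -> dict:
    """Per-split ablation on purely linear signal: all models fall to chance."""
    config = SimulationConfig(
        n_samples, n_linear_features=n_linear,
        seed=substream_seed(root_seed, "linear_only/data"),
    )
    data = zero_one_scale(simulate_linear_only(config))
    records = run_ablation_comparison(
        data, list(MODEL_KINDS), seeds=_holdout_seeds(root_seed, n_holdouts),
        ablation_modes=("per_split",),
        grid=_GRID, grid_kinds=LINEAR_KINDS, train_config=TrainConfig(),
    )
    return _mean_by_mode_kind(records)


def noise_control(
    root_seed: int = 0, n_samples: int = 800, n_noise: int = 250, n_holdouts: int = 2
) -> dict:
    """Negative control: pure noise scores at chance before and after ablation."""
    config = SimulationConfig(
        n_samples, n_noise_features=n_noise,
        seed=substream_seed(root_seed, "noise/data"),
    )
    data = zero_one_scale(simulate_noise(config))
    records = run_ablation_comparison(
        data, list(MODEL_KINDS), seeds=_holdout_seeds(root_seed, n_holdouts),
        ablation_modes=("none", "per_split"),
        grid=_GRID, grid_kinds=LINEAR_KINDS, train_config=TrainConfig(),
    )
    return _mean_by_mode_kind(records)


def _centroid_readout(train_values, train_labels, val_values, val_labels) -> float:
    """Nearest-centroid classifier: the simplest consumer of linear signal.

    Its decision direction is exactly the train-side per-gene class-mean
    difference, making it a deterministic probe for mean-shift signal that
    a fitted model would follow.
    """
    levels = np.unique(train_labels)
    m0 = train_values[train_labels == levels[0]].mean(axis=0)
    m1 = train_values[train_labels == levels[1]].mean(axis=0)
    w = m1 - m0
    threshold = (m0 + m1) @ w / 2
    pred = np.where(val_values @ w > threshold, levels[1], levels[0])
    return balanced_accuracy(val_labels, pred)


def induced_signal_failure(
    root_seed: int = 0, n_samples: int = 300, n_noise: int = 1500, n_holdouts: int = 2
) -> dict:
    """The leaky-removal failure mode on label-free noise.

    Fitting the removal on the pooled dataset equalizes pooled class
    means, which forces any later split's class-mean deviations to cancel
    (validation = -(n_train/n_val) x train per gene): the procedure
    manufactures strong spurious signal, anti-aligned across the split.
    The feature-to-sample ratio (5:1) matches the canonical simulation,
    where the induced separation is ~sqrt(p/n) within-class standard
    deviations on the training side.

    Returns mean balanced accuracies of the model suite under per-split
    and full-dataset removal, plus a nearest-centroid readout per mode —
    the deterministic witness of the induced signal (far below chance
    under pooled removal, at chance under per-split removal).
    """
    config = SimulationConfig(
        n_samples, n_noise_features=n_noise,
        seed=substream_seed(root_seed, "induced/data"),
    )
    data = zero_one_scale(simulate_noise(config))
    records = run_ablation_comparison(
        data, list(MODEL_KINDS), seeds=_holdout_seeds(root_seed, n_holdouts),
        ablation_modes=("per_split", "full_dataset"),
        grid=_GRID, grid_kinds=LINEAR_KINDS, train_config=TrainConfig(),
    )
    out = _mean_by_mode_kind(records)

    y = data.class_labels
    all_idx = np.arange(data.n_samples)
    pooled = remove_signal_full_dataset(data)
    centroid = {"per_split": [], "full_dataset": []}
    for holdout in _holdout_seeds(root_seed, n_holdouts):
        val_idx = subsample_training(
            all_idx, 0.2, y, substream_seed(holdout, "holdout")
        )
        tr_idx = np.setdiff1d(all_idx, val_idx)
        centroid["full_dataset"].append(
            _centroid_readout(
                pooled.values[tr_idx], y[tr_idx], pooled.values[val_idx], y[val_idx]
            )
        )
        tr_m = remove_linear_signal(data.subset_samples(tr_idx))
        va_m = remove_linear_signal(data.subset_samples(val_idx))
        centroid["per_split"].append(
            _centroid_readout(
                tr_m.values, tr_m.class_labels, va_m.values, va_m.class_labels
            )
        )
    for mode, values in centroid.items():
        out[(mode, "centroid")] = float(np.mean(values))
    return out


def leakage_comparison(
    root_seed: int = 0,
    n_samples: int = 300,
    n_studies: int = 6,
    k: int = 3,
    n_seeds: int = 2,
) -> dict:
    """Study-wise versus sample-wise cross-validation on confounded data.

    The base simulation carries weak linear (shift 1) and moderate
    non-linear (shift 3) signal; studies are strongly label-associated
    (0.8) with large per-study offsets (sd 2), so scattering a study's
    samples across folds leaks study identity into validation. Expected:
    every model scores higher under sample-wise than study-wise splitting,
    with the model ordering preserved.
    """
    config = SimulationConfig(
        n_samples, n_linear_features=60, n_nonlinear_features=60,
        linear_shift=1.0, nonlinear_shift=3.0,
        seed=substream_seed(root_seed, "leakage/data"),
    )
    study = StudyEffectConfig(
        n_studies=n_studies, study_shift_sd=2.0, label_study_association=0.8,
        seed=substream_seed(root_seed, "leakage/studies"),
    )
    data = zero_one_scale(simulate_study_structured(config, study))
    out = {}
    for mode in ("study", "sample"):
        plan = BenchmarkPlan(k=k, split_mode=mode, seeds=_holdout_seeds(root_seed, n_seeds))
        records, failures = run_benchmark(
            data, list(MODEL_KINDS), plan,
            grid=_GRID, grid_kinds=LINEAR_KINDS, train_config=TrainConfig(),
        )
        if failures:
            raise RuntimeError(f"benchmark cells failed: {failures}")
        out.update({(mode, k2): v for (k2, v) in _mean_by(records, lambda r: r.model_kind).items()})
    return out


def benchmark_grid_sweep(
    root_seed: int = 0,
    n_seeds: int = 3,
    n_fractions: int = 10,
    k: int = 5,
) -> dict:
    """The full factorial sweep at toy scale: seeds x fractions x folds.

    Uses a small study-structured two-signal dataset and the two linear
    model kinds; returns the per-model record count (seeds x fractions x
    folds) and the records themselves.
    """
    config = SimulationConfig(
        150, n_linear_features=10, n_nonlinear_features=10,
        seed=substream_seed(root_seed, "grid/data"),
    )
    study = StudyEffectConfig(
        n_studies=15, study_shift_sd=0.3, label_study_association=0.0,
        seed=substream_seed(root_seed, "grid/studies"),
    )
    data = zero_one_scale(simulate_study_structured(config, study))
    plan = BenchmarkPlan(
        k=k, split_mode="study", seeds=_holdout_seeds(root_seed, n_seeds),
        fractions=tuple(np.round(np.linspace(1.0 / n_fractions, 1.0, n_fractions), 10)),
    )
    records, failures = run_benchmark(
        data, list(LINEAR_KINDS), plan,
        train_config=TrainConfig(max_epochs=20),
    )
    counts = {}
    for r in records:
        counts[r.model_kind] = counts.get(r.model_kind, 0) + 1
    return {"records_per_model": counts, "n_failures": len(failures), "records": records}
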