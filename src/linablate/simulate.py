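"""Synthetic expression matrices with controlled linear and non-linear signal.

The generators emulate a two-class "expression-like" study in which every
feature (gene) belongs to one of three blocks:

``linear``
    Class 0 values are standard normal; class 1 values are
    ``N(linear_shift, 1)``. A single per-feature threshold separates the
    classes, so the class signal is linear.
``nonlinear``
    Class 0 values are standard normal; class 1 values are an
    equal-probability mixture of ``N(+nonlinear_shift, 1)`` and
    ``N(-nonlinear_shift, 1)``, drawn independently per matrix entry. The
    class-conditional means are equal, so no single threshold separates
    the classes, but ``|x| > shift/2`` does: the signal is purely
    non-linear, and per-gene removal of class-mean differences cannot
    ablate it.
``noise``
    Standard normal regardless of class: a negative control.

A fourth generator layers study-structured batch effects, confounded with
the class labels to a controllable degree, on top of any base simulation;
it exists to exercise study-wise versus sample-wise cross-validation.

All generation is a pure function of the config (seed included): the same
config yields a byte-identical matrix in any process. Each block draws
from its own named substream of the root seed, so e.g. adding noise
features never changes the linear block's values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .data import LabeledExpressionMatrix
from .rng import substream

__all__ = [
    "SimulationConfig",
    "StudyEffectConfig",
    "simulate",
    "simulate_two_signal",
    "simulate_linear_only",
    "simulate_noise",
    "simulate_study_structured",
    "default_two_signal_config",
    "default_linear_only_config",
    "default_noise_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes, effect sizes and seed of one synthetic dataset.

    ``linear_shift`` / ``nonlinear_shift`` are in expression units
    (standard deviations of the within-class noise, which is 1).
    ``class_fraction`` is the fraction of samples assigned to class "1",
    the class that carries the shifted distributions.
    """

    n_samples: int
    n_linear_features: int = 0
    n_nonlinear_features: int = 0
    n_noise_features: int = 0
    linear_shift: float = 6.0
    nonlinear_shift: float = 6.0
    class_fraction: float = 0.5
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.n_linear_features + self.n_nonlinear_features + self.n_noise_features

    def n_class1(self) -> int:
        # round half up so 0.5 on odd n favours the shifted class
        return int(np.floor(self.n_samples * self.class_fraction + 0.5))

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if min(self.n_linear_features, self.n_nonlinear_features, self.n_noise_features) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_features <= 0:
            raise ValueError("total feature count must be positive")
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must lie in (0, 1)")
        n1 = self.n_class1()
        if n1 < 1 or n1 > self.n_samples - 1:
            raise ValueError("class_fraction leaves a class empty at this n_samples")


@dataclass(frozen=True)
class StudyEffectConfig:
    """Study-structured batch effects confounded with class labels.

    ``study_shift_sd`` is the standard deviation of the per-(study, gene)
    additive offset shared by all samples of a study.
    ``label_study_association`` interpolates the class composition of each
    study between fully balanced (0) and one class per study (1).
    """

    n_studies: int
    study_shift_sd: float = 1.0
    label_study_association: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2")
        if self.study_shift_sd < 0:
            raise ValueError("study_shift_sd must be non-negative")
        if not 0.0 <= self.label_study_association <= 1.0:
            raise ValueError("label_study_association must lie in [0, 1]")


def default_two_signal_config(seed: int = 0) -> SimulationConfig:
    """The canonical two-signal dataset: 1,000 samples x 5,000 features,
    2,500 linear + 2,500 non-linear, shifts of 6."""
    return SimulationConfig(
        n_samples=1000, n_linear_features=2500, n_nonlinear_features=2500, seed=seed
    )


def default_linear_only_config(seed: int = 0) -> SimulationConfig:
    """The linear-only control: 1,000 samples x 2,500 linear features."""
    return SimulationConfig(n_samples=1000, n_linear_features=2500, seed=seed)


def default_noise_config(seed: int = 0) -> SimulationConfig:
    """The pure-noise negative control: 1,000 samples x 2,500 features."""
    return SimulationConfig(n_samples=1000, n_noise_features=2500, seed=seed)


def _labels(config: SimulationConfig) -> np.ndarray:
    """0/1 integer labels, shuffled by the ``labels`` substream."""
    y = np.zeros(config.n_samples, dtype=int)
    y[: config.n_class1()] = 1
    substream(config.seed, "labels").shuffle(y)
    return y


def simulate(config: SimulationConfig) -> LabeledExpressionMatrix:
    """Generate a matrix with the configured mix of feature blocks.

    Gene order is linear block, then non-linear, then noise, with
    ``feature_kind`` tags recording the block of every gene.
    """
    config.validate()
    y = _labels(config)
    n = config.n_samples
    blocks, kinds = [], []

    if config.n_linear_features:
        x = substream(config.seed, "linear").normal(size=(n, config.n_linear_features))
        x[y == 1] += config.linear_shift
        blocks.append(x)
        kinds += ["linear"] * config.n_linear_features
    if config.n_nonlinear_features:
        p = config.n_nonlinear_features
        x = substream(config.seed, "nonlinear").normal(size=(n, p))
        # mixture component chosen per entry: each feature stays marginally
        # bimodal, which is what defeats a single per-feature threshold
        signs = substream(config.seed, "mixture").choice([-1.0, 1.0], size=(int((y == 1).sum()), p))
        x[y == 1] += signs * config.nonlinear_shift
        blocks.append(x)
        kinds += ["nonlinear"] * p
    if config.n_noise_features:
        blocks.append(substream(config.seed, "noise").normal(size=(n, config.n_noise_features)))
        kinds += ["noise"] * config.n_noise_features

    values = np.concatenate(blocks, axis=1)
    width = max(4, len(str(config.n_features - 1)))
    swidth = max(4, len(str(n - 1)))
    return LabeledExpressionMatrix(
        values=values,
        sample_ids=[f"sample_{i:0{swidth}d}" for i in range(n)],
        gene_ids=[f"gene_{j:0{width}d}" for j in range(config.n_features)],
        class_labels=y,
        feature_kind=kinds,
    )


def simulate_two_signal(config: SimulationConfig) -> LabeledExpressionMatrix:
    """The headline dataset: linear and non-linear signal blocks side by side."""
    if config.n_linear_features <= 0 or config.n_nonlinear_features <= 0:
        raise ValueError("two-signal simulation needs both linear and non-linear features")
    if config.n_noise_features != 0:
        raise ValueError("two-signal simulation carries no noise block")
    return simulate(config)


def simulate_linear_only(config: SimulationConfig) -> LabeledExpressionMatrix:
    """Control dataset whose class signal is entirely linear."""
    if config.n_linear_features <= 0:
        raise ValueError("linear-only simulation needs linear features")
    if config.n_nonlinear_features != 0 or config.n_noise_features != 0:
        raise ValueError("linear-only simulation has only the linear block")
    return simulate(config)


def simulate_noise(config: SimulationConfig) -> LabeledExpressionMatrix:
    """Negative control: labels are independent of all values."""
    if config.n_linear_features != 0 or config.n_nonlinear_features != 0:
        raise ValueError("noise simulation has only the noise block")
    if config.n_noise_features <= 0:
        raise ValueError("noise simulation needs noise features")
    return simulate(config)


def simulate_study_structured(
    config: SimulationConfig, study_config: StudyEffectConfig
) -> LabeledExpressionMatrix:
    """Layer confounded study-level batch effects on a base simulation.

    Each sample is assigned to one of ``n_studies`` studies. Studies are
    alternately designated class-0 and class-1 studies; a sample joins a
    study of its own class with probability ``label_study_association``
    and a uniformly random study otherwise, so association 0 gives
    class-balanced studies and association 1 gives one-class studies. All
    samples of a study then share one additive per-gene offset drawn with
    standard deviation ``study_shift_sd``; at sd 0 the values equal the
    base simulator's output exactly.
    """
    study_config.validate()
    base = simulate(config)
    y = base.class_labels.astype(int)
    n_studies = study_config.n_studies
    study_class = np.arange(n_studies) % 2  # designated majority class

    rng = substream(study_config.seed, "study_assign")
    assignment = np.empty(base.n_samples, dtype=int)
    all_studies = np.arange(n_studies)
    for i, yi in enumerate(y):
        own = all_studies[study_class == yi]
        if rng.random() < study_config.label_study_association:
            assignment[i] = rng.choice(own)
        else:
            assignment[i] = rng.choice(all_studies)

    offsets = substream(study_config.seed, "study_offsets").normal(
        size=(n_studies, base.n_genes)
    )
    values = base.values + study_config.study_shift_sd * offsets[assignment]
    width = max(2, len(str(n_studies - 1)))
    return dataclasses.replace(
        base,
        values=values,
        study_ids=[f"study_{s:0{width}d}" for s in assignment],
    )
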