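"""Removal of label-linear signal from expression matrices.

The ablation at the heart of the benchmark: for every gene, fit an
ordinary-least-squares model of expression on the class labels and
subtract the fitted class component. With a single categorical factor and
sum-to-zero contrasts the OLS solution has a closed form — the fitted
value for a sample of class ``c`` is that class's mean for the gene — so
removal subtracts ``class_mean - unweighted_mean_of_class_means`` from
every entry. This is the linear-model batch correction familiar from
differential-expression workflows (a design of intercept + class
contrasts, no covariates), with the *class* labels playing the role of
the batch.

After removal every gene's class means are equal, so no affine classifier
retains signal, while within-class deviations — including symmetric
mixture structure that ``|x|``-style rules can exploit — pass through
untouched.

Two application modes matter:

* per split (:func:`remove_signal_per_split`): fit and apply the removal
  independently on the training and validation sets, so no statistic
  crosses the split. This is the correct protocol.
* full dataset (:func:`remove_signal_full_dataset`): one pooled fit
  before splitting. This uses validation labels and is provided only to
  reproduce the induced-signal failure mode: pooling equalizes the
  *pooled* class means, which forces any later train/validation split's
  class-mean deviations to be exactly anti-proportional
  (``val = -(n_train / n_val) * train`` per gene), i.e. the removal
  manufactures a strong spurious signal where none existed. Outputs are
  flagged as leaky.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .data import LabeledExpressionMatrix

__all__ = [
    "RemovalModel",
    "fit_removal_model",
    "remove_linear_signal",
    "remove_signal_per_split",
    "remove_signal_full_dataset",
]


@dataclass
class RemovalModel:
    """Per-gene intercepts and sum-to-zero class effects.

    ``intercept[g]`` is the unweighted mean of the class means of gene
    ``g`` (the OLS intercept under sum-to-zero contrast coding, which is
    *not* the grand sample mean when classes are unbalanced).
    ``effects[c, g]`` is class ``c``'s deviation from that intercept;
    effects sum to zero over classes for every gene.
    """

    class_levels: np.ndarray  # (L,) ordered labels
    intercept: np.ndarray  # (n_genes,)
    effects: np.ndarray  # (L, n_genes)

    def effect_for(self, labels: np.ndarray) -> np.ndarray:
        """Per-sample fitted class effect, shape (n_samples, n_genes)."""
        lookup = {lvl: i for i, lvl in enumerate(self.class_levels)}
        try:
            idx = np.asarray([lookup[lbl] for lbl in labels])
        except KeyError as err:
            raise ValueError(f"label {err.args[0]!r} was not seen when fitting") from None
        return self.effects[idx]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("signal removal needs at least two class levels")
    return levels


def fit_removal_model(
    matrix: LabeledExpressionMatrix, labels: np.ndarray | None = None
) -> RemovalModel:
    """Per-gene OLS of expression on intercept + sum-to-zero class contrasts.

    Every class level must have at least one sample. All class levels
    enter one joint design, so multiclass removal is a single fit.
    """
    if labels is None:
        labels = matrix.class_labels
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("labels length must equal sample count")
    levels = _check_labels(labels)
    class_means = np.stack([matrix.values[labels == lvl].mean(axis=0) for lvl in levels])
    intercept = class_means.mean(axis=0)
    return RemovalModel(class_levels=levels, intercept=intercept, effects=class_means - intercept)


def remove_linear_signal(
    matrix: LabeledExpressionMatrix, labels: np.ndarray | None = None
) -> LabeledExpressionMatrix:
    """Fit the removal model on this matrix and subtract the class effects.

    Post-removal, every gene's class means are equal (to the unweighted
    mean of its pre-removal class means); shape and metadata are
    unchanged.
    """
    if labels is None:
        labels = matrix.class_labels
    model = fit_removal_model(matrix, labels)
    out = dataclasses.replace(matrix, values=matrix.values - model.effect_for(np.asarray(labels)))
    out.notes["ablation_mode"] = "per_set"
    return out


def remove_signal_per_split(
    train: LabeledExpressionMatrix,
    validation: LabeledExpressionMatrix,
    train_labels: np.ndarray | None = None,
    validation_labels: np.ndarray | None = None,
) -> tuple[LabeledExpressionMatrix, LabeledExpressionMatrix]:
    """Apply removal to training and validation sets independently.

    Each set gets its own fitted model; no statistic crosses the split.
    Both sets must contain every class of the other (a class with no
    samples on one side cannot have its mean equalized there).
    """
    train_labels = train.class_labels if train_labels is None else np.asarray(train_labels)
    validation_labels = (
        validation.class_labels if validation_labels is None else np.asarray(validation_labels)
    )
    for name, labels, other in (
        ("training", train_labels, validation_labels),
        ("validation", validation_labels, train_labels),
    ):
        missing = set(np.unique(other)) - set(np.unique(labels))
        if missing:
            raise ValueError(f"class {sorted(missing)[0]!r} is absent from the {name} set")
    out_train = remove_linear_signal(train, train_labels)
    out_val = remove_linear_signal(validation, validation_labels)
    out_train.notes["ablation_mode"] = out_val.notes["ablation_mode"] = "per_split"
    return out_train, out_val


def remove_signal_full_dataset(
    matrix: LabeledExpressionMatrix, labels: np.ndarray | None = None
) -> LabeledExpressionMatrix:
    """Pooled removal fit on the whole dataset before any splitting.

    Leaky by construction (validation labels inform the fit); provided to
    reproduce the induced-signal failure mode. The output is flagged via
    ``notes['ablation_mode'] = 'full_dataset'`` and downstream benchmark
    records carry the mode.
    """
    out = remove_linear_signal(matrix, labels)
    out.notes["ablation_mode"] = "full_dataset"
    out.notes["leaky"] = True
    return out
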