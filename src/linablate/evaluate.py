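"""Metrics, the benchmark orchestrator and results serialization.

Performance is measured as balanced accuracy — the unweighted mean of
per-class recall — so that large classes cannot dominate the score; its
chance level is ``1/L`` for ``L`` classes, which is also what the naive
most-frequent-class baseline attains.

:func:`run_benchmark` sweeps the full factorial grid of
seeds x training-set fractions x cross-validation folds x models under a
chosen ablation mode and split mode, emitting one
:class:`BenchmarkRecord` per completed cell.
:func:`run_ablation_comparison` is the focused before/after-ablation
experiment on a single stratified 80/20 split, and
:func:`run_pretraining_comparison` contrasts identically initialized
model copies trained with and without a pretraining stage. Results
round-trip losslessly through a schema-versioned TSV.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .ablation import remove_signal_full_dataset, remove_signal_per_split
from .data import LabeledExpressionMatrix
from .models import (
    HyperparameterGrid,
    ModelSpec,
    TrainConfig,
    build_model,
    nested_cv_select,
    predict,
    train,
)
from .rng import substream, substream_seed
from .splits import group_kfold, pretrain_split, subsample_training

__all__ = [
    "ConfusionTable",
    "BenchmarkRecord",
    "BenchmarkPlan",
    "balanced_accuracy",
    "accuracy",
    "confusion_table",
    "naive_baseline",
    "run_benchmark",
    "run_ablation_comparison",
    "run_pretraining_comparison",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

ABLATION_MODES = ("none", "per_split", "full_dataset")


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionTable:
    """L x L counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_levels: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())


def confusion_table(truth, predictions) -> ConfusionTable:
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    levels = np.unique(np.concatenate([truth, predictions]))
    counts = _sk_confusion(truth, predictions, labels=levels)
    return ConfusionTable(counts=counts, class_levels=levels)


def balanced_accuracy(truth, predictions) -> float:
    """Mean per-class recall over the classes present in ``truth``.

    Classes that never occur in ``truth`` contribute no recall term and
    are excluded from the mean.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.size == 0:
        raise ValueError("balanced accuracy of an empty sample is undefined")
    if truth.shape != predictions.shape:
        raise ValueError("truth and predictions must have the same length")
    recalls = [
        float(np.mean(predictions[truth == lvl] == lvl)) for lvl in np.unique(truth)
    ]
    return float(np.mean(recalls))


def accuracy(truth, predictions) -> float:
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("accuracy of an empty sample is undefined")
    return float(np.mean(truth == np.asarray(predictions)))


def naive_baseline(truth) -> float:
    """Balanced accuracy of the constant most-frequent-class predictor.

    Equals ``1/L`` when all ``L`` classes occur (0.5 for binary data,
    regardless of imbalance); degenerate single-class truth gives 1.0.
    """
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("baseline of an empty sample is undefined")
    levels, counts = np.unique(truth, return_counts=True)
    if len(levels) == 1:
        logger.warning("naive baseline on single-class truth is degenerate (1.0)")
    majority = levels[np.argmax(counts)]
    return balanced_accuracy(truth, np.full(truth.shape, majority))


# --------------------------------------------------------------------------
# benchmark records
# --------------------------------------------------------------------------

_RESULT_SCHEMA = "# linablate-results v1"
_RESULT_COLUMNS = (
    "model_kind",
    "seed",
    "fold_index",
    "subset_fraction",
    "ablation_mode",
    "split_mode",
    "regime",
    "balanced_accuracy",
    "accuracy",
    "n_train",
    "n_val",
    "evaluated_classes",
)


@dataclass
class BenchmarkRecord:
    """One completed (model, seed, fold, fraction, ablation) measurement."""

    model_kind: str
    seed: int
    fold_index: int
    subset_fraction: float
    ablation_mode: str
    split_mode: str
    balanced_accuracy: float
    accuracy: float
    n_train: int
    n_val: int
    evaluated_classes: str = ""
    regime: str = "standard"

    def key(self) -> tuple:
        return (
            self.model_kind,
            self.seed,
            self.fold_index,
            round(self.subset_fraction, 10),
            self.ablation_mode,
            self.split_mode,
            self.regime,
        )


@dataclass(frozen=True)
class BenchmarkPlan:
    """The sweep grid: folds, split mode, seeds and training fractions."""

    k: int = 5
    split_mode: str = "study"
    seeds: tuple = (0, 1, 2)
    fractions: tuple = (1.0,)
    inner_k: int = 2

    def validate(self) -> None:
        if self.split_mode not in ("study", "donor", "sample"):
            raise ValueError(f"unknown split mode {self.split_mode!r}")
        if not self.seeds or not self.fractions:
            raise ValueError("seeds and fractions must be non-empty")


# --------------------------------------------------------------------------
# shared training cell
# --------------------------------------------------------------------------


def _carve_early_stop(
    y: np.ndarray, groups: np.ndarray | None, seed: int, fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Positions (train, early_stop) carving ~``fraction`` off the training side.

    Whole groups are moved when grouping information is available and the
    result keeps every class represented in the remaining training data;
    otherwise the carve falls back to a class-stratified sample that
    leaves at least one training sample per class.
    """
    n = len(y)
    positions = np.arange(n)
    if groups is not None and len(np.unique(groups)) >= 3:
        uniq = np.unique(groups)
        order = substream(seed, "early_stop_groups").permutation(len(uniq))
        target = max(1, int(round(fraction * n)))
        es_mask = np.zeros(n, dtype=bool)
        taken = 0
        for gi in order[:-1]:  # always leave at least one group in train
            if taken >= target:
                break
            members = groups == uniq[gi]
            es_mask |= members
            taken += int(members.sum())
        train_pos, es_pos = positions[~es_mask], positions[es_mask]
        if es_pos.size and set(y[es_pos]) <= set(y[train_pos]):
            return train_pos, es_pos
    # stratified fallback
    es = []
    for lvl in np.unique(y):
        members = positions[y == lvl]
        if len(members) < 2:
            continue
        m = min(len(members) - 1, max(1, int(np.floor(len(members) * fraction + 0.5))))
        perm = substream(seed, f"early_stop/{lvl}").permutation(len(members))
        es.append(members[perm[:m]])
    es_pos = np.sort(np.concatenate(es)) if es else np.asarray([], dtype=int)
    mask = np.zeros(n, dtype=bool)
    mask[es_pos] = True
    return positions[~mask], es_pos


def _fit_and_score(
    kind: str,
    train_matrix: LabeledExpressionMatrix,
    val_matrix: LabeledExpressionMatrix,
    levels: np.ndarray,
    cell_seed: int,
    train_config: TrainConfig,
    grid: HyperparameterGrid | None,
    inner_k: int = 2,
    grouping_key: str | None = None,
) -> tuple[float, float, int, int]:
    """Train one model kind on a prepared train/validation pair."""
    code = {lvl: i for i, lvl in enumerate(levels)}
    y_tr = np.asarray([code[l] for l in train_matrix.class_labels])
    groups = None
    if grouping_key and grouping_key != "sample":
        groups = train_matrix.group_ids(grouping_key)
    spec = ModelSpec(kind=kind, input_dim=train_matrix.n_genes, n_classes=len(levels))
    X = train_matrix.values
    cfg = dataclasses.replace(train_config, seed=cell_seed)
    if grid is not None and len(grid.points()) > 1:
        lr, wd = nested_cv_select(
            spec, grid, X, y_tr, groups=groups, inner_k=inner_k,
            base_config=cfg, seed=cell_seed,
        )
        cfg = dataclasses.replace(cfg, learning_rate=lr, weight_decay=wd)
    tr_pos, es_pos = _carve_early_stop(y_tr, groups, cell_seed)
    model = build_model(spec, cell_seed)
    train(model, (X[tr_pos], y_tr[tr_pos]), (X[es_pos], y_tr[es_pos]), cfg)
    pred, _ = predict(model, val_matrix.values)
    y_val = np.asarray([code[l] for l in val_matrix.class_labels])
    return (
        balanced_accuracy(y_val, pred),
        accuracy(y_val, pred),
        len(tr_pos),
        val_matrix.n_samples,
    )


# --------------------------------------------------------------------------
# orchestrators
# --------------------------------------------------------------------------


def run_benchmark(
    dataset: LabeledExpressionMatrix,
    model_kinds: list[str],
    plan: BenchmarkPlan = BenchmarkPlan(),
    ablation_mode: str = "none",
    grid: HyperparameterGrid | None = None,
    grid_kinds: tuple | None = None,
    train_config: TrainConfig = TrainConfig(),
    resume_records: list[BenchmarkRecord] | None = None,
) -> tuple[list[BenchmarkRecord], list[dict]]:
    """Full factorial sweep: seeds x fractions x folds x models.

    Under ``per_split`` ablation the removal model is fit on the training
    and validation sides separately, after the split and after
    subsampling, so the ablated training set is exactly what the model
    sees. Under ``full_dataset`` one leaky pooled removal precedes
    splitting. Cells already present in ``resume_records`` are skipped;
    cell failures are recorded and the sweep continues. Returns
    (records, failures).
    """
    plan.validate()
    if ablation_mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {ablation_mode!r}")
    levels = dataset.class_levels
    if ablation_mode == "full_dataset":
        dataset = remove_signal_full_dataset(dataset)
    records = list(resume_records or [])
    done = {r.key() for r in records}
    failures: list[dict] = []
    for seed in plan.seeds:
        split_plan = group_kfold(dataset, plan.k, plan.split_mode, seed)
        for fold in range(plan.k):
            train_idx, val_idx = split_plan.fold_split(fold)
            for fraction in plan.fractions:
                sub_idx = subsample_training(
                    train_idx, fraction, dataset.class_labels[train_idx], seed
                )
                train_m = dataset.subset_samples(sub_idx)
                val_m = dataset.subset_samples(val_idx)
                if ablation_mode == "per_split":
                    try:
                        train_m, val_m = remove_signal_per_split(train_m, val_m)
                    except ValueError as err:
                        failures.append(
                            {"seed": seed, "fold": fold, "fraction": fraction,
                             "model": "*", "error": str(err)}
                        )
                        continue
                for kind in model_kinds:
                    probe = BenchmarkRecord(
                        kind, seed, fold, fraction, ablation_mode, plan.split_mode,
                        0.0, 0.0, 0, 0,
                    )
                    if probe.key() in done:
                        continue
                    cell_seed = substream_seed(
                        seed, f"cell/{fold}/{fraction}/{kind}/{ablation_mode}"
                    )
                    kind_grid = grid if (grid_kinds is None or kind in grid_kinds) else None
                    try:
                        ba, acc, n_tr, n_va = _fit_and_score(
                            kind, train_m, val_m, levels, cell_seed, train_config,
                            kind_grid, plan.inner_k, plan.split_mode,
                        )
                    except Exception as err:  # cell failure: record, continue
                        failures.append(
                            {"seed": seed, "fold": fold, "fraction": fraction,
                             "model": kind, "error": str(err)}
                        )
                        logger.warning("benchmark cell failed: %s", err)
                        continue
                    records.append(
                        BenchmarkRecord(
                            model_kind=kind,
                            seed=seed,
                            fold_index=fold,
                            subset_fraction=fraction,
                            ablation_mode=ablation_mode,
                            split_mode=plan.split_mode,
                            balanced_accuracy=ba,
                            accuracy=acc,
                            n_train=n_tr,
                            n_val=n_va,
                            evaluated_classes="|".join(np.unique(val_m.class_labels)),
                        )
                    )
    return records, failures


def run_ablation_comparison(
    dataset: LabeledExpressionMatrix,
    model_kinds: list[str],
    seeds: tuple = (0,),
    val_fraction: float = 0.2,
    ablation_modes: tuple = ("none", "per_split"),
    grid: HyperparameterGrid | None = None,
    grid_kinds: tuple | None = None,
    train_config: TrainConfig = TrainConfig(),
) -> list[BenchmarkRecord]:
    """Before/after-ablation comparison on a stratified 80/20 sample split.

    For every seed a class-stratified ``val_fraction`` of samples is held
    out; each requested ablation mode is applied (``none`` trains on the
    raw data, ``per_split`` fits removal on the two sides independently,
    ``full_dataset`` pools the fit before the split) and every model kind
    is trained and scored on the held-out side.
    """
    levels = dataset.class_levels
    records = []
    for seed in seeds:
        all_idx = np.arange(dataset.n_samples)
        val_idx = subsample_training(
            all_idx, val_fraction, dataset.class_labels, substream_seed(seed, "holdout")
        )
        train_idx = np.setdiff1d(all_idx, val_idx)
        for mode in ablation_modes:
            if mode == "full_dataset":
                ablated = remove_signal_full_dataset(dataset)
                train_m = ablated.subset_samples(train_idx)
                val_m = ablated.subset_samples(val_idx)
            else:
                train_m = dataset.subset_samples(train_idx)
                val_m = dataset.subset_samples(val_idx)
                if mode == "per_split":
                    train_m, val_m = remove_signal_per_split(train_m, val_m)
                elif mode != "none":
                    raise ValueError(f"unknown ablation mode {mode!r}")
            for kind in model_kinds:
                cell_seed = substream_seed(seed, f"ablation_cmp/{mode}/{kind}")
                kind_grid = grid if (grid_kinds is None or kind in grid_kinds) else None
                ba, acc, n_tr, n_va = _fit_and_score(
                    kind, train_m, val_m, levels, cell_seed, train_config, kind_grid
                )
                records.append(
                    BenchmarkRecord(
                        model_kind=kind,
                        seed=seed,
                        fold_index=0,
                        subset_fraction=1.0,
                        ablation_mode=mode,
                        split_mode="sample",
                        balanced_accuracy=ba,
                        accuracy=acc,
                        n_train=n_tr,
                        n_val=n_va,
                        evaluated_classes="|".join(np.unique(val_m.class_labels)),
                    )
                )
    return records


def run_pretraining_comparison(
    dataset: LabeledExpressionMatrix,
    model_kinds: list[str],
    seeds: tuple = (0, 1, 2, 3, 4),
    fractions: tuple = (0.4, 0.4, 0.2),
    grouping_key: str = "study",
    train_config: TrainConfig = TrainConfig(),
) -> list[BenchmarkRecord]:
    """Pretraining versus plain training from identical initializations.

    Per seed the studies are split 40/40/20 into pretrain/train/validation
    sets. For each model kind two copies are built from the same seed (so
    their initial parameters are bit-identical); one trains on the
    training set only, the other trains on the pretraining set first and
    is then fine-tuned on the training set. Both are scored on the
    validation set; records carry ``regime`` = ``standard`` or
    ``pretrained``.
    """
    levels = dataset.class_levels
    code = {lvl: i for i, lvl in enumerate(levels)}
    records = []
    for seed in seeds:
        plan = pretrain_split(dataset, fractions, seed, grouping_key)
        parts = {
            name: dataset.subset_samples(plan.indices(name))
            for name in ("pretrain", "train", "validation")
        }
        y = {k: np.asarray([code[l] for l in m.class_labels]) for k, m in parts.items()}
        for kind in model_kinds:
            cell_seed = substream_seed(seed, f"pretrain_cmp/{kind}")
            spec = ModelSpec(kind, dataset.n_genes, len(levels))
            cfg = dataclasses.replace(train_config, seed=cell_seed)

            def _stage(model, part):
                groups = parts[part].group_ids(grouping_key)
                tr, es = _carve_early_stop(y[part], groups, cell_seed)
                X = parts[part].values
                train(model, (X[tr], y[part][tr]), (X[es], y[part][es]), cfg)
                return model

            for regime in ("standard", "pretrained"):
                model = build_model(spec, cell_seed)  # identical init both regimes
                if regime == "pretrained":
                    _stage(model, "pretrain")
                _stage(model, "train")
                pred, _ = predict(model, parts["validation"].values)
                records.append(
                    BenchmarkRecord(
                        model_kind=kind,
                        seed=seed,
                        fold_index=0,
                        subset_fraction=1.0,
                        ablation_mode="none",
                        split_mode=grouping_key,
                        balanced_accuracy=balanced_accuracy(y["validation"], pred),
                        accuracy=accuracy(y["validation"], pred),
                        n_train=parts["train"].n_samples,
                        n_val=parts["validation"].n_samples,
                        evaluated_classes="|".join(np.unique(parts["validation"].class_labels)),
                        regime=regime,
                    )
                )
    return records


# --------------------------------------------------------------------------
# results I/O
# --------------------------------------------------------------------------


def write_results(records: list[BenchmarkRecord], path) -> None:
    """Write records as tab-separated text with a schema-version line."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(_RESULT_SCHEMA + "\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_RESULT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.model_kind, r.seed, r.fold_index, repr(r.subset_fraction),
                    r.ablation_mode, r.split_mode, r.regime,
                    repr(r.balanced_accuracy), repr(r.accuracy),
                    r.n_train, r.n_val, r.evaluated_classes,
                ]
            )


def read_results(path) -> list[BenchmarkRecord]:
    """Read a results TSV; strict about schema, columns and field types."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _RESULT_SCHEMA:
        raise ValueError(f"{path}: line 1: missing schema line {_RESULT_SCHEMA!r}")
    if len(lines) < 2:
        raise ValueError(f"{path}: line 2: missing header")
    header = lines[1].split("\t")
    unknown = [c for c in header if c not in _RESULT_COLUMNS]
    if unknown:
        raise ValueError(f"{path}: line 2: unknown column {unknown[0]!r}")
    missing = [c for c in _RESULT_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: line 2: missing column {missing[0]!r}")
    records = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(f"{path}: line {lineno}: expected {len(header)} fields")
        row = dict(zip(header, fields))
        try:
            records.append(
                BenchmarkRecord(
                    model_kind=row["model_kind"],
                    seed=int(row["seed"]),
                    fold_index=int(row["fold_index"]),
                    subset_fraction=float(row["subset_fraction"]),
                    ablation_mode=row["ablation_mode"],
                    split_mode=row["split_mode"],
                    regime=row["regime"],
                    balanced_accuracy=float(row["balanced_accuracy"]),
                    accuracy=float(row["accuracy"]),
                    n_train=int(row["n_train"]),
                    n_val=int(row["n_val"]),
                    evaluated_classes=row["evaluated_classes"],
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}: line {lineno}: {err}") from None
    return records
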