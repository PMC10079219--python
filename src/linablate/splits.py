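"""Leakage-aware data splitting.

Expression compendia are study-structured: samples from one study (or
donor) share technical and biological factors, so scattering a study's
samples across cross-validation folds lets models exploit within-study
correlation and inflates validation scores. The splitters here therefore
assign whole *groups* — studies, donors, or (degenerately) single samples
— to folds or to pretrain/train/validation sets.

Fold assignment is deterministic given the seed: groups are shuffled,
stably sorted by descending size, and each is placed greedily on the
currently smallest fold, keeping fold sizes comparable when group sizes
vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledExpressionMatrix
from .rng import substream

__all__ = [
    "SplitPlan",
    "group_fold_assignment",
    "group_kfold",
    "pretrain_split",
    "subsample_training",
    "read_split_plan",
]

PRETRAIN_SETS = ("pretrain", "train", "validation")


@dataclass
class SplitPlan:
    """Assignment of every sample to one fold (or named set).

    ``assignment`` holds fold indices as strings ("0".."k-1") for k-fold
    plans, or set tags ("pretrain" / "train" / "validation") for
    three-way plans. No group ever spans two folds or sets unless the
    grouping key is ``sample``.
    """

    sample_ids: np.ndarray
    assignment: np.ndarray
    grouping_key: str
    seed: int

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.assignment = np.asarray([str(a) for a in self.assignment], dtype=object)
        if len(self.sample_ids) != len(self.assignment):
            raise ValueError("every sample needs exactly one assignment")

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.assignment)

    def indices(self, label) -> np.ndarray:
        """Positions of the samples assigned to ``label`` (fold or set)."""
        return np.flatnonzero(self.assignment == str(label))

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_positions, validation_positions) for one held-out fold."""
        val = self.indices(fold)
        if val.size == 0:
            raise ValueError(f"no samples in fold {fold}")
        train = np.flatnonzero(self.assignment != str(fold))
        return train, val

    def check_group_integrity(self, groups: np.ndarray) -> None:
        """Assert no group's samples span two folds/sets."""
        frame = pd.DataFrame({"group": groups, "fold": self.assignment})
        spread = frame.groupby("group")["fold"].nunique()
        if (spread > 1).any():
            bad = spread.index[spread > 1][0]
            raise AssertionError(f"group {bad!r} spans multiple folds")

    def achieved_fractions(self) -> dict:
        """Fraction of samples in each fold/set."""
        n = len(self.assignment)
        return {lbl: self.indices(lbl).size / n for lbl in self.labels}

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "fold_or_set": self.assignment,
                "grouping_key": self.grouping_key,
                "seed": self.seed,
            }
        ).to_csv(Path(path), sep="\t", index=False)


def read_split_plan(path) -> SplitPlan:
    frame = pd.read_csv(Path(path), sep="\t", dtype=str)
    return SplitPlan(
        sample_ids=frame["sample_id"].to_numpy(),
        assignment=frame["fold_or_set"].to_numpy(),
        grouping_key=frame["grouping_key"].iloc[0],
        seed=int(frame["seed"].iloc[0]),
    )


def _ordered_groups(groups: np.ndarray, seed: int, stream: str) -> list:
    """Unique groups, shuffled by seed then stably sorted by descending size."""
    uniq, counts = np.unique(groups, return_counts=True)
    order = substream(seed, stream).permutation(len(uniq))
    uniq, counts = uniq[order], counts[order]
    by_size = np.argsort(-counts, kind="stable")
    return [(uniq[i], int(counts[i])) for i in by_size]


def group_fold_assignment(
    groups: np.ndarray, k: int, seed: int = 0, stream: str = "group_kfold"
) -> np.ndarray:
    """Per-sample fold index (0..k-1) from greedy balanced group assignment."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ordered = _ordered_groups(np.asarray(groups), seed, f"{stream}/k{k}")
    if len(ordered) < k:
        raise ValueError(f"only {len(ordered)} groups for {k} folds")
    fold_of = {}
    sizes = np.zeros(k, dtype=int)
    for group, count in ordered:
        fold = int(np.argmin(sizes))
        fold_of[group] = fold
        sizes[fold] += count
    return np.asarray([fold_of[g] for g in groups])


def group_kfold(
    matrix: LabeledExpressionMatrix,
    k: int = 5,
    grouping_key: str = "study",
    seed: int = 0,
) -> SplitPlan:
    """Assign whole groups to ``k`` folds, balancing fold sample counts.

    ``grouping_key`` is ``study``, ``donor`` or ``sample``; with
    ``sample`` this reduces to plain (ungrouped) k-fold. Largest groups
    are placed first, each on the fold with the fewest samples so far
    (ties to the lowest fold index), after a seed-driven shuffle that
    randomizes the placement of equal-sized groups.
    """
    groups = matrix.group_ids(grouping_key)
    fold = group_fold_assignment(groups, k, seed)
    plan = SplitPlan(
        sample_ids=matrix.sample_ids,
        assignment=fold,
        grouping_key=grouping_key,
        seed=seed,
    )
    if grouping_key != "sample":
        plan.check_group_integrity(groups)
    return plan


def pretrain_split(
    matrix: LabeledExpressionMatrix,
    fractions: tuple[float, float, float] = (0.4, 0.4, 0.2),
    seed: int = 0,
    grouping_key: str = "study",
) -> SplitPlan:
    """Three-way study-wise split into pretrain/train/validation sets.

    Whole groups are assigned greedily to the set with the largest
    remaining sample-count deficit relative to its target fraction, so
    achieved fractions approximate the targets. Different seeds reassign
    studies, supporting repeated-pretraining designs.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != 3:
        raise ValueError("expected (pretrain, train, validation) fractions")
    groups = matrix.group_ids(grouping_key)
    ordered = _ordered_groups(groups, seed, "pretrain_split")
    if len(ordered) < 3:
        raise ValueError("pretraining splits need at least three groups")
    total = matrix.n_samples
    assigned = np.zeros(3)
    set_of = {}
    for group, count in ordered:
        deficits = [fractions[i] * total - assigned[i] for i in range(3)]
        best = int(np.argmax(deficits))
        set_of[group] = PRETRAIN_SETS[best]
        assigned[best] += count
    plan = SplitPlan(
        sample_ids=matrix.sample_ids,
        assignment=[set_of[g] for g in groups],
        grouping_key=grouping_key,
        seed=seed,
    )
    plan.check_group_integrity(groups)
    return plan


def subsample_training(
    train_indices: np.ndarray,
    fraction: float,
    labels: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Class-stratified subsample of a training index set, nested in fraction.

    Per class, ``round_half_up(n_class * fraction)`` samples (at least 1)
    are taken without replacement. For a fixed seed the per-class order
    is a single permutation and every fraction takes a prefix of it, so
    the 10% subset is contained in the 20% subset and learning curves are
    monotone in data rather than resampling noise. ``fraction=1`` returns
    the input set unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    train_indices = np.asarray(train_indices)
    labels = np.asarray(labels)
    if len(labels) != len(train_indices):
        raise ValueError("labels must align with train_indices")
    if fraction == 1.0:
        return np.sort(train_indices)
    chosen = []
    for lvl in np.unique(labels):
        members = train_indices[labels == lvl]
        perm = substream(seed, f"subsample/{lvl}").permutation(len(members))
        m = max(1, int(np.floor(len(members) * fraction + 0.5)))
        chosen.append(members[perm[:m]])
    return np.sort(np.concatenate(chosen))
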