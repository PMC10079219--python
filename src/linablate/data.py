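"""Labeled expression matrices and their plain-text serialization.

The central container is :class:`LabeledExpressionMatrix`: a dense
samples x genes matrix with per-sample class labels and optional study /
donor identifiers (the grouping keys that leakage-aware cross-validation
needs), plus an optional per-gene ``feature_kind`` tag used by the
synthetic generators.

On disk a matrix is a pair of tab-separated files: ``<stem>.tsv`` holding
the values (header row of gene ids, one row per sample keyed by sample id)
and ``<stem>.meta.tsv`` holding the sample metadata. When genes carry
``feature_kind`` tags a third file ``<stem>.genes.tsv`` records them.
Floats are written with 17 significant digits, so a round-trip is exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledExpressionMatrix", "read_matrix", "FEATURE_KINDS"]

FEATURE_KINDS = ("linear", "nonlinear", "noise")

_FLOAT_FMT = "%.17g"


def _as_str_array(x: Sequence) -> np.ndarray:
    return np.asarray([str(v) for v in x], dtype=object)


@dataclass
class LabeledExpressionMatrix:
    """Samples x genes expression values with per-sample labels.

    Parameters
    ----------
    values
        Dense ``(n_samples, n_genes)`` float array. Rows are observations,
        matching the classification-task view of the data.
    sample_ids, gene_ids
        Unique string identifiers for rows and columns.
    class_labels
        Per-sample categorical label (stored as strings).
    study_ids, donor_ids
        Optional per-sample grouping identifiers for leakage-aware splits.
    feature_kind
        Optional per-gene tag in ``{"linear", "nonlinear", "noise"}``
        recording which signal block a synthetic gene belongs to.
    notes
        Free-form provenance (e.g. the ablation mode applied); carried
        along by operators, not serialized into the value matrix.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    gene_ids: np.ndarray
    class_labels: np.ndarray
    study_ids: Optional[np.ndarray] = None
    donor_ids: Optional[np.ndarray] = None
    feature_kind: Optional[np.ndarray] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        self.sample_ids = _as_str_array(self.sample_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.class_labels = _as_str_array(self.class_labels)
        for name in ("study_ids", "donor_ids", "feature_kind"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, _as_str_array(val))
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise ValueError("sample_ids / class_labels length must equal row count")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must equal column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no NaN/inf)")
        for name in ("study_ids", "donor_ids"):
            val = getattr(self, name)
            if val is not None and len(val) != n:
                raise ValueError(f"{name} length must equal sample count")
        if self.feature_kind is not None:
            if len(self.feature_kind) != p:
                raise ValueError("feature_kind length must equal gene count")
            bad = set(self.feature_kind) - set(FEATURE_KINDS)
            if bad:
                raise ValueError(f"unknown feature_kind values: {sorted(bad)}")

    # -- views -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def class_levels(self) -> np.ndarray:
        """Sorted unique class labels."""
        return np.unique(self.class_labels)

    def subset_samples(self, index) -> "LabeledExpressionMatrix":
        """New matrix restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            values=self.values[index],
            sample_ids=self.sample_ids[index],
            class_labels=self.class_labels[index],
            study_ids=None if self.study_ids is None else self.study_ids[index],
            donor_ids=None if self.donor_ids is None else self.donor_ids[index],
            notes=dict(self.notes),
        )

    def subset_genes(self, index) -> "LabeledExpressionMatrix":
        """New matrix restricted to the given gene positions (order kept)."""
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            values=self.values[:, index],
            gene_ids=self.gene_ids[index],
            feature_kind=None if self.feature_kind is None else self.feature_kind[index],
            notes=dict(self.notes),
        )

    def group_ids(self, grouping_key: str) -> np.ndarray:
        """Per-sample grouping values for ``study``, ``donor`` or ``sample``."""
        if grouping_key == "sample":
            return self.sample_ids
        if grouping_key == "study":
            if self.study_ids is None:
                raise ValueError("matrix carries no study_ids")
            return self.study_ids
        if grouping_key == "donor":
            if self.donor_ids is None:
                raise ValueError("matrix carries no donor_ids")
            return self.donor_ids
        raise ValueError(f"unknown grouping key: {grouping_key!r}")

    # -- serialization ---------------------------------------------------
    def to_tsv(self, stem) -> None:
        """Write ``<stem>.tsv`` (+ ``.meta.tsv``, optionally ``.genes.tsv``)."""
        stem = Path(stem)
        stem = stem.with_suffix("") if stem.suffix == ".tsv" else stem
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        frame.index.name = "sample_id"
        frame.to_csv(stem.with_suffix(".tsv"), sep="\t", float_format=_FLOAT_FMT)
        meta = pd.DataFrame({"sample_id": self.sample_ids, "class_label": self.class_labels})
        if self.study_ids is not None:
            meta["study_id"] = self.study_ids
        if self.donor_ids is not None:
            meta["donor_id"] = self.donor_ids
        meta.to_csv(stem.with_suffix(".meta.tsv"), sep="\t", index=False)
        if self.feature_kind is not None:
            genes = pd.DataFrame({"gene_id": self.gene_ids, "feature_kind": self.feature_kind})
            genes.to_csv(stem.with_suffix(".genes.tsv"), sep="\t", index=False)


def read_matrix(stem) -> LabeledExpressionMatrix:
    """Read a matrix written by :meth:`LabeledExpressionMatrix.to_tsv`."""
    stem = Path(stem)
    stem = stem.with_suffix("") if stem.suffix == ".tsv" else stem
    frame = pd.read_csv(
        stem.with_suffix(".tsv"), sep="\t", index_col="sample_id",
        float_precision="round_trip",
    )
    meta = pd.read_csv(stem.with_suffix(".meta.tsv"), sep="\t", dtype=str)
    meta = meta.set_index("sample_id")
    meta = meta.loc[[str(s) for s in frame.index]]
    kinds = None
    genes_path = stem.with_suffix(".genes.tsv")
    if genes_path.exists():
        genes = pd.read_csv(genes_path, sep="\t", dtype=str).set_index("gene_id")
        kinds = genes.loc[[str(g) for g in frame.columns], "feature_kind"].to_numpy()
    return LabeledExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        sample_ids=frame.index.to_numpy(),
        gene_ids=frame.columns.to_numpy(),
        class_labels=meta["class_label"].to_numpy(),
        study_ids=meta["study_id"].to_numpy() if "study_id" in meta else None,
        donor_ids=meta["donor_id"].to_numpy() if "donor_id" in meta else None,
        feature_kind=kinds,
    )
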