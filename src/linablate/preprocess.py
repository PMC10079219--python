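"""Expression preprocessing: TPM, sparsity filtering, scaling, gene selection.

The operators mirror a common bulk RNA-seq preparation pipeline:
counts -> TPM (length-normalized, per-sample rescale to one million) ->
drop ultra-sparse samples (a crude single-cell filter) -> per-gene
zero-one scaling -> keep the most variable genes. Each step is usable on
its own; :func:`preprocess_pipeline` runs them in that order.

Scaling and gene selection have a fitted state (per-gene min/max, the
selected gene set). Fitting them on a full dataset before cross-validation
splitting leaks fold information; :func:`preprocess_pipeline` therefore
takes a ``split_safe`` flag, and the leak status is recorded in the
matrix's notes either way.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledExpressionMatrix

__all__ = [
    "GeneLengthTable",
    "read_gene_lengths",
    "tpm_normalize",
    "filter_sparse_samples",
    "zero_one_scale",
    "select_most_variable",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneLengthTable:
    """Gene lengths in base pairs, keyed by gene id."""

    lengths: pd.Series  # index gene_id, values length_bp

    def __post_init__(self) -> None:
        self.lengths = pd.Series(self.lengths)
        self.lengths.index = self.lengths.index.astype(str)
        if self.lengths.index.has_duplicates:
            raise ValueError("duplicate gene ids in length table")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")

    @classmethod
    def from_dict(cls, mapping) -> "GeneLengthTable":
        return cls(pd.Series(mapping, dtype=float))

    def lengths_for(self, gene_ids) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise KeyError(f"no gene length for gene {missing[0]!r}")
        return self.lengths.loc[list(gene_ids)].to_numpy(dtype=float)


def read_gene_lengths(path) -> GeneLengthTable:
    """Read a two-column tab-separated table (gene_id, length_bp)."""
    table = pd.read_csv(Path(path), sep="\t")
    if table.shape[1] < 2:
        raise ValueError("gene length table needs columns gene_id and length_bp")
    return GeneLengthTable(
        pd.Series(table.iloc[:, 1].to_numpy(dtype=float), index=table.iloc[:, 0].astype(str))
    )


def tpm_normalize(
    counts: LabeledExpressionMatrix, lengths: GeneLengthTable
) -> LabeledExpressionMatrix:
    """Convert raw counts to transcripts per kilobase million.

    Per sample: ``rate_g = count_g / (length_g / 1000)``, then rates are
    rescaled to sum to 10^6. Rows that are entirely zero stay zero.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative for TPM conversion")
    length_kb = lengths.lengths_for(counts.gene_ids) / 1000.0
    rates = counts.values / length_kb
    totals = rates.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(totals > 0, rates / totals * 1e6, 0.0)
    return dataclasses.replace(counts, values=tpm)


def filter_sparse_samples(
    matrix: LabeledExpressionMatrix, max_sparsity: float = 0.75
) -> LabeledExpressionMatrix:
    """Drop samples whose fraction of zero-valued genes exceeds ``max_sparsity``.

    The rule is strictly greater-than: a sample at exactly the threshold
    is retained. Sample metadata is filtered in lockstep and order kept.
    """
    sparsity = (matrix.values == 0).mean(axis=1)
    keep = np.flatnonzero(sparsity <= max_sparsity)
    if keep.size == 0:
        logger.warning(
            "sparsity filter at %.2f removed all %d samples", max_sparsity, matrix.n_samples
        )
    if keep.size == matrix.n_samples:
        return matrix
    return matrix.subset_samples(keep)


def zero_one_scale(matrix: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """Scale each gene's range to [0, 1]; constant genes map to 0."""
    lo = matrix.values.min(axis=0)
    span = matrix.values.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = np.where(span > 0, (matrix.values - lo) / safe, 0.0)
    return dataclasses.replace(matrix, values=scaled)


def select_most_variable(matrix: LabeledExpressionMatrix, k: int = 5000) -> LabeledExpressionMatrix:
    """Keep the ``k`` genes with the largest variance.

    Ties are broken toward the lexicographically smaller gene id; the
    retained genes keep their input order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds gene count {matrix.n_genes}")
    if k == matrix.n_genes:
        return matrix
    var = matrix.values.var(axis=0, ddof=1)
    ranked = sorted(range(matrix.n_genes), key=lambda j: (-var[j], matrix.gene_ids[j]))
    keep = np.sort(np.asarray(ranked[:k]))
    return matrix.subset_genes(keep)


def preprocess_pipeline(
    matrix: LabeledExpressionMatrix,
    lengths: GeneLengthTable | None = None,
    *,
    tpm: bool = False,
    max_sparsity: float | None = 0.75,
    scale: bool = True,
    top_k: int | None = 5000,
    split_safe: bool = False,
) -> LabeledExpressionMatrix:
    """TPM -> sparsity filter -> zero-one scale -> most-variable genes.

    With ``split_safe=False`` (the default, matching dataset-level
    preparation) scaling and gene selection are fit on all samples given,
    which leaks information across any later split; the choice is recorded
    in ``notes['preprocess_fit']``. Pass the training fold alone with
    ``split_safe=True`` to fit split-safely.
    """
    out = matrix
    if tpm:
        if lengths is None:
            raise ValueError("TPM conversion requires a gene length table")
        out = tpm_normalize(out, lengths)
    if max_sparsity is not None:
        out = filter_sparse_samples(out, max_sparsity)
    if scale:
        out = zero_one_scale(out)
    if top_k is not None and top_k < out.n_genes:
        out = select_most_variable(out, top_k)
    out.notes["preprocess_fit"] = "train-only" if split_safe else "full-dataset"
    return out


def preprocess_per_split(
    train: LabeledExpressionMatrix,
    validation: LabeledExpressionMatrix,
    lengths: GeneLengthTable | None = None,
    *,
    tpm: bool = False,
    max_sparsity: float | None = 0.75,
    scale: bool = True,
    top_k: int | None = 5000,
) -> tuple[LabeledExpressionMatrix, LabeledExpressionMatrix]:
    """Split-safe pipeline: fit every stateful step on the training fold only.

    TPM and the sparsity filter are per-sample and need no fitting. The
    scaler's per-gene min/max and the selected gene set come from the
    training fold and are applied unchanged to the validation fold
    (validation values are clipped into [0, 1] after scaling).
    """
    if tpm:
        if lengths is None:
            raise ValueError("TPM conversion requires a gene length table")
        train = tpm_normalize(train, lengths)
        validation = tpm_normalize(validation, lengths)
    if max_sparsity is not None:
        train = filter_sparse_samples(train, max_sparsity)
        validation = filter_sparse_samples(validation, max_sparsity)
    if scale:
        lo = train.values.min(axis=0)
        span = train.values.max(axis=0) - lo
        safe = np.where(span > 0, span, 1.0)

        def _apply(m: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
            scaled = np.where(span > 0, (m.values - lo) / safe, 0.0)
            return dataclasses.replace(m, values=np.clip(scaled, 0.0, 1.0))

        train, validation = _apply(train), _apply(validation)
    if top_k is not None and top_k < train.n_genes:
        selected = select_most_variable(train, top_k)
        keep_ids = set(selected.gene_ids)
        keep = np.flatnonzero([g in keep_ids for g in validation.gene_ids])
        train, validation = selected, validation.subset_genes(keep)
    train.notes["preprocess_fit"] = "train-only"
    validation.notes["preprocess_fit"] = "train-only"
    return train, validation
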