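"""Containers for expression matrices, knowledge masks and participation vectors.

An expression matrix is genes x samples on a log-like additive scale; the
coordinative direction lives in sample space (length M), the participation
vector in gene space (length N).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError

__all__ = [
    "ExpressionMatrix",
    "KnowledgeMask",
    "participation",
    "preprocess",
]


def _as_str_array(ids: Iterable, what: str, expected: int | None = None) -> np.ndarray:
    arr = np.asarray(list(ids) if not isinstance(ids, np.ndarray) else ids, dtype=object)
    arr = arr.astype(str)
    if expected is not None and arr.size != expected:
        raise InputError(f"{what}: expected {expected} identifiers, got {arr.size}")
    return arr


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with unique gene and sample identifiers."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError(f"expression values must be 2-D, got shape {self.values.shape}")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise InputError(f"need at least 2 genes and 2 samples, got {n} x {m}")
        if not np.isfinite(self.values).all():
            raise InputError("expression matrix contains non-finite values")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids", n)
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids", m)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids, return_counts=True)
            if (counts > 1).any():
                dups = uniq[counts > 1].tolist()
                raise InputError(f"duplicate {name} ids: {dups}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_indices(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices of the given gene ids (exact string match, input order)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx, missing = [], []
        for g in ids:
            g = str(g)
            (idx if g in lookup else missing).append(lookup.get(g, g))
        if missing:
            raise InputError(f"gene ids not present in matrix: {missing}")
        return np.asarray(idx, dtype=int)

    def subset(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(self.values[idx], self.gene_ids[idx], self.sample_ids)


def preprocess(values: np.ndarray, center: bool = True, scale: bool = False) -> np.ndarray:
    """Row-wise preprocessing: remove each gene's mean across samples and,
    optionally, scale rows to unit variance (constant rows are left at zero).

    Centering removes baseline offsets so that projections onto a direction
    reflect covariation rather than absolute expression level.
    """
    out = np.array(values, dtype=float, copy=True)
    if center:
        out -= out.mean(axis=1, keepdims=True)
    if scale:
        sd = out.std(axis=1, ddof=1, keepdims=True)
        np.divide(out, sd, out=out, where=sd > 0)
        out[np.broadcast_to(sd == 0, out.shape)] = 0.0
    return out


@dataclass
class KnowledgeMask:
    """Paired positive/negative weight vectors over genes.

    Weights are non-negative; a strictly positive weight marks membership.
    Integer weights > 1 on the negative side record bootstrap multiplicity.
    A gene may carry weight in neither vector (excluded from the objective).
    """

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=float)
        self.negative = np.asarray(self.negative, dtype=float)
        if self.positive.shape != self.negative.shape or self.positive.ndim != 1:
            raise InputError(
                f"mask vectors must be 1-D and equal length, got "
                f"{self.positive.shape} and {self.negative.shape}"
            )
        if (self.positive < 0).any() or (self.negative < 0).any():
            raise InputError("mask weights must be non-negative")
        if (self.positive * self.negative != 0).any():
            raise InputError("a gene cannot be both positive and negative")
        if self.positive.sum() < 2:
            raise InputError("need total positive weight >= 2 (at least two knowledge genes)")
        if self.negative.sum() < 2:
            raise InputError("need total negative weight >= 2 (at least two background draws)")

    @property
    def n_genes(self) -> int:
        return self.positive.size

    @classmethod
    def from_gene_sets(
        cls,
        gene_ids: Sequence[str],
        positives: Iterable[str],
        negatives: Iterable[str] | None = None,
    ) -> "KnowledgeMask":
        """Build unit-weight masks from gene-id sets.

        When ``negatives`` is None every gene outside ``positives`` is background.
        """
        gene_ids = _as_str_array(gene_ids, "gene_ids")
        pos_set = {str(g) for g in positives}
        pos = np.isin(gene_ids, list(pos_set)).astype(float)
        if negatives is None:
            neg = 1.0 - pos
        else:
            neg_set = {str(g) for g in negatives} - pos_set
            neg = np.isin(gene_ids, list(neg_set)).astype(float)
        return cls(pos, neg)


def _direction_vector(w) -> np.ndarray:
    # accept a raw vector or a CoordinativeDirection-like object with .w
    return np.asarray(getattr(w, "w", w), dtype=float)


def participation(x, w) -> np.ndarray:
    """Participation vector A = X @ w: per-gene projection onto direction w."""
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    wv = _direction_vector(w)
    if wv.ndim != 1 or values.shape[1] != wv.size:
        raise InputError(
            f"dimension mismatch: matrix has {values.shape[1]} samples but "
            f"direction has length {wv.size}"
        )
    return values @ wv
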