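"""Functional wrappers around the baseline rankers.

Each returns a full permutation of the gene ids, score-descending with ties
broken by gene id ascending — the same contract as the COCA ranking.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .data import ExpressionMatrix
from .estimators import (
    FoldChangeRanker,
    PcaGuidedRanker,
    SamRanker,
    VarianceRanker,
)

__all__ = ["variance_rank", "fold_change_rank", "sam_rank", "pca_guided_rank"]


def variance_rank(x: ExpressionMatrix) -> np.ndarray:
    return VarianceRanker().fit(x.values, gene_ids=x.gene_ids).ranking_


def fold_change_rank(x: ExpressionMatrix, labels: Sequence) -> np.ndarray:
    est = FoldChangeRanker().fit(x.values, gene_ids=x.gene_ids, sample_labels=labels)
    return est.ranking_


def sam_rank(x: ExpressionMatrix, labels: Sequence, s0: float | None = None) -> np.ndarray:
    est = SamRanker(s0=s0).fit(x.values, gene_ids=x.gene_ids, sample_labels=labels)
    return est.ranking_


def pca_guided_rank(x: ExpressionMatrix, knowledge: Iterable[str]) -> np.ndarray:
    know = {str(g) for g in knowledge}
    y = np.isin(x.gene_ids, sorted(know)).astype(int)
    return PcaGuidedRanker().fit(x.values, y, gene_ids=x.gene_ids).ranking_
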