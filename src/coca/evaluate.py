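"""ROC/AUC evaluation of gene rankings against a labeled positive set.

The curve and area are computed with scikit-learn; the AUC equals the
tie-corrected Mann-Whitney concordance probability (tied positive-negative
pairs count one half).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn import metrics

from ._exceptions import InputError

__all__ = ["LabeledRanking", "roc_curve", "auc", "evaluate_ranking"]


@dataclass
class LabeledRanking:
    """A scored gene ordering plus the set of true positives."""

    gene_ids: np.ndarray
    scores: np.ndarray
    positives: set

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_ids.size != self.scores.size:
            raise InputError("gene_ids and scores must have equal length")
        if np.any(np.diff(self.scores) > 0):
            raise InputError("scores must be non-increasing along the ranking")
        self.positives = {str(g) for g in self.positives}
        extra = self.positives - set(self.gene_ids.tolist())
        if extra:
            raise InputError(f"positives not present in ranking: {sorted(extra)[:10]}")

    @property
    def labels(self) -> np.ndarray:
        return np.isin(self.gene_ids, sorted(self.positives)).astype(int)


def _check_both_classes(r: LabeledRanking) -> np.ndarray:
    y = r.labels
    if y.all() or not y.any():
        raise InputError("ROC needs at least one positive and one negative gene")
    return y


def roc_curve(r: LabeledRanking) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the ROC sweep; tied scores form a single step."""
    y = _check_both_classes(r)
    fpr, tpr, _ = metrics.roc_curve(y, r.scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def auc(r: LabeledRanking) -> float:
    """Trapezoidal area under the ROC curve (= Mann-Whitney probability)."""
    y = _check_both_classes(r)
    return float(metrics.roc_auc_score(y, r.scores))


def evaluate_ranking(
    gene_ids: Sequence[str],
    scores: Sequence[float],
    positives: Iterable[str],
    exclude: Iterable[str] | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """AUC and ROC points for a ranking, optionally excluding genes (e.g. the
    knowledge genes used to train the ranking) from scoring."""
    ids = np.asarray(gene_ids, dtype=str)
    sc = np.asarray(scores, dtype=float)
    if exclude is not None:
        drop = {str(g) for g in exclude}
        keep = ~np.isin(ids, sorted(drop))
        ids, sc = ids[keep], sc[keep]
    pos = {str(g) for g in positives} & set(ids.tolist())
    if not pos:
        raise InputError("no positives remain after exclusion/matching")
    r = LabeledRanking(ids, sc, pos)
    return auc(r), roc_curve(r)
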