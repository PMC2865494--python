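"""Bootstrap-aggregated COCA: resampled background masks, sign correction,
replicate aggregation and the final gene ranking.

A knowledge set of a few hundred genes faces thousands of background genes;
fitting one direction against the full background overfits.  Each bootstrap
replicate instead draws (with replacement) a background multiset of about the
knowledge set's size, fits a direction on that balanced subproblem, resolves
the inherent +/- sign ambiguity of a linear component, and projects the FULL
matrix so every gene receives a participation value.  The bagged mean over
replicates is what gets ranked, by absolute value, descending.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .data import ExpressionMatrix, KnowledgeMask, participation

__all__ = [
    "BootstrapPlan",
    "ParticipationResult",
    "make_bootstrap_mask",
    "correct_ambiguity",
    "rank_order",
    "run_coca",
]


@dataclass
class BootstrapPlan:
    """How to resample the background: B replicates of ``per_boot_background``
    draws (with replacement) from ``background_pool``.

    ``background_pool`` of None means all non-knowledge genes;
    ``per_boot_background`` of None means a background of the knowledge set's
    own size — the balanced comparison that motivates bootstrapping.
    """

    n_boot: int = 100
    background_pool: Sequence[str] | None = None
    per_boot_background: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise InputError("n_boot must be >= 1")
        if self.per_boot_background is not None and self.per_boot_background < 2:
            raise InputError("per_boot_background must be >= 2")


def make_bootstrap_mask(
    gene_ids: Sequence[str],
    knowledge: Iterable[str],
    pool: Iterable[str],
    size: int,
    rng: np.random.Generator,
) -> KnowledgeMask:
    """One replicate's mask: the full knowledge set as positives (never
    resampled) and ``size`` with-replacement draws from ``pool`` as negatives,
    duplicates collapsing to integer weights.

    Draws are made over the id-sorted pool so the result depends only on the
    gene identities, not on their row order.
    """
    gene_ids = np.asarray(gene_ids, dtype=str)
    know = {str(g) for g in knowledge}
    pool_ids = np.array(sorted({str(g) for g in pool} - know), dtype=str)
    if pool_ids.size == 0:
        raise InputError("background pool is empty")
    if size < 1:
        raise InputError("background sample size must be >= 1")
    draws = rng.integers(0, pool_ids.size, size=size)
    uniq, counts = np.unique(draws, return_counts=True)
    neg = np.zeros(len(gene_ids))
    lookup = {g: i for i, g in enumerate(gene_ids)}
    for u, c in zip(pool_ids[uniq], counts):
        if u not in lookup:
            raise InputError(f"pool gene {u!r} not present in matrix")
        neg[lookup[u]] = c
    pos = np.isin(gene_ids, list(know)).astype(float)
    return KnowledgeMask(pos, neg)


def correct_ambiguity(w_raw: np.ndarray, x, knowledge) -> np.ndarray:
    """Resolve the sign indeterminacy of a linear component.

    The direction is flipped when the mean participation of the knowledge
    genes is negative, so knowledge genes always project positively on
    average; the rule is idempotent.  ``knowledge`` may be gene ids (with an
    ExpressionMatrix) or row indices (with a plain array).
    """
    w_raw = np.asarray(w_raw, dtype=float)
    if not np.any(w_raw):
        raise InputError("cannot sign-correct a zero direction")
    if isinstance(x, ExpressionMatrix):
        idx = x.gene_indices(knowledge)
        values = x.values
    else:
        values = np.asarray(x, dtype=float)
        idx = np.asarray(list(knowledge), dtype=int)
    mean_part = float((values[idx] @ w_raw).mean())
    if mean_part < 0:
        return -w_raw
    if mean_part == 0:
        warnings.warn(
            "knowledge-gene mean participation is exactly zero; keeping sign",
            RuntimeWarning,
            stacklevel=2,
        )
    return w_raw


def rank_order(scores: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices ordering genes by score descending, ties by gene id ascending."""
    gene_ids = np.asarray(gene_ids, dtype=str)
    return np.lexsort((gene_ids, -np.asarray(scores, dtype=float)))


@dataclass
class ParticipationResult:
    """Bagged participation values, per-replicate estimates and the ranking."""

    gene_ids: np.ndarray
    a_bagged: np.ndarray
    a_replicates: np.ndarray  # B x N
    w_replicates: np.ndarray  # B x M, sign-corrected
    ranking: np.ndarray  # gene ids, descending |a_bagged|
    a_sd: np.ndarray = field(default=None)  # type: ignore[assignment]
    objectives: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_boot(self) -> int:
        return self.a_replicates.shape[0]

    def to_frame(self, method: str = "coca") -> pd.DataFrame:
        order = rank_order(np.abs(self.a_bagged), self.gene_ids)
        sd = self.a_sd if self.a_sd is not None else np.zeros_like(self.a_bagged)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "gene_id": self.gene_ids[order],
                "participation_bagged": self.a_bagged[order],
                "abs_participation": np.abs(self.a_bagged[order]),
                "participation_sd": sd[order],
                "method": method,
            }
        )


def run_coca(
    x: ExpressionMatrix,
    knowledge: Iterable[str],
    plan: BootstrapPlan | None = None,
    cfg=None,
    p: int = 1,
    center: bool = True,
    scale: bool = False,
    aggregate: str = "mean",
) -> ParticipationResult:
    """Bagged COCA over an expression matrix and a knowledge gene-id set.

    Thin wrapper over :class:`coca.estimators.CocaRanker`; unmatched knowledge
    ids are logged and dropped, and fewer than two matches is an error.
    """
    from .estimators import CocaRanker  # local import breaks the module cycle
    from .spsa import SpsaConfig

    plan = plan or BootstrapPlan()
    cfg = cfg or SpsaConfig()
    know = {str(g) for g in knowledge}
    present = set(x.gene_ids.tolist())
    matched = sorted(know & present)
    unmatched = sorted(know - present)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} knowledge ids not found and dropped: {unmatched[:10]}"
            + (" ..." if len(unmatched) > 10 else ""),
            RuntimeWarning,
            stacklevel=2,
        )
    if len(matched) < 2:
        raise InputError(
            f"fewer than 2 knowledge genes matched the matrix; unmatched ids: {unmatched}"
        )
    y = np.isin(x.gene_ids, matched).astype(int)
    if plan.background_pool is not None:
        pool = {str(g) for g in plan.background_pool} - set(matched)
        in_pool = np.isin(x.gene_ids, sorted(pool))
        y[(y == 0) & ~in_pool] = -1
    est = CocaRanker(
        n_boot=plan.n_boot,
        background_size=plan.per_boot_background or "auto",
        p=p,
        center=center,
        scale=scale,
        aggregate=aggregate,
        max_iter=cfg.max_iter,
        a0=cfg.a0,
        c0=cfg.c0,
        alpha=cfg.alpha,
        gamma=cfg.gamma,
        tol=cfg.tol,
        patience=cfg.patience,
        restarts=cfg.restarts,
        random_state=plan.seed if plan.seed is not None else cfg.seed,
    )
    est.fit(x.values, y, gene_ids=x.gene_ids)
    return est.to_result()
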