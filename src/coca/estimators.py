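"""Scikit-learn-style gene rankers.

Rows are genes (the objects being ranked) and columns are array samples, so
``fit(X, y)`` receives a genes x samples matrix with per-gene labels:
``y == 1`` marks knowledge genes, ``y == 0`` background-pool candidates and
``y == -1`` genes excluded from the pool but still ranked.  Two-condition
baselines take per-column condition labels through the ``sample_labels`` fit
parameter.

All rankers expose ``scores_`` (higher = stronger evidence), ``ranking_``
(gene ids, score-descending, ties broken by gene id ascending) and
``ranking_idx_`` after fitting.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._exceptions import InputError, NumericalError
from .bagging import ParticipationResult, correct_ambiguity, rank_order
from .data import KnowledgeMask, preprocess
from .spsa import SpsaConfig, optimize_direction

__all__ = [
    "CocaRanker",
    "DifferentialCocaRanker",
    "VarianceRanker",
    "FoldChangeRanker",
    "SamRanker",
    "PcaGuidedRanker",
]


def _gene_ids_for(X, gene_ids, n: int) -> np.ndarray:
    if gene_ids is not None:
        ids = np.asarray(gene_ids, dtype=str)
        if ids.size != n:
            raise InputError(f"gene_ids has length {ids.size}, expected {n}")
        return ids
    if hasattr(X, "index"):
        return np.asarray(X.index, dtype=str)
    width = len(str(max(n - 1, 1)))
    return np.array([f"g{i:0{width}d}" for i in range(n)], dtype=str)


class _RankerMixin:
    """Shared ranking bookkeeping for all gene rankers."""

    def _finalize(self, scores: np.ndarray, gene_ids: np.ndarray) -> None:
        self.scores_ = np.asarray(scores, dtype=float)
        self.gene_ids_ = gene_ids
        self.ranking_idx_ = rank_order(self.scores_, gene_ids)
        self.ranking_ = gene_ids[self.ranking_idx_]

    def _validate(self, X, min_samples: int = 2):
        arr = check_array(X, dtype=float, ensure_min_samples=2,
                          ensure_min_features=min_samples)
        return arr


def _condition_split(sample_labels, m: int):
    if sample_labels is None:
        raise InputError("sample_labels (per-column condition labels) are required")
    labels = np.asarray(sample_labels)
    if labels.size != m:
        raise InputError(f"sample_labels has length {labels.size}, expected {m}")
    levels = np.unique(labels)
    if levels.size != 2:
        raise InputError(f"need exactly 2 conditions, got {levels.tolist()}")
    g1 = labels == levels[0]
    g2 = labels == levels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise InputError("each condition needs at least 2 samples")
    return g1, g2, levels


class CocaRanker(_RankerMixin, BaseEstimator):
    """Bootstrap-aggregated coordinative component analysis.

    Learns, per bootstrap replicate, a unit direction in sample space that
    maximizes the ratio of knowledge-gene to background-gene projection
    amplitudes, then ranks every gene by the absolute bagged projection.

    Parameters
    ----------
    n_boot : number of bootstrap replicates B.
    background_size : background draws per replicate; "auto" uses the
        knowledge-set size (the balanced comparison).
    pool_size : optional random subsample size for the background pool.
    p : norm order of the objective (1 or 2); 1 is the outlier-robust default.
    center, scale : row-wise preprocessing flags.
    aggregate : "mean" (default) or "median" aggregation over replicates.
    max_iter, a0, c0, alpha, gamma, tol, patience, restarts :
        simultaneous-perturbation optimizer settings (see SpsaConfig).
    random_state : master seed; replicate b runs on the deterministic
        substream keyed by (seed, b), so aggregation is order-independent and
        replicates are parallelizable in principle.
    """

    def __init__(
        self,
        n_boot: int = 100,
        background_size="auto",
        pool_size: int | None = None,
        p: int = 1,
        center: bool = True,
        scale: bool = False,
        aggregate: str = "mean",
        max_iter: int = 500,
        a0: float = 0.1,
        c0: float = 0.05,
        alpha: float = 0.602,
        gamma: float = 0.101,
        tol: float = 1e-6,
        patience: int = 20,
        restarts: int = 4,
        random_state: int | None = None,
    ):
        self.n_boot = n_boot
        self.background_size = background_size
        self.pool_size = pool_size
        self.p = p
        self.center = center
        self.scale = scale
        self.aggregate = aggregate
        self.max_iter = max_iter
        self.a0 = a0
        self.c0 = c0
        self.alpha = alpha
        self.gamma = gamma
        self.tol = tol
        self.patience = patience
        self.restarts = restarts
        self.random_state = random_state

    def _spsa_config(self) -> SpsaConfig:
        return SpsaConfig(
            max_iter=self.max_iter, a0=self.a0, c0=self.c0, alpha=self.alpha,
            gamma=self.gamma, tol=self.tol, patience=self.patience,
            restarts=self.restarts,
        )

    def fit(self, X, y, gene_ids=None):
        Xv = self._validate(X)
        n, m = Xv.shape
        ids = _gene_ids_for(X, gene_ids, n)
        y = np.asarray(y)
        if y.size != n:
            raise InputError(f"y has length {y.size}, expected {n} (one label per gene)")
        if self.n_boot < 1:
            raise InputError("n_boot must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise InputError("aggregate must be 'mean' or 'median'")
        know_idx = np.flatnonzero(y == 1)
        if know_idx.size < 2:
            raise InputError(f"need >= 2 knowledge genes, got {know_idx.size}")
        pool_idx = np.flatnonzero(y == 0)
        if pool_idx.size == 0:
            raise InputError("background pool is empty (no genes labeled 0)")

        master = self.random_state
        if master is None:
            master = int(np.random.SeedSequence().entropy % (2**31))
        self.master_seed_ = int(master)

        Xc = preprocess(Xv, center=self.center, scale=self.scale)

        # canonical (id-sorted) orders make the fit independent of row order
        know_sorted = know_idx[np.argsort(ids[know_idx])]
        pool_sorted = pool_idx[np.argsort(ids[pool_idx])]
        if self.pool_size is not None and self.pool_size < pool_sorted.size:
            rng = np.random.default_rng(np.random.SeedSequence((self.master_seed_, 1 << 20)))
            keep = np.sort(rng.choice(pool_sorted.size, self.pool_size, replace=False))
            pool_sorted = pool_sorted[keep]
        self.pool_idx_ = pool_sorted

        nk = know_sorted.size
        size = nk if self.background_size == "auto" else int(self.background_size)
        if size < 2:
            raise InputError("background_size must be >= 2")

        cfg = self._spsa_config()
        B = self.n_boot
        directions = np.empty((B, m))
        a_reps = np.empty((B, n))
        objectives = np.empty(B)
        know_block = Xc[know_sorted]
        for b in range(B):
            ss = np.random.SeedSequence((self.master_seed_, b))
            draw_ss, opt_ss = ss.spawn(2)
            rng = np.random.default_rng(draw_ss)
            draws = rng.integers(0, pool_sorted.size, size=size)
            uniq, counts = np.unique(draws, return_counts=True)
            bg_rows = pool_sorted[uniq]
            sub = np.vstack([know_block, Xc[bg_rows]])
            mask = KnowledgeMask(
                np.concatenate([np.ones(nk), np.zeros(uniq.size)]),
                np.concatenate([np.zeros(nk), counts.astype(float)]),
            )
            d = optimize_direction(sub, mask, cfg, p=self.p, seed_sequence=opt_ss)
            w = correct_ambiguity(d.w, Xc, know_sorted)
            directions[b] = w
            objectives[b] = d.objective
            a_reps[b] = Xc @ w

        self.directions_ = directions
        self.objectives_ = objectives
        self.participation_replicates_ = a_reps
        if self.aggregate == "mean":
            a_bag = a_reps.mean(axis=0)
        else:
            a_bag = np.median(a_reps, axis=0)
        self.participation_ = a_bag
        self.participation_sd_ = (
            a_reps.std(axis=0, ddof=1) if B > 1 else np.zeros(n)
        )
        self.knowledge_idx_ = know_sorted
        self.n_features_in_ = m
        self._finalize(np.abs(a_bag), ids)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed participation of new genes along the mean bagged direction."""
        check_is_fitted(self, "directions_")
        Xv = check_array(X, dtype=float)
        if Xv.shape[1] != self.n_features_in_:
            raise InputError(
                f"X has {Xv.shape[1]} samples, expected {self.n_features_in_}"
            )
        return preprocess(Xv, center=self.center, scale=self.scale) @ self.directions_.mean(axis=0)

    def transform(self, X) -> np.ndarray:
        return self.decision_function(X).reshape(-1, 1)

    def to_result(self) -> ParticipationResult:
        check_is_fitted(self, "directions_")
        return ParticipationResult(
            gene_ids=self.gene_ids_,
            a_bagged=self.participation_,
            a_replicates=self.participation_replicates_,
            w_replicates=self.directions_,
            ranking=self.ranking_,
            a_sd=self.participation_sd_,
            objectives=self.objectives_,
        )


class DifferentialCocaRanker(_RankerMixin, BaseEstimator):
    """Two-condition COCA: rank genes by the change in their participation.

    Fits one bagged COCA model per condition with the same knowledge genes,
    normalizes each condition's bagged participation by the mean knowledge-gene
    participation (knowledge genes calibrate the per-condition scale, which
    otherwise depends on the realized latent amplitude along the learned
    direction), and scores each gene by the absolute normalized difference.
    Genes whose process involvement was switched off in one condition score
    high; genes with unchanged involvement cancel.
    """

    def __init__(self, **coca_params):
        self.coca_params = coca_params

    def get_params(self, deep=True):
        return {"coca_params": self.coca_params}

    def set_params(self, **params):
        if "coca_params" in params:
            self.coca_params = params.pop("coca_params")
        self.coca_params = {**self.coca_params, **params}
        return self

    @staticmethod
    def _knowledge_scale(a: np.ndarray, know_idx: np.ndarray) -> float:
        scale = float(a[know_idx].mean())
        if scale <= 0:
            scale = float(np.abs(a[know_idx]).mean())
        if scale == 0:
            raise NumericalError("knowledge genes have zero mean participation")
        return scale

    def fit(self, X, y, gene_ids=None, sample_labels=None):
        Xv = self._validate(X, min_samples=4)
        n, m = Xv.shape
        ids = _gene_ids_for(X, gene_ids, n)
        g1, g2, levels = _condition_split(sample_labels, m)
        params = dict(self.coca_params)
        master = params.pop("random_state", None)
        if master is None:
            master = int(np.random.SeedSequence().entropy % (2**31))
        fitted = []
        for k, g in enumerate((g1, g2)):
            sub_seed = int(
                np.random.SeedSequence((int(master), 1000 + k)).generate_state(1)[0]
                % (2**31)
            )
            est = CocaRanker(random_state=sub_seed, **params)
            est.fit(Xv[:, g], y, gene_ids=ids)
            fitted.append(est)
        self.coca_cond1_, self.coca_cond2_ = fitted
        self.condition_levels_ = levels
        know_idx = self.coca_cond1_.knowledge_idx_
        a1 = self.coca_cond1_.participation_
        a2 = self.coca_cond2_.participation_
        diff = a1 / self._knowledge_scale(a1, know_idx) - a2 / self._knowledge_scale(
            a2, know_idx
        )
        self.participation_change_ = diff
        self.n_features_in_ = m
        self._finalize(np.abs(diff), ids)
        return self


class VarianceRanker(_RankerMixin, BaseEstimator):
    """Unsupervised baseline: rank genes by unbiased sample variance."""

    def fit(self, X, y=None, gene_ids=None):
        Xv = self._validate(X)
        ids = _gene_ids_for(X, gene_ids, Xv.shape[0])
        self.variances_ = Xv.var(axis=1, ddof=1)
        self.n_features_in_ = Xv.shape[1]
        self._finalize(self.variances_, ids)
        return self


class FoldChangeRanker(_RankerMixin, BaseEstimator):
    """Two-condition baseline: absolute difference of condition means
    (a log-scale fold change on additively scaled data)."""

    def fit(self, X, y=None, gene_ids=None, sample_labels=None):
        Xv = self._validate(X, min_samples=4)
        ids = _gene_ids_for(X, gene_ids, Xv.shape[0])
        g1, g2, levels = _condition_split(sample_labels, Xv.shape[1])
        self.condition_levels_ = levels
        self.fold_change_ = Xv[:, g2].mean(axis=1) - Xv[:, g1].mean(axis=1)
        self.n_features_in_ = Xv.shape[1]
        self._finalize(np.abs(self.fold_change_), ids)
        return self


class SamRanker(_RankerMixin, BaseEstimator):
    """SAM-style modified t statistic: d_j = (m2 - m1) / (s_j + s0).

    s_j is the pooled standard error of the mean difference and s0 a
    variance-stabilizing offset, by default the median of the s_j (the
    original percentile search is deliberately not reproduced).
    """

    def __init__(self, s0: float | None = None):
        self.s0 = s0

    def fit(self, X, y=None, gene_ids=None, sample_labels=None):
        Xv = self._validate(X, min_samples=4)
        ids = _gene_ids_for(X, gene_ids, Xv.shape[0])
        g1, g2, levels = _condition_split(sample_labels, Xv.shape[1])
        self.condition_levels_ = levels
        x1, x2 = Xv[:, g1], Xv[:, g2]
        n1, n2 = x1.shape[1], x2.shape[1]
        diff = x2.mean(axis=1) - x1.mean(axis=1)
        ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (x2 - x2.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        pooled_var = ss / (n1 + n2 - 2)
        s = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
        s0 = float(np.median(s)) if self.s0 is None else float(self.s0)
        denom = s + s0
        if np.all(denom == 0):
            raise NumericalError(
                "all genes have zero variance and s0 = 0; SAM statistic undefined"
            )
        d = np.zeros_like(diff)
        np.divide(diff, denom, out=d, where=denom > 0)
        self.s_ = s
        self.s0_ = s0
        self.d_ = d
        self.n_features_in_ = Xv.shape[1]
        self._finalize(np.abs(d), ids)
        return self


class PcaGuidedRanker(_RankerMixin, BaseEstimator):
    """Knowledge-guided PCA baseline.

    Takes the first principal component (first right-singular direction) of
    the row-centered knowledge-gene submatrix as a length-M reference profile
    and ranks every gene by the absolute Pearson correlation of its expression
    profile with it.
    """

    def fit(self, X, y=None, gene_ids=None):
        Xv = self._validate(X)
        n, m = Xv.shape
        ids = _gene_ids_for(X, gene_ids, n)
        if y is None:
            raise InputError("PcaGuidedRanker needs y (1 = knowledge gene)")
        y = np.asarray(y)
        know_idx = np.flatnonzero(y == 1)
        if know_idx.size < 2:
            raise InputError(f"need >= 2 knowledge genes, got {know_idx.size}")
        sub = Xv[know_idx]
        subc = sub - sub.mean(axis=1, keepdims=True)
        if not np.any(subc):
            raise NumericalError("knowledge submatrix has rank 0 (all rows constant)")
        _, _, vt = np.linalg.svd(subc, full_matrices=False)
        comp = vt[0]
        mean_profile = subc.mean(axis=0)
        if float(mean_profile @ comp) < 0:  # sign fixed toward the knowledge centroid
            comp = -comp
        compc = comp - comp.mean()
        Xcent = Xv - Xv.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Xcent, axis=1) * np.linalg.norm(compc)
        corr = np.zeros(n)
        np.divide(Xcent @ compc, denom, out=corr, where=denom > 0)
        self.component_ = comp
        self.correlations_ = corr
        self.knowledge_idx_ = know_idx
        self.n_features_in_ = m
        self._finalize(np.abs(corr), ids)
        return self
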