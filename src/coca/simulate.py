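"""Synthetic expression data from the linear latent model X = A T + E.

A (genes x processes) holds participation strengths, T (processes x samples)
latent process activities, E i.i.d. Gaussian noise whose variance is set to
hit a requested signal-to-noise ratio in dB.  Each process regulates a
contiguous block of genes (blocks overlap by a small fraction so genes can
serve several processes); loadings are half-normal — participation is a
non-negative strength — and activities are standard normal.

Two designs mirror the two benchmark settings:

* one condition — knowledge genes are a random subset of the "ground truth"
  genes (the top-|truth| loadings of process 1), and the task is to recover
  the rest of the ground truth;
* two conditions — 100 genes regulated by process 1 in condition 1 have that
  participation switched off in condition 2; those are the ground truth.
  Knowledge genes come from the *unchanged* part of the process-1 support,
  never overlapping the ground truth.  The latent activities are shared
  between conditions (the eliminated participations are the only systematic
  difference); the noise is drawn independently per condition.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .data import ExpressionMatrix

__all__ = [
    "SimulationDesign",
    "SimulationTruth",
    "one_condition_design",
    "two_condition_design",
    "simulate_one_condition",
    "simulate_two_condition",
    "detection_accuracy",
    "snr_sweep",
    "rank_one_fixture",
    "BENCHMARK_COCA_PARAMS",
]

# moderate optimizer effort for repeated benchmark fits
BENCHMARK_COCA_PARAMS: dict = dict(
    n_boot=20, max_iter=300, restarts=2, tol=1e-5, patience=15
)


@dataclass
class SimulationDesign:
    """Sizes and noise level of a simulated study."""

    n_genes: int = 5000
    n_samples: int = 8
    n_processes: int = 5
    n_knowledge: int = 50
    n_ground_truth: int = 200
    design: str = "one_condition"
    snr_db: float | None = 10.0
    block_overlap: float = 0.1

    def __post_init__(self) -> None:
        if self.design not in ("one_condition", "two_condition"):
            raise InputError(f"unknown design {self.design!r}")
        for name in ("n_genes", "n_samples", "n_processes", "n_knowledge", "n_ground_truth"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            self.snr_db = None  # +inf means noiseless
        if not (0 <= self.block_overlap < 1):
            raise InputError("block_overlap must be in [0, 1)")


def one_condition_design(**overrides) -> SimulationDesign:
    return replace(SimulationDesign(design="one_condition"), **overrides)


def two_condition_design(**overrides) -> SimulationDesign:
    base = SimulationDesign(
        design="two_condition", n_genes=10000, n_samples=20, n_ground_truth=100
    )
    return replace(base, **overrides)


@dataclass
class SimulationTruth:
    """Generating quantities kept for scoring and diagnostics."""

    a_true: np.ndarray  # N x L (condition 1 in the two-condition design)
    t_true: np.ndarray  # L x M
    ground_truth_genes: set
    knowledge_genes: set
    snr_db: float | None
    seed: int | None = None
    a_true_cond2: np.ndarray | None = None
    signal: np.ndarray | tuple = None  # type: ignore[assignment]
    noise: np.ndarray | tuple = None  # type: ignore[assignment]

    def realized_snr_db(self) -> float | tuple[float, ...]:
        def one(sig, noi):
            return 10.0 * np.log10(np.var(sig) / np.var(noi))

        if isinstance(self.signal, tuple):
            return tuple(one(s, n) for s, n in zip(self.signal, self.noise))
        return one(self.signal, self.noise)


def _gene_ids(n: int) -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"g{i:0{width}d}" for i in range(n)], dtype=str)


def _sample_ids(m: int, prefix: str = "s") -> np.ndarray:
    width = len(str(m - 1))
    return np.array([f"{prefix}{j:0{width}d}" for j in range(m)], dtype=str)


def _block_loadings(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Half-normal loadings on overlapping contiguous blocks, one per process."""
    n, L = design.n_genes, design.n_processes
    base = n // L
    if base < 2:
        raise InputError("n_genes too small for the number of processes")
    extra = int(round(design.block_overlap * base))
    a = np.zeros((n, L))
    for i in range(L):
        block = (np.arange(i * base, i * base + base + extra)) % n
        a[block, i] = np.abs(rng.standard_normal(block.size))
    return a


def _noise_for(signal: np.ndarray, snr_db: float | None, rng: np.random.Generator) -> np.ndarray:
    if snr_db is None:
        return np.zeros_like(signal)
    var_sig = float(np.var(signal))
    if var_sig == 0:
        raise InputError("signal has zero variance; cannot set an SNR")
    sigma = np.sqrt(var_sig / 10.0 ** (snr_db / 10.0))
    return rng.normal(0.0, sigma, size=signal.shape)


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_one_condition(
    design: SimulationDesign | None = None, rng=None
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """One-condition dataset; knowledge genes are a random subset of the
    ground truth (the top-|truth| loadings of process 1)."""
    design = design or one_condition_design()
    if design.design != "one_condition":
        raise InputError("design.design must be 'one_condition'")
    rng = _as_rng(rng)
    ids = _gene_ids(design.n_genes)
    a = _block_loadings(design, rng)
    t = rng.standard_normal((design.n_processes, design.n_samples))
    signal = a @ t
    noise = _noise_for(signal, design.snr_db, rng)
    x = ExpressionMatrix(signal + noise, ids, _sample_ids(design.n_samples))

    order = np.lexsort((ids, -np.abs(a[:, 0])))
    truth_idx = order[: design.n_ground_truth]
    know_idx = rng.choice(truth_idx, size=design.n_knowledge, replace=False)
    truth = SimulationTruth(
        a_true=a,
        t_true=t,
        ground_truth_genes=set(ids[truth_idx].tolist()),
        knowledge_genes=set(ids[know_idx].tolist()),
        snr_db=design.snr_db,
        signal=signal,
        noise=noise,
    )
    return x, truth


def simulate_two_condition(
    design: SimulationDesign | None = None, rng=None
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Two-condition dataset; the ground truth is 100 (by default) process-1
    participations present in condition 1 and eliminated in condition 2."""
    design = design or two_condition_design()
    if design.design != "two_condition":
        raise InputError("design.design must be 'two_condition'")
    rng = _as_rng(rng)
    ids = _gene_ids(design.n_genes)
    a1 = _block_loadings(design, rng)
    support = np.flatnonzero(a1[:, 0] != 0)
    if support.size < design.n_ground_truth + design.n_knowledge:
        raise InputError(
            f"process-1 support ({support.size}) smaller than ground truth + knowledge "
            f"({design.n_ground_truth + design.n_knowledge})"
        )
    truth_idx = rng.choice(support, size=design.n_ground_truth, replace=False)
    a2 = a1.copy()
    a2[truth_idx, 0] = 0.0
    remaining = np.setdiff1d(support, truth_idx)
    know_idx = rng.choice(remaining, size=design.n_knowledge, replace=False)

    # latent activities shared between conditions: the eliminated
    # participations are the only systematic difference
    t = rng.standard_normal((design.n_processes, design.n_samples))
    sig1, sig2 = a1 @ t, a2 @ t
    noi1 = _noise_for(sig1, design.snr_db, rng)
    noi2 = _noise_for(sig2, design.snr_db, rng)
    x1 = ExpressionMatrix(sig1 + noi1, ids, _sample_ids(design.n_samples, "c1s"))
    x2 = ExpressionMatrix(sig2 + noi2, ids, _sample_ids(design.n_samples, "c2s"))
    truth = SimulationTruth(
        a_true=a1,
        t_true=t,
        ground_truth_genes=set(ids[truth_idx].tolist()),
        knowledge_genes=set(ids[know_idx].tolist()),
        snr_db=design.snr_db,
        a_true_cond2=a2,
        signal=(sig1, sig2),
        noise=(noi1, noi2),
    )
    return x1, x2, truth


def detection_accuracy(ranking: Sequence[str], truth: Iterable[str]) -> float:
    """Fraction of ground-truth genes among the top-|truth| ranked genes."""
    truth_set = {str(g) for g in truth}
    if not truth_set:
        raise InputError("truth set is empty")
    ranking = [str(g) for g in ranking]
    missing = truth_set - set(ranking)
    if missing:
        raise InputError(f"truth genes absent from ranking: {sorted(missing)[:10]}")
    k = len(truth_set)
    return len(set(ranking[:k]) & truth_set) / k


def _method_ranking(
    method: str,
    design: SimulationDesign,
    data,
    truth: SimulationTruth,
    seed: int,
    coca_params: dict,
):
    from .estimators import (
        CocaRanker,
        DifferentialCocaRanker,
        FoldChangeRanker,
        PcaGuidedRanker,
        SamRanker,
        VarianceRanker,
    )

    if design.design == "one_condition":
        x = data
        y = np.isin(x.gene_ids, sorted(truth.knowledge_genes)).astype(int)
        if method == "coca":
            est = CocaRanker(random_state=seed, **coca_params)
            return est.fit(x.values, y, gene_ids=x.gene_ids).ranking_
        if method == "vr":
            return VarianceRanker().fit(x.values, gene_ids=x.gene_ids).ranking_
        if method == "pca":
            return PcaGuidedRanker().fit(x.values, y, gene_ids=x.gene_ids).ranking_
        raise InputError(f"method {method!r} needs two conditions or is unknown")

    x1, x2 = data
    values = np.hstack([x1.values, x2.values])
    labels = np.array([0] * x1.n_samples + [1] * x2.n_samples)
    ids = x1.gene_ids
    y = np.isin(ids, sorted(truth.knowledge_genes)).astype(int)
    if method == "coca":
        est = DifferentialCocaRanker(random_state=seed, **coca_params)
        return est.fit(values, y, gene_ids=ids, sample_labels=labels).ranking_
    if method == "fc":
        return FoldChangeRanker().fit(values, gene_ids=ids, sample_labels=labels).ranking_
    if method == "sam":
        return SamRanker().fit(values, gene_ids=ids, sample_labels=labels).ranking_
    if method == "vr":
        return VarianceRanker().fit(values, gene_ids=ids).ranking_
    if method == "pca":
        return PcaGuidedRanker().fit(values, y, gene_ids=ids).ranking_
    raise InputError(f"unknown method {method!r}")


def snr_sweep(
    design: SimulationDesign,
    methods: Sequence[str],
    snr_grid: Sequence[float],
    reps: int = 3,
    seed: int | None = None,
    coca_params: dict | None = None,
) -> pd.DataFrame:
    """Detection accuracy of each method on fresh simulations across an SNR
    grid; long-format table (method, snr_db, rep, accuracy)."""
    if reps < 1:
        raise InputError("reps must be >= 1")
    if coca_params is None:
        coca_params = BENCHMARK_COCA_PARAMS
    root = 0 if seed is None else int(seed)
    rows = []
    for si, snr in enumerate(snr_grid):
        d = replace(design, snr_db=float(snr))
        for rep in range(reps):
            ss = np.random.SeedSequence((root, si, rep))
            sim_ss, fit_ss = ss.spawn(2)
            if design.design == "one_condition":
                data, truth = simulate_one_condition(d, np.random.default_rng(sim_ss))
            else:
                x1, x2, truth = simulate_two_condition(d, np.random.default_rng(sim_ss))
                data = (x1, x2)
            fit_seed = int(fit_ss.generate_state(1)[0] % (2**31))
            for method in methods:
                try:
                    ranking = _method_ranking(method, d, data, truth, fit_seed, coca_params)
                    acc = detection_accuracy(ranking, truth.ground_truth_genes)
                except Exception as exc:  # tag origin, then re-raise
                    raise type(exc)(f"(snr={snr}, rep={rep}, method={method}) {exc}") from exc
                rows.append(
                    {"method": method, "snr_db": float(snr), "rep": rep, "accuracy": acc}
                )
    return pd.DataFrame(rows)


def rank_one_fixture(
    n_pos: int = 60,
    n_neg: int = 40,
    n_samples: int = 8,
    noise: float = 0.05,
    rng=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Near rank-one recovery fixture.

    Positive genes follow a shared latent profile t with strong positive
    loadings; negative genes have zero loading on t — low-amplitude noise
    confined to the orthogonal complement of t — so the coordinative ratio
    is maximized exactly at the direction t.
    Returns (values, y, t, loadings) with y the knowledge indicator.
    """
    rng = _as_rng(rng)
    t = rng.standard_normal(n_samples)
    t /= np.linalg.norm(t)
    a = np.zeros(n_pos + n_neg)
    a[:n_pos] = rng.uniform(1.0, 2.0, size=n_pos)
    x = np.outer(a, t)
    z = noise * rng.standard_normal((n_neg, n_samples))
    x[n_pos:] = z - np.outer(z @ t, t)
    y = np.zeros(n_pos + n_neg, dtype=int)
    y[:n_pos] = 1
    return x, y, t, a
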