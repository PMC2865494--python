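"""Simultaneous-perturbation stochastic ascent on the unit sphere.

The objective has no convenient analytic gradient (it involves absolute
values of projections), so the gradient is estimated from exactly two
function evaluations per step: perturb the direction by +/- c*s along a
random Rademacher vector s and divide the difference quotient by each
perturbation component.  The stochastic gradient doubles as a means of
escaping shallow local maxima.

Gain schedules follow standard simultaneous-perturbation practice:

    a_n = a0 / (n + 1 + A)^alpha,   c_n = c0 / (n + 1)^gamma

with alpha = 0.602, gamma = 0.101 and stability offset A = 0.1 * max_iter.
The iterate is renormalized to unit length every step (the objective is
scale-invariant, so the sphere is the canonical domain and renormalization
prevents numeric drift).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from ._exceptions import InputError, NumericalError
from .data import ExpressionMatrix, KnowledgeMask
from .objective import make_objective

__all__ = ["SpsaConfig", "CoordinativeDirection", "spsa_gradient", "optimize_direction"]


@dataclass
class SpsaConfig:
    """Optimizer settings; defaults are conventional, not data-derived.

    ``alpha``/``gamma`` are the step-size and perturbation decay exponents
    (0 < gamma < alpha <= 1); ``tol`` is the relative objective improvement
    below which a check counts as stalled, and ``patience`` the number of
    consecutive stalled checks that stops a restart.
    """

    max_iter: int = 500
    a0: float = 0.1
    c0: float = 0.05
    alpha: float = 0.602
    gamma: float = 0.101
    tol: float = 1e-6
    patience: int = 20
    restarts: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise InputError("max_iter must be >= 1")
        if self.a0 <= 0 or self.c0 <= 0:
            raise InputError("a0 and c0 must be positive")
        if not (0 < self.gamma < self.alpha <= 1):
            raise InputError("require 0 < gamma < alpha <= 1")
        if self.tol < 0:
            raise InputError("tol must be >= 0")
        if self.patience < 1 or self.restarts < 1:
            raise InputError("patience and restarts must be >= 1")

    @property
    def stability_offset(self) -> float:
        return 0.1 * self.max_iter

    @classmethod
    def from_file(cls, path: str | Path) -> "SpsaConfig":
        """Load from a flat YAML/INI-style key-value mapping."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {path} must hold a flat key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CoordinativeDirection:
    """A learned unit direction with its objective value and optimizer trace."""

    w: np.ndarray
    objective: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    seed: int | None = None
    restart: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace, columns=["iteration", "objective"])


def spsa_gradient(
    f: Callable[[np.ndarray], float],
    w: np.ndarray,
    c: float,
    s: np.ndarray,
) -> np.ndarray:
    """Two-evaluation simultaneous-perturbation gradient estimate.

    g_k = [f(w + c s) - f(w - c s)] / (2 c s_k) with s a +/-1 vector.
    """
    if c <= 0:
        raise InputError("perturbation magnitude c must be positive")
    s = np.asarray(s, dtype=float)
    if not np.all(np.abs(s) == 1):
        raise InputError("perturbation vector entries must be +/-1")
    w = np.asarray(w, dtype=float)
    f_plus = f(w + c * s)
    f_minus = f(w - c * s)
    if not (np.isfinite(f_plus) and np.isfinite(f_minus)):
        raise NumericalError(
            f"objective non-finite at perturbed point (f+={f_plus}, f-={f_minus}) "
            f"for w={w!r}"
        )
    return (f_plus - f_minus) / (2.0 * c * s)


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise NumericalError("cannot normalize a zero vector")
    return v / nrm


def _warm_start(values: np.ndarray, mask: KnowledgeMask) -> np.ndarray | None:
    """Normalized mean expression profile of the knowledge genes."""
    pos = mask.positive > 0
    centroid = mask.positive[pos] @ values[pos] / mask.positive[pos].sum()
    nrm = np.linalg.norm(centroid)
    return None if nrm == 0 else centroid / nrm


def optimize_direction(
    x,
    mask: KnowledgeMask,
    cfg: SpsaConfig | None = None,
    p: int = 1,
    seed_sequence: np.random.SeedSequence | None = None,
) -> CoordinativeDirection:
    """Maximize the coordinative ratio objective over unit directions.

    Runs ``cfg.restarts`` independent ascents: the first from the knowledge
    centroid warm start, the rest from random unit vectors, each on its own
    deterministic random substream.  Returns the restart with the highest
    objective, reporting the best iterate seen (not silently the last one)
    together with that restart's full (iteration, objective) trace.
    """
    cfg = cfg or SpsaConfig()
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    m = values.shape[1]
    f = make_objective(values, mask, p=p)

    root = seed_sequence if seed_sequence is not None else np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.restarts)
    warm = _warm_start(values, mask)

    best: CoordinativeDirection | None = None
    any_nonzero = False
    init0: np.ndarray | None = None
    offset = cfg.stability_offset
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if r == 0 and warm is not None:
            w = warm.copy()
        else:
            w = _unit(rng.standard_normal(m))
        if init0 is None:
            init0 = w.copy()
        j = f(w)
        trace = [(0, j)]
        best_j, best_w = j, w.copy()
        stall = 0
        for n in range(1, cfg.max_iter + 1):
            c_n = cfg.c0 / n**cfg.gamma
            a_n = cfg.a0 / (n + offset) ** cfg.alpha
            s = rng.integers(0, 2, size=m) * 2.0 - 1.0
            g = spsa_gradient(f, w, c_n, s)
            step = w + a_n * g
            nrm = np.linalg.norm(step)
            if nrm > 0:
                w = step / nrm
            j = f(w)
            trace.append((n, j))
            rel = (j - best_j) / max(abs(best_j), 1e-30)
            if j > best_j:
                best_j, best_w = j, w.copy()
            stall = stall + 1 if rel < cfg.tol else 0
            if stall >= cfg.patience:
                break
        if best_j > 0:
            any_nonzero = True
        cand = CoordinativeDirection(
            w=best_w, objective=best_j, trace=trace, seed=cfg.seed, restart=r
        )
        if best is None or cand.objective > best.objective:
            best = cand

    if not any_nonzero:
        warnings.warn(
            "objective was identically zero for every evaluated direction; "
            "returning the initial direction (degenerate)",
            RuntimeWarning,
            stacklevel=2,
        )
        return CoordinativeDirection(
            w=init0, objective=0.0, trace=[(0, 0.0)], seed=cfg.seed, restart=0,
            degenerate=True,
        )
    assert best is not None
    return best
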