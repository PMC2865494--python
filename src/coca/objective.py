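"""The coordinative ratio objective.

For a direction w the objective is the ratio of masked p-norms of the
per-gene projections a_j = x_j . w:

    J_p(w) = (sum_{j in P} u_j |a_j|^p)^(1/p)
             ---------------------------------------
             (sum_{j in B} v_j |a_j|^p)^(1/p) + eps

with P the knowledge (positive-mask) genes, B the background (negative-mask)
genes, and u, v non-negative mask weights (bootstrap multiplicity on the
background side).  Both numerator and denominator are homogeneous of degree
one in w, so J is invariant to rescaling w; the unit sphere is the canonical
parameterization.  p = 1 is the default: the amplitude form is less affected
by outliers than the energy (p = 2) form.

eps guards against a vanishing denominator.  It is 1e-12 times the weighted
mean |a_j| over all masked genes (floored at 1e-300), which keeps J finite
even when every background projection is zero while preserving exact scale
invariance (eps itself scales linearly with |w|).
"""
from __future__ import annotations

from typing import Callable

import numpy as np

from ._exceptions import InputError
from .data import ExpressionMatrix, KnowledgeMask

__all__ = ["objective_j", "make_objective"]

_EPS_REL = 1e-12
_EPS_FLOOR = 1e-300


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)


def _ratio(absa: np.ndarray, pos: np.ndarray, neg: np.ndarray, p: int) -> float:
    if p == 1:
        ap = absa
    else:
        ap = absa**p
    num = float(pos @ ap) ** (1.0 / p)
    den = float(neg @ ap) ** (1.0 / p)
    wsum = pos.sum() + neg.sum()
    mean_abs = float((pos + neg) @ absa) / wsum
    eps = _EPS_REL * max(mean_abs, _EPS_FLOOR)
    return num / (den + eps)


def objective_j(x, mask: KnowledgeMask, w: np.ndarray, p: int = 1) -> float:
    """Evaluate the masked ratio objective J_p at direction ``w``."""
    if p not in (1, 2):
        raise InputError(f"p must be 1 or 2, got {p!r}")
    values = _values(x)
    if mask.n_genes != values.shape[0]:
        raise InputError(
            f"mask covers {mask.n_genes} genes but matrix has {values.shape[0]}"
        )
    if not (mask.positive > 0).any() or not (mask.negative > 0).any():
        raise InputError("objective needs at least one positive and one negative gene")
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size != values.shape[1]:
        raise InputError(
            f"direction length {w.size} does not match sample count {values.shape[1]}"
        )
    if not np.any(w):
        raise InputError("direction w must be nonzero")
    absa = np.abs(values @ w)
    return _ratio(absa, mask.positive, mask.negative, p)


def make_objective(x, mask: KnowledgeMask, p: int = 1) -> Callable[[np.ndarray], float]:
    """Closure evaluating J_p(w); masked rows are extracted once for speed."""
    if p not in (1, 2):
        raise InputError(f"p must be 1 or 2, got {p!r}")
    values = _values(x)
    if mask.n_genes != values.shape[0]:
        raise InputError(
            f"mask covers {mask.n_genes} genes but matrix has {values.shape[0]}"
        )
    active = (mask.positive > 0) | (mask.negative > 0)
    sub = np.ascontiguousarray(values[active])
    pos = mask.positive[active]
    neg = mask.negative[active]
    if not pos.any() or not neg.any():
        raise InputError("objective needs at least one positive and one negative gene")

    def f(w: np.ndarray) -> float:
        absa = np.abs(sub @ w)
        return _ratio(absa, pos, neg, p)

    return f
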