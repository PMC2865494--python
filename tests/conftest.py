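import numpy as np
import pytest

from coca import ExpressionMatrix, KnowledgeMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """Random 20 x 5 expression matrix with 6 knowledge and 14 background genes."""
    values = rng.standard_normal((20, 5))
    ids = [f"g{i:02d}" for i in range(20)]
    x = ExpressionMatrix(values, ids, [f"s{j}" for j in range(5)])
    y = np.zeros(20, dtype=float)
    y[:6] = 1.0
    mask = KnowledgeMask(y, 1.0 - y)
    return x, mask


def brute_force_objective(values, mask, w, p=1):
    """Independent double-loop evaluation of the masked ratio objective."""
    num = 0.0
    den = 0.0
    total_w = 0.0
    total_abs = 0.0
    n = values.shape[0]
    for j in range(n):
        a_j = 0.0
        for k in range(values.shape[1]):
            a_j += values[j, k] * w[k]
        a_j = abs(a_j)
        if mask.positive[j] > 0:
            num += mask.positive[j] * a_j**p
        if mask.negative[j] > 0:
            den += mask.negative[j] * a_j**p
        weight = mask.positive[j] + mask.negative[j]
        total_w += weight
        total_abs += weight * a_j
    eps = 1e-12 * max(total_abs / total_w, 1e-300)
    return num ** (1.0 / p) / (den ** (1.0 / p) + eps)
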