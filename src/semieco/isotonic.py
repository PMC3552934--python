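"""Weighted isotonic regression of group means under a simple linear order.

Given unconstrained group mean estimates v_1..v_G with positive weights
alpha_1..alpha_G (here: observed sample sizes), the isotonic regression is the
minimizer of sum_g alpha_g * (v_g - mu_g)^2 subject to mu_1 <= ... <= mu_G.
It is computed by the pool-adjacent-violators algorithm (PAVA): scan left to
right, and whenever an adjacent pair violates the order, pool it into a block
carrying the alpha-weighted average, back-merging as needed.  The solution
equals the max-min formula mu*_g = max_{l<=g} min_{j>=g} Av(l, j) over
weighted block averages Av.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np


@dataclass
class IsotonicFit:
    """Result of a weighted isotonic regression.

    ``fitted`` is the nondecreasing projection; ``blocks`` lists the pooled
    index ranges as 0-based inclusive ``(start, end)`` pairs (singletons
    included); ``weights_used`` echoes the weight vector.  Within each block
    the fitted values are equal to the weighted mean of the inputs over the
    block, and the weighted sum is conserved overall.
    """

    fitted: np.ndarray
    blocks: List[Tuple[int, int]]
    weights_used: np.ndarray


def _validated(values: Sequence[float], weights: Sequence[float]):
    v = np.asarray(values, dtype=float)
    a = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != a.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-D of equal length")
    if not np.all(np.isfinite(v)) or not np.all(np.isfinite(a)):
        raise ValueError("non-finite values or weights")
    if np.any(a <= 0):
        raise ValueError("weights must be strictly positive")
    return v, a


def block_average(values: Sequence[float], weights: Sequence[float], i: int, j: int) -> float:
    """Weighted average Av(i, j) of values over the index block i..j inclusive.

    Indices are 0-based.  This is the quantity whose max-min over blocks
    yields the isotonic regression.
    """
    v, a = _validated(values, weights)
    if not (0 <= i <= j < v.size):
        raise ValueError(f"invalid block [{i}, {j}] for length {v.size}")
    sl = slice(i, j + 1)
    return float(np.sum(a[sl] * v[sl]) / np.sum(a[sl]))


def pava(values: Sequence[float], weights: Sequence[float], increasing: bool = True) -> IsotonicFit:
    """Weighted isotonic regression by pool-adjacent-violators.

    Parameters
    ----------
    values, weights
        Group estimates and positive weights (observed sample sizes).
    increasing
        If False, fit a nonincreasing order by negating inputs and outputs.

    Only strict decreases are pooled: ties already satisfy the constraint and
    the least-squares solution leaves them untouched.
    """
    v, a = _validated(values, weights)
    if not increasing:
        inner = pava(-v, a, increasing=True)
        return IsotonicFit(-inner.fitted, inner.blocks, inner.weights_used)

    means: list[float] = []
    wsum: list[float] = []
    start: list[int] = []
    for k in range(v.size):
        means.append(v[k])
        wsum.append(a[k])
        start.append(k)
        while len(means) > 1 and means[-2] > means[-1]:
            m = (means[-2] * wsum[-2] + means[-1] * wsum[-1]) / (wsum[-2] + wsum[-1])
            wsum[-2] += wsum[-1]
            means[-2] = m
            means.pop()
            wsum.pop()
            start.pop()

    fitted = np.empty_like(v)
    blocks: List[Tuple[int, int]] = []
    bounds = start + [v.size]
    for b in range(len(means)):
        lo, hi = bounds[b], bounds[b + 1] - 1
        fitted[lo : hi + 1] = means[b]
        blocks.append((lo, hi))
    return IsotonicFit(fitted=fitted, blocks=blocks, weights_used=a.copy())
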