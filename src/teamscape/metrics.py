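"""Group-level outcome statistics for payoff vectors."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["GroupSummary", "payoff_summary", "gini_coefficient"]


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    max_payoff: float
    mean_payoff: float
    min_payoff: float
    gini: float


def gini_coefficient(payoffs: np.ndarray) -> float:
    """Population Gini: mean absolute pairwise difference over twice the mean.

    G = sum_ij |x_i - x_j| / (2 n^2 xbar), computed via the sorted
    identity; defined as 0 for an all-zero vector. No small-sample
    correction, so G <= (n-1)/n.
    """
    x = np.asarray(payoffs, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("payoffs must be a non-empty 1-D vector")
    if np.any(x < 0):
        raise ValueError("payoffs must be non-negative")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    # sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) x_(i), i 0-based ascending
    weighted = np.sum((2 * np.arange(1, n + 1) - n - 1) * xs)
    # rounding can leave a ~1e-17 negative residue on near-equal vectors
    return max(0.0, float(weighted / (n * total)))


def payoff_summary(payoffs: np.ndarray) -> GroupSummary:
    """Componentwise max/mean/min plus Gini of a payoff vector."""
    x = np.asarray(payoffs, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("payoffs must be a non-empty 1-D vector")
    return GroupSummary(
        max_payoff=float(x.max()),
        mean_payoff=float(x.mean()),
        min_payoff=float(x.min()),
        gini=gini_coefficient(x),
    )
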