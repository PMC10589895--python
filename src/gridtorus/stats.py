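"""Ensemble-overlap significance statistics.

Given two unit ensembles of sizes ``n_a`` and ``n_b`` drawn from a
population of ``N_total`` units, the chance overlap under independent
selection is modelled as X ~ Binomial(n_a, n_b / N_total); the tail
probability P(X <= x) measures whether an observed overlap ``x`` is smaller
than chance.  The exact hypergeometric tail (sampling without replacement)
is reported alongside as a sensitivity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, hypergeom

__all__ = ["OverlapTest", "overlap_tail_probability", "overlap_test"]


@dataclass
class OverlapTest:
    n_total: int
    n_a: int
    n_b: int
    overlap: int
    p_binomial: float
    p_hypergeometric: float


def _validate(n_total: int, n_a: int, n_b: int, x: int) -> None:
    if not (0 < n_a <= n_total and 0 < n_b <= n_total):
        raise ValueError("set sizes must lie in (0, N_total]")
    if not 0 <= x <= min(n_a, n_b):
        raise ValueError("overlap must lie in [0, min(n_a, n_b)]")


def overlap_tail_probability(n_total: int, n_a: int, n_b: int, x: int) -> float:
    """P(X <= x) for X ~ Binomial(n_a, n_b / n_total), by exact summation."""
    _validate(n_total, n_a, n_b, x)
    q = n_b / n_total
    ks = np.arange(0, x + 1)
    return float(np.sum(binom.pmf(ks, n_a, q)))


def overlap_test(n_total: int, n_a: int, n_b: int, x: int) -> OverlapTest:
    """Binomial tail with the hypergeometric alternative for sensitivity."""
    _validate(n_total, n_a, n_b, x)
    return OverlapTest(
        n_total, n_a, n_b, x,
        p_binomial=overlap_tail_probability(n_total, n_a, n_b, x),
        p_hypergeometric=float(hypergeom.cdf(x, n_total, n_a, n_b)),
    )
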