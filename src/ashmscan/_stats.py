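"""Exact-tail helpers shared by the feature statistics.

The enrichment recipe used throughout the scanner fixes a success rate and a
trial count, which is a binomial model; a hypergeometric variant is offered
for the region-burden test when the genome-wide SNV total is treated as a
fixed draw rather than a rate.
"""

from __future__ import annotations

import math

from scipy import stats as _sps

__all__ = [
    "binom_upper_tail",
    "hypergeom_upper_tail",
    "cap_at_half",
    "geometric_mean_p",
]


def binom_upper_tail(k: int, n: int, rate: float) -> float:
    """One-sided upper-tail P(X >= k) for X ~ Binomial(n, rate).

    ``k <= 0`` returns 1.0 exactly (the whole mass); values are never
    clamped, so callers decide whether to apply the 0.5 reporting cap.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if k > n:
        return 0.0
    if k <= 0:
        return 1.0
    return float(_sps.binom.sf(k - 1, n, rate))


def hypergeom_upper_tail(k: int, n_universe: int, n_marked: int, n_drawn: int) -> float:
    """One-sided upper-tail P(X >= k) for X ~ Hypergeom(universe, marked, drawn)."""
    if min(n_universe, n_marked, n_drawn) < 0 or n_marked > n_universe or n_drawn > n_universe:
        raise ValueError("inconsistent hypergeometric parameters")
    if k <= max(0, n_drawn + n_marked - n_universe):
        return 1.0
    return float(_sps.hypergeom.sf(k - 1, n_universe, n_marked, n_drawn))


def cap_at_half(p: float) -> float:
    """Reporting convention: depleted regions print p = 0.5, never larger."""
    return min(p, 0.5)


def geometric_mean_p(*pvalues: float) -> float:
    """Geometric mean of p-values, computed in log space at full precision.

    Every input must lie in (0, 1]; the result is symmetric in its arguments.
    """
    if not pvalues:
        raise ValueError("at least one p-value required")
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return math.exp(math.fsum(math.log(p) for p in pvalues) / len(pvalues))
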