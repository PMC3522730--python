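"""Detectable-odds-ratio power calculation for a case-control allelic test.

Power of the two-sided 1-df allelic test comparing minor-allele
frequencies between 2*n_cases case alleles and 2*n_controls control
alleles, under a normal approximation: with control frequency p0 (the
MAF) and case frequency p1 implied by the per-allele odds ratio,

    power = Phi( (|p1 - p0| - z_{alpha/2} * SE0) / SE1 ),

where SE0 is the pooled-null and SE1 the alternative standard error of
the frequency difference.  ``detectable_or`` inverts this by bisection to
the smallest risk odds ratio reaching the target power; the protective
bound is its reciprocal.

The default significance level is the Bonferroni level 0.05/320 for a
320-SNP panel — configurable via :class:`PowerQuery`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["PowerQuery", "power_allelic", "detectable_or"]

DEFAULT_ALPHA = 0.05 / 320


@dataclass
class PowerQuery:
    maf: float
    n_cases: int = 494
    n_controls: int = 536
    alpha: float = DEFAULT_ALPHA
    target_power: float = 0.80
    direction: str = "risk"        # risk | protective

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target power must be in (0, 1)")
        if self.direction not in ("risk", "protective"):
            raise ValueError("direction must be 'risk' or 'protective'")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


def power_allelic(odds_ratio: float, query: PowerQuery) -> float:
    """Analytic power of the two-sided allelic test at the given odds ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if odds_ratio == 1.0:
        return query.alpha
    p0 = query.maf
    odds1 = odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    m1 = 2.0 * query.n_cases      # allele counts
    m0 = 2.0 * query.n_controls
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m0))
    se1 = np.sqrt(p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0)
    z = norm.isf(query.alpha / 2.0)
    return float(norm.cdf((abs(p1 - p0) - z * se0) / se1))


def detectable_or(query: PowerQuery, or_max: float = 50.0,
                  tol: float = 1e-6) -> float:
    """Smallest risk odds ratio with power >= target (reciprocal if protective).

    Bisection on the monotone risk-direction power curve; raises when even
    ``or_max`` cannot reach the target power.
    """
    if power_allelic(or_max, query) < query.target_power:
        raise ValueError(
            f"target power {query.target_power} unattainable below OR {or_max}")
    lo, hi = 1.0, or_max
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_allelic(mid, query) >= query.target_power:
            hi = mid
        else:
            lo = mid
    return 1.0 / hi if query.direction == "protective" else hi
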