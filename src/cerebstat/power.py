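"""Sampling power for rare cell types.

How many nuclei must be profiled so that every rare cell type is seen often
enough to be clusterable?  Modelling the number of nuclei of one rare type
among n sampled as X ~ Binomial(n, p), the probability that a single type
with prevalence p is captured at least k times is the upper tail P(X >= k);
assuming independence across m equally rare types, the overall probability
of adequately sampling all of them is that tail raised to the m-th power.
A Poisson tail is available as an approximation for very small p.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .core import ValidationError

__all__ = ["PowerParams", "detection_probability", "min_nuclei_for_power"]


@dataclass(frozen=True)
class PowerParams:
    """Parameters of the rare-type detection calculation.

    n: total nuclei sampled; p: prevalence of each rare type; k: minimum
    number of nuclei per type considered adequate; m_types: number of
    independent rare types that must all be captured.
    """

    n: int
    p: float
    k: int = 70
    m_types: int = 1

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p must lie in [0, 1]")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.m_types < 1:
            raise ValidationError("m_types must be >= 1")


def detection_probability(params: PowerParams, approx: str = "exact") -> float:
    """Probability that each of m rare types is sampled at least k times.

    ``approx='exact'`` evaluates the exact binomial upper tail; ``'poisson'``
    replaces it with a Poisson(n*p) tail, adequate when p is small.
    """
    if params.n < params.k:
        return 0.0
    if approx == "exact":
        per_type = stats.binom.sf(params.k - 1, params.n, params.p)
    elif approx == "poisson":
        per_type = stats.poisson.sf(params.k - 1, params.n * params.p)
    else:
        raise ValidationError(f"unknown approximation {approx!r}")
    return float(per_type) ** params.m_types


def min_nuclei_for_power(
    target_prob: float, p: float, k: int = 70, m_types: int = 1
) -> int:
    """Smallest n with detection_probability >= target_prob (bisection).

    The tail is nondecreasing in n, so binary search over n is exact.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValidationError("target_prob must lie strictly in (0, 1)")
    if p <= 0.0:
        raise ValidationError("target unreachable: prevalence must be positive")

    def prob(n: int) -> float:
        return detection_probability(PowerParams(n, p, k, m_types))

    lo, hi = k, max(2 * k, 16)
    while prob(hi) < target_prob:
        hi *= 2
        if hi > 10**12:
            raise ValidationError("target unreachable within 1e12 nuclei")
    while lo < hi:
        mid = (lo + hi) // 2
        if prob(mid) >= target_prob:
            hi = mid
        else:
            lo = mid + 1
    return lo
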