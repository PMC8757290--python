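"""Brute-force enumeration oracle for small 2x2 exact tests.

Everything here is computed from first principles — binomial coefficients
via :func:`math.comb`, the two-sided p-value in exact rational arithmetic,
and the conditional-MLE odds ratio and exact CI bounds by plain bisection
over an explicitly enumerated noncentral hypergeometric pmf.  It shares no
code with :mod:`multiphewas.exact` and exists to validate it on tables
small enough to enumerate (total count up to a few hundred).
"""

from __future__ import annotations

import math
from fractions import Fraction

from .exact import ExactTestResult

__all__ = ["enumerate_oracle"]


def _support(a, b, c, d):
    n1, n2, big_k = a + b, c + d, a + c
    kmin = max(0, big_k - n2)
    kmax = min(big_k, n1)
    weights = {
        k: math.comb(n1, k) * math.comb(n2, big_k - k) for k in range(kmin, kmax + 1)
    }
    return kmin, kmax, weights


def _p_two_sided(a, weights) -> Fraction:
    total = sum(weights.values())
    obs = Fraction(weights[a], total)
    return min(
        Fraction(1),
        sum(Fraction(w, total) for w in weights.values() if Fraction(w, total) <= obs),
    )


def _mean(psi: float, weights) -> float:
    num = den = 0.0
    # scale by psi**kmin implicitly: iterate in order, multiply up
    kmin = min(weights)
    f = 1.0
    for k in sorted(weights):
        w = weights[k] * f
        num += k * w
        den += w
        f *= psi
    return num / den


def _tail_ge(psi: float, weights, a: int) -> float:
    num = den = 0.0
    kmin = min(weights)
    f = 1.0
    for k in sorted(weights):
        w = weights[k] * f
        den += w
        if k >= a:
            num += w
        f *= psi
    return num / den


def _tail_le(psi: float, weights, a: int) -> float:
    num = den = 0.0
    f = 1.0
    for k in sorted(weights):
        w = weights[k] * f
        den += w
        if k <= a:
            num += w
        f *= psi
    return num / den


def _bisect(f, target, increasing: bool, iters: int = 200) -> float:
    """Solve f(psi) = target for psi > 0 by bisection on log(psi)."""
    lo, hi = -1.0, 1.0
    def g(t):
        v = f(math.exp(t)) - target
        return v if increasing else -v
    while g(lo) > 0:
        lo *= 2
        if lo < -700:
            return 0.0
    while g(hi) < 0:
        hi *= 2
        if hi > 700:
            return math.inf
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def enumerate_oracle(a: int, b: int, c: int, d: int, confidence: float = 0.95) -> ExactTestResult:
    """Exact-test result for a small table by explicit enumeration.

    Intended for tests only; cost grows with the conditional support, so
    keep totals below a few hundred.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        return ExactTestResult(math.nan, math.nan, math.nan, 1.0)
    kmin, kmax, weights = _support(a, b, c, d)
    p = float(_p_two_sided(a, weights))
    alpha = (1.0 - confidence) / 2.0

    if a == kmin:
        or_cmle, ci_low = 0.0, 0.0
    else:
        ci_low = _bisect(lambda s: _tail_ge(s, weights, a), alpha, increasing=True)
    if a == kmax:
        or_cmle, ci_high = math.inf, math.inf
    else:
        ci_high = _bisect(lambda s: _tail_le(s, weights, a), alpha, increasing=False)
    if kmin < a < kmax:
        or_cmle = _bisect(lambda s: _mean(s, weights), float(a), increasing=True)
    return ExactTestResult(or_cmle, ci_low, ci_high, p)
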