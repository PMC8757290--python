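"""Exact inference for 2x2 contingency tables.

Conditioning on both margins of a 2x2 table, the count in the upper-left
cell follows Fisher's noncentral hypergeometric distribution with
noncentrality equal to the odds ratio (OR).  This module provides

* the two-sided Fisher exact p-value (sum of all conditional outcomes at
  most as probable as the observed one),
* the conditional maximum-likelihood estimate (CMLE) of the OR, i.e. the
  noncentrality psi solving ``E[A | margins, psi] = a``,
* the exact two-sided confidence interval obtained by inverting the
  one-sided tails at (1 - confidence)/2 each,

matching the conventions of R's ``fisher.test``.  At the boundary of the
conditional support the CMLE is 0 or +inf and the corresponding CI bound
is 0 or +inf.

All computations run in log space over the conditional support, so tables
with counts in the tens of thousands are handled in milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "fisher_exact",
    "bonferroni_threshold",
]

#: relative slack when deciding which outcomes tie with the observed
#: probability in the two-sided p-value (same convention as R).
TIE_SLACK = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Counts ``a``/``b`` (group 1 with/without the phenotype) and
    ``c``/``d`` (group 2 with/without)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table total must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class ExactTestResult:
    """Conditional-MLE odds ratio, exact two-sided CI and Fisher p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __iter__(self):
        yield from (self.odds_ratio, self.ci_low, self.ci_high, self.p_value)


def _support(a: int, b: int, c: int, d: int):
    """Conditional support of the upper-left cell and its central log-weights.

    Weight of outcome k is C(n1, k) * C(n2, K - k); multiplying by psi**k
    gives the unnormalised noncentral pmf.
    """
    n1, n2, big_k = a + b, c + d, a + c
    kmin = max(0, big_k - n2)
    kmax = min(big_k, n1)
    k = np.arange(kmin, kmax + 1)
    logw = (
        gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
        + gammaln(n2 + 1) - gammaln(big_k - k + 1) - gammaln(n2 - big_k + k + 1)
    )
    return k, logw


def _lse(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _two_sided_p(k: np.ndarray, logw: np.ndarray, a: int) -> float:
    logpmf = logw - _lse(logw)
    obs = logpmf[int(a - k[0])]
    # outcomes at most as probable as the observed one, with relative slack
    mask = logpmf <= obs + np.log1p(TIE_SLACK)
    return float(min(1.0, np.exp(_lse(logpmf[mask]))))


def _conditional_mean(theta: float, k: np.ndarray, logw: np.ndarray) -> float:
    logterms = logw + k * theta
    logterms -= logterms.max()
    w = np.exp(logterms)
    return float((k * w).sum() / w.sum())


def _log_tail(theta: float, k: np.ndarray, logw: np.ndarray, mask: np.ndarray) -> float:
    logterms = logw + k * theta
    return _lse(logterms[mask]) - _lse(logterms)


def _bracket_and_solve(f, lo: float = -1.0, hi: float = 1.0) -> float:
    """Solve f(theta)=0 for increasing f, expanding the bracket as needed."""
    for _ in range(200):
        if f(lo) <= 0:
            break
        lo *= 2.0
    for _ in range(200):
        if f(hi) >= 0:
            break
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-9, rtol=4e-15)


def fisher_exact(
    a: int,
    b: int,
    c: int,
    d: int,
    confidence: float = 0.95,
    or_kind: str = "conditional",
) -> ExactTestResult:
    """Exact test of association in the 2x2 table ``[[a, b], [c, d]]``.

    Parameters
    ----------
    a, b, c, d
        Cell counts: group 1 with / without the phenotype, group 2 with /
        without.
    confidence
        Two-sided confidence level of the exact CI (default 0.95).
    or_kind
        ``"conditional"`` (default) reports the conditional-MLE odds
        ratio; ``"sample"`` reports the cross-product ratio ad/bc.  The CI
        always inverts the exact conditional tails.

    Returns
    -------
    ExactTestResult
        With ``odds_ratio`` 0 or +inf when the observed count sits at the
        boundary of its conditional support.  A table with an empty row or
        column margin is degenerate: ``p_value`` 1, OR and CI undefined
        (NaN), with a warning.
    """
    t = ContingencyTable(a, b, c, d)
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if or_kind not in ("conditional", "sample"):
        raise ValueError(f"unknown or_kind {or_kind!r}")

    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn(
            "degenerate 2x2 table (empty margin): odds ratio undefined, p = 1",
            stacklevel=2,
        )
        return ExactTestResult(np.nan, np.nan, np.nan, 1.0)

    k, logw = _support(a, b, c, d)
    p = _two_sided_p(k, logw, a)

    kmin, kmax = int(k[0]), int(k[-1])
    alpha = (1.0 - confidence) / 2.0
    log_alpha = np.log(alpha)

    # conditional MLE of the noncentrality
    if a == kmin:
        or_cmle = 0.0
    elif a == kmax:
        or_cmle = np.inf
    else:
        theta = _bracket_and_solve(lambda t_: _conditional_mean(t_, k, logw) - a)
        or_cmle = float(np.exp(theta))

    # lower bound: psi with P(A >= a | psi) = alpha (tail increasing in psi)
    if a == kmin:
        ci_low = 0.0
    else:
        ge = k >= a
        ci_low = float(np.exp(
            _bracket_and_solve(lambda t_: _log_tail(t_, k, logw, ge) - log_alpha)
        ))
    # upper bound: psi with P(A <= a | psi) = alpha (tail decreasing in psi)
    if a == kmax:
        ci_high = np.inf
    else:
        le = k <= a
        ci_high = float(np.exp(
            _bracket_and_solve(lambda t_: log_alpha - _log_tail(t_, k, logw, le))
        ))

    or_out = or_cmle if or_kind == "conditional" else t.sample_odds_ratio
    return ExactTestResult(or_out, ci_low, ci_high, p)


def bonferroni_threshold(alpha: float = 0.01, n_tests: int = 1) -> float:
    """Bonferroni-corrected significance threshold ``alpha / n_tests``.

    Significance is declared with the strict rule ``p < threshold``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests
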