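"""Probability laws of the droplet encapsulation process.

A drop-on-demand ejector samples nanoliter droplets from a well-mixed
suspension of target and non-target cells.  Four discrete random variables
describe one printed array of droplets:

* ``X_d`` — whether a droplet contains at least one cell ("success" in the
  Bernoulli framing); across *n* droplets the success count is binomial.
* ``X_c`` — the number of cells in a droplet; cell capture is a rare event
  relative to the reservoir, so ``X_c`` is Poisson with rate
  λ = concentration × droplet volume.
* ``X_t`` — the number of *target* cells in a droplet; binomial thinning of
  ``X_c`` by the target fraction F gives a Poisson with rate λF.
* ``X_s`` — the indicator that a droplet holds exactly one target cell, the
  event an isolation experiment prices.  Its law combines droplet occupancy
  with the Poisson singleton probability: P(X_s=1) = P(X_d≥1) · λ_t e^{−λ_t}.

This module provides exact PMFs for these laws plus the Stirling-factorial
approximation to the binomial PMF that makes large-``n`` evaluation cheap,
and the normal density used for law-of-large-numbers comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import DomainError

__all__ = [
    "BinomialLaw",
    "PoissonLaw",
    "SingleTargetLaw",
    "binomial_pmf",
    "binomial_pmf_stirling",
    "binomial_to_poisson_params",
    "normal_approximation",
    "poisson_pmf",
    "single_target_pmf",
    "stirling_factorial",
    "stirling_relative_error",
]

#: above this trial count the binomial PMF is evaluated in log space;
#: below it, the naive product is exact-by-construction and bit-stable.
_LOG_SPACE_N = 50


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name}={value!r} is not a probability in [0, 1]")


@dataclass(frozen=True)
class BinomialLaw:
    """Success count over ``n_trials`` droplets, success probability ``p_success``.

    "Success" is the event that a droplet contains at least one cell; the
    law of the occupied-droplet count X_d over a printed array.
    """

    n_trials: int
    p_success: float

    def __post_init__(self) -> None:
        if not isinstance(self.n_trials, int) or self.n_trials < 1:
            raise DomainError(f"n_trials={self.n_trials!r} must be a positive integer")
        _check_probability("p_success", self.p_success)

    @property
    def q(self) -> float:
        """Failure (empty droplet) probability, 1 − p."""
        return 1.0 - self.p_success

    @property
    def mean(self) -> float:
        """μ = np."""
        return self.n_trials * self.p_success

    @property
    def variance(self) -> float:
        """σ² = npq."""
        return self.n_trials * self.p_success * self.q

    def pmf(self, k: int) -> float:
        return binomial_pmf(self, k)


@dataclass(frozen=True)
class PoissonLaw:
    """Cell count per droplet, X_c ~ Poisson(rate).

    ``sigma_sq`` carries the variance of the binomial law the Poisson
    approximates, λ(1 − λ/n); for the pure Poisson limit it equals the rate.
    """

    rate: float
    sigma_sq: float | None = None

    def __post_init__(self) -> None:
        if not self.rate >= 0.0:
            raise DomainError(f"rate={self.rate!r} must be nonnegative")
        if self.sigma_sq is None:
            object.__setattr__(self, "sigma_sq", self.rate)

    @property
    def mu(self) -> float:
        """μ = λ."""
        return self.rate

    def pmf(self, k: int) -> float:
        return poisson_pmf(self, k)

    def truncation_point(self, tail: float = 1e-12) -> int:
        """Smallest k whose cumulative mass exceeds 1 − ``tail``."""
        if self.rate == 0.0:
            return 0
        return int(stats.poisson.ppf(1.0 - tail, self.rate))


@dataclass(frozen=True)
class SingleTargetLaw:
    """Indicator law of a droplet holding exactly one target cell.

    Occupancy (X_d) and the target count (X_t) are treated as independent
    conditional on the droplet being occupied; an empty droplet forces
    X_t = 0.  The combined singleton probability is therefore
    ``p_occupied × λ_t e^{−λ_t}`` and the law is Bernoulli:
    P(X_s=0) = 1 − P(X_s=1) exactly.
    """

    p_occupied: float
    lambda_target: float

    def __post_init__(self) -> None:
        _check_probability("p_occupied", self.p_occupied)
        if not self.lambda_target >= 0.0:
            raise DomainError(f"lambda_target={self.lambda_target!r} must be nonnegative")

    @property
    def p_single(self) -> float:
        """P(X_s = 1)."""
        return self.p_occupied * self.lambda_target * math.exp(-self.lambda_target)

    def pmf(self, k: int) -> float:
        if not isinstance(k, int) or k < 0:
            raise DomainError(f"k={k!r} must be a nonnegative integer")
        if k == 0:
            return 1.0 - self.p_single
        if k == 1:
            return self.p_single
        return 0.0


def binomial_pmf(law: BinomialLaw, k: int) -> float:
    """P(X_d = k) = C(n,k) p^k q^{n−k}.

    Small trial counts use the exact integer binomial coefficient; beyond
    ``n > 50`` the PMF is assembled from log-gamma terms so factorials never
    overflow.
    """
    n, p, q = law.n_trials, law.p_success, law.q
    if not isinstance(k, int) or not 0 <= k <= n:
        raise DomainError(f"k={k!r} outside the support 0..{n}")
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == n else 0.0
    if n <= _LOG_SPACE_N:
        return math.comb(n, k) * p**k * q ** (n - k)
    log_pmf = (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log(q)
    )
    return math.exp(log_pmf)


def _log_stirling(n: int) -> float:
    return 0.5 * math.log(2.0 * math.pi * n) + n * math.log(n) - n


def stirling_factorial(n: int) -> float:
    """Stirling's approximation √(2πn)(n/e)^n to n!.

    ``n = 0`` returns 1.0 exactly by convention (0! = 1; the formula itself
    is undefined there).  For n large enough that the value exceeds float
    range, +inf is returned.
    """
    if not isinstance(n, int) or n < 0:
        raise DomainError(f"n={n!r} must be a nonnegative integer")
    if n == 0:
        return 1.0
    log_value = _log_stirling(n)
    if log_value > 709.0:  # exp overflow threshold for IEEE doubles
        return math.inf
    return math.exp(log_value)


def stirling_relative_error(n: int) -> float:
    """Relative error |Stirling(n) − n!| / n!, evaluated in log space.

    Stirling's formula always underestimates the factorial, and the error
    falls roughly as 1/(12n): below 0.5% already at n = 20.
    """
    if not isinstance(n, int) or n < 0:
        raise DomainError(f"n={n!r} must be a nonnegative integer")
    if n == 0:
        return 0.0
    return 1.0 - math.exp(_log_stirling(n) - math.lgamma(n + 1))


def binomial_pmf_stirling(law: BinomialLaw, k: int) -> float:
    """Binomial PMF with every factorial replaced by Stirling's approximation.

    Defined for interior k (1 ≤ k ≤ n−1); at the boundary the approximation
    would need a Stirling form for 0!, which does not exist, so the exact
    PMF is substituted there.  For n ≥ 20 and central k the approximation
    agrees with the exact PMF to well within 1.5% relative.
    """
    n, p, q = law.n_trials, law.p_success, law.q
    if not isinstance(k, int) or not 0 <= k <= n:
        raise DomainError(f"k={k!r} outside the support 0..{n}")
    if k == 0 or k == n:
        return binomial_pmf(law, k)
    if p == 0.0 or p == 1.0:
        return 0.0  # interior k is impossible under a degenerate trial
    log_pmf = (
        _log_stirling(n)
        - _log_stirling(k)
        - _log_stirling(n - k)
        + k * math.log(p)
        + (n - k) * math.log(q)
    )
    return math.exp(log_pmf)


def poisson_pmf(law: PoissonLaw, k: int) -> float:
    """P(X_c = k) = e^{−λ} λ^k / k! (log-space evaluation for large k)."""
    if not isinstance(k, int) or k < 0:
        raise DomainError(f"k={k!r} must be a nonnegative integer")
    return float(stats.poisson.pmf(k, law.rate))


def binomial_to_poisson_params(n: int, p: float) -> PoissonLaw:
    """Poisson parameters matching a Binomial(n, p): λ = μ = np, σ² = λ(1 − λ/n).

    As n → ∞ with np held fixed the variance tends to the rate and the
    binomial converges to the Poisson — the rare-event limit that justifies
    modeling per-droplet cell counts as Poisson.
    """
    if not isinstance(n, int) or n < 1:
        raise DomainError(f"n={n!r} must be a positive integer")
    _check_probability("p", p)
    rate = n * p
    return PoissonLaw(rate=rate, sigma_sq=rate * (1.0 - rate / n))


def single_target_pmf(p_occupied: float, lambda_target: float) -> SingleTargetLaw:
    """Combined law of the single-target-cell event.

    ``p_occupied`` is the per-droplet probability of containing any cell
    (1 − e^{−λ} under Poisson loading, or an empirically measured value);
    ``lambda_target`` is the mean number of target cells per droplet (λF).
    """
    return SingleTargetLaw(p_occupied=p_occupied, lambda_target=lambda_target)


def normal_approximation(mu: float, sigma: float, x: float) -> float:
    """Gaussian density at x — the continuous curve the binomial proportion
    approaches as the droplet count grows (law of large numbers / CLT)."""
    if not sigma > 0.0:
        raise DomainError(f"sigma={sigma!r} must be strictly positive")
    return float(stats.norm.pdf(x, loc=mu, scale=sigma))
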