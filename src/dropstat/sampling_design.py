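"""Chebyshev / law-of-large-numbers sample-size planning.

How many droplets must be scored for the observed occupancy fraction k/n to
sit within a tolerance ε of the true per-droplet success probability p, with
confidence 1 − α?  Chebyshev's inequality bounds the deviation probability

    P(|k/n − p| ≥ ε) ≤ p(1 − p) / (n ε²),

so requiring the bound not to exceed α gives the minimum sample size

    n_min = p(1 − p) / (α ε²).

The bound is distribution-free and conservative: empirical coverage at
n_min comfortably exceeds the nominal confidence.  At the field's customary
ε = 0.15 and 1 − α = 0.90 the formula asks for 50 (p = 0.87) to 108
(p = 0.58) droplets, which is why a 10×10 printed array is a statistically
adequate sample of a 0.1 ml reservoir despite holding <1% of its volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError
from .units import ml_to_deci_pl, nl_to_deci_pl

__all__ = [
    "SamplingDesign",
    "chebyshev_deviation_bound",
    "min_sample_size",
    "sampling_fraction",
    "worst_case_min_sample_size",
]


def _validate(p: float, tolerance: float, alpha: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p={p!r} is not a probability in [0, 1]")
    if not 0.0 < tolerance < 1.0:
        raise DomainError(f"tolerance={tolerance!r} must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha={alpha!r} must lie in (0, 1)")


def chebyshev_deviation_bound(n: int, p: float, eps: float) -> float:
    """Upper bound on P(|k/n − p| ≥ eps) for a binomial proportion.

    Returns min(1, p(1−p)/(n eps²)); degenerate trials (p ∈ {0, 1}) have a
    zero bound because the proportion cannot deviate at all.
    """
    if not isinstance(n, int) or n < 1:
        raise DomainError(f"n={n!r} must be a positive integer")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p={p!r} is not a probability in [0, 1]")
    if not eps > 0.0:
        raise DomainError(f"eps={eps!r} must be strictly positive")
    return min(1.0, p * (1.0 - p) / (n * eps * eps))


def min_sample_size(p: float, eps: float, alpha: float, *, ceiling: bool = False) -> int:
    """Minimum droplet count for |k/n − p| < eps with confidence 1 − alpha.

    Rounds p(1−p)/(α ε²) to the nearest integer by default — the rounding
    that maps 106.7 → 107, 50.3 → 50 and 108.3 → 108 at the customary
    ε = 0.15, α = 0.10.  Pass ``ceiling=True`` for a strictly conservative
    design that never rounds down.  Degenerate p floors at n = 1.
    """
    _validate(p, eps, alpha)
    raw = p * (1.0 - p) / (alpha * eps * eps)
    n = math.ceil(raw) if ceiling else math.floor(raw + 0.5)
    return max(1, n)


def worst_case_min_sample_size(eps: float, alpha: float, *, ceiling: bool = False) -> int:
    """``min_sample_size`` at the least favorable p = 0.5 (p(1−p) maximal)."""
    return min_sample_size(0.5, eps, alpha, ceiling=ceiling)


def sampling_fraction(
    n_droplets: int, droplet_volume_nl: float, reservoir_volume_ml: float
) -> float:
    """Percentage of the reservoir volume consumed by the sampled droplets.

    Volumes are resolved onto a 0.1 pl integer grid before dividing, so
    100 droplets × 7.6 nl / 0.1 ml is exactly 0.76%.
    """
    if not isinstance(n_droplets, int) or n_droplets < 1:
        raise DomainError(f"n_droplets={n_droplets!r} must be a positive integer")
    if not droplet_volume_nl > 0.0:
        raise DomainError(f"droplet_volume_nl={droplet_volume_nl!r} must be positive")
    if not reservoir_volume_ml > 0.0:
        raise DomainError(f"reservoir_volume_ml={reservoir_volume_ml!r} must be positive")
    sampled = n_droplets * nl_to_deci_pl(droplet_volume_nl)
    total = ml_to_deci_pl(reservoir_volume_ml)
    return 100.0 * sampled / total


@dataclass(frozen=True)
class SamplingDesign:
    """A resolved sample-size contract: (p, ε, α) together with n_min."""

    p_worst: float
    tolerance: float
    alpha: float
    n_min: int
    ceiling: bool = False

    @classmethod
    def plan(
        cls, p: float, tolerance: float, alpha: float, *, ceiling: bool = False
    ) -> "SamplingDesign":
        n_min = min_sample_size(p, tolerance, alpha, ceiling=ceiling)
        return cls(p_worst=p, tolerance=tolerance, alpha=alpha, n_min=n_min, ceiling=ceiling)

    @property
    def confidence(self) -> float:
        return 1.0 - self.alpha

    @property
    def bound_at_n_min(self) -> float:
        """Chebyshev deviation bound actually achieved at the planned n."""
        return chebyshev_deviation_bound(self.n_min, self.p_worst, self.tolerance)
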