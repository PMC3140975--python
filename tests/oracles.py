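"""Independent brute-force oracles for the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic for binomial probabilities, and an exhaustive (a, b) grid scan
for the saturation regression.
"""

import numpy as np
import sympy


def exact_binomial_pmf(n: int, p_numerator: int, p_denominator: int, k: int) -> float:
    """Binomial PMF via exact rational arithmetic (sympy), then one float cast."""
    p = sympy.Rational(p_numerator, p_denominator)
    return float(sympy.binomial(n, k) * p**k * (1 - p) ** (n - k))


def saturation_grid_search(concentrations, probabilities, a_step=0.5, b_step=0.002):
    """Exhaustive SSE scan of P(C) = a(1 − e^{−bC}) over a ∈ [50,300], b ∈ [0.05,2]."""
    a_grid = np.arange(50.0, 300.0 + a_step / 2, a_step)
    b_grid = np.arange(0.05, 2.0 + b_step / 2, b_step)
    c = np.asarray(concentrations, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    pred = a_grid[:, None, None] * (-np.expm1(-b_grid[None, :, None] * c[None, None, :]))
    sse = ((p - pred) ** 2).sum(axis=2)
    i, j = np.unravel_index(sse.argmin(), sse.shape)
    return float(a_grid[i]), float(b_grid[j]), float(sse[i, j])
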