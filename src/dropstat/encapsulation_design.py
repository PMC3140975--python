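"""Physical design equations for droplet encapsulation.

Links the experimenter's three levers — cell loading concentration C
(cells/ml), droplet volume V (nl) and target-cell fraction F — to the
Poisson loading rate λ = C·V, the occupancy probability 1 − e^{−λ}, and the
volume-fraction design rule for the smallest droplet that can reach near-
certain encapsulation:

    V_min = V_cell / f        and        C_max = 1 / V_min,

where f is the cell-to-droplet volume fraction at which occupancy saturates
(empirically ≈ 1.7%, giving V_min ≈ 30.8 pl and C_max ≈ 32.5×10⁶ cells/ml
for a 10 µm cell).  A saturating-exponential regression
P(C) = a(1 − e^{−bC}) summarizes measured occupancy versus concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DomainError
from .units import NL_PER_ML, PL_PER_ML, PL_PER_NL

__all__ = [
    "DEFAULT_CELL_VOLUME_PL",
    "DropletSpec",
    "OCCUPANCY_REFERENCE",
    "SaturationFit",
    "SuspensionSpec",
    "expected_cells_per_droplet",
    "fit_saturation_curve",
    "max_cell_concentration",
    "min_droplet_volume",
    "occupancy_probability",
    "volume_fraction",
]

#: Volume of a 10 µm-diameter spherical cell, π/6 · d³ ≈ 0.5236 pl.
#: An inferred default — measurements never print a cell volume directly,
#: but 0.5236 pl / 0.017 reproduces the 30.8 pl minimum droplet volume.
#: Override per cell type via ``SuspensionSpec.cell_volume_pl``.
DEFAULT_CELL_VOLUME_PL = 0.5236

#: Measured occupancy percentages for valve-ejected 7.7 nl droplets, keyed by
#: loading concentration in units of 1e5 cells/ml.  The package's built-in
#: reference table for the saturation regression.
OCCUPANCY_REFERENCE: dict[float, float] = {0.5: 27.1, 1.0: 58.3, 1.5: 76.8, 2.0: 87.3}


@dataclass(frozen=True)
class SuspensionSpec:
    """Composition of the ejection reservoir."""

    concentration_per_ml: float
    target_fraction: float = 0.0
    cell_volume_pl: float = DEFAULT_CELL_VOLUME_PL

    def __post_init__(self) -> None:
        if not self.concentration_per_ml >= 0.0:
            raise DomainError(
                f"concentration_per_ml={self.concentration_per_ml!r} must be nonnegative"
            )
        if not 0.0 <= self.target_fraction <= 1.0:
            raise DomainError(
                f"target_fraction={self.target_fraction!r} must lie in [0, 1]"
            )
        if not self.cell_volume_pl > 0.0:
            raise DomainError(f"cell_volume_pl={self.cell_volume_pl!r} must be positive")


@dataclass(frozen=True)
class DropletSpec:
    """Ejection geometry: droplet volume, reservoir, and array layout."""

    droplet_volume_nl: float = 7.7
    reservoir_volume_ml: float = 0.1
    grid_rows: int = 10
    grid_cols: int = 10

    def __post_init__(self) -> None:
        if not self.droplet_volume_nl > 0.0:
            raise DomainError(
                f"droplet_volume_nl={self.droplet_volume_nl!r} must be positive"
            )
        if not self.reservoir_volume_ml > 0.0:
            raise DomainError(
                f"reservoir_volume_ml={self.reservoir_volume_ml!r} must be positive"
            )
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DomainError("grid dimensions must be positive integers")

    @property
    def n_droplets(self) -> int:
        return self.grid_rows * self.grid_cols


class LoadingRates(NamedTuple):
    """Poisson rates implied by a suspension/droplet pairing."""

    lam: float  # mean cells per droplet, λ = C·V
    lam_target: float  # mean target cells per droplet, λF


def expected_cells_per_droplet(
    suspension: SuspensionSpec, droplet: DropletSpec
) -> LoadingRates:
    """λ = concentration × droplet volume, and its target-thinned companion λF."""
    lam = suspension.concentration_per_ml * droplet.droplet_volume_nl / NL_PER_ML
    return LoadingRates(lam=lam, lam_target=lam * suspension.target_fraction)


def occupancy_probability(lam: float) -> float:
    """P(droplet contains ≥1 cell) = 1 − e^{−λ} under Poisson loading."""
    if not lam >= 0.0:
        raise DomainError(f"lam={lam!r} must be nonnegative")
    return -math.expm1(-lam)


def min_droplet_volume(cell_volume_pl: float, volume_fraction: float) -> float:
    """Smallest droplet (pl) whose cell-to-droplet volume ratio is ``volume_fraction``.

    At the saturating ratio f ≈ 0.017 a 0.5236 pl cell needs a 30.8 pl droplet.
    """
    if not cell_volume_pl > 0.0:
        raise DomainError(f"cell_volume_pl={cell_volume_pl!r} must be positive")
    if not 0.0 < volume_fraction < 1.0:
        raise DomainError(f"volume_fraction={volume_fraction!r} must lie in (0, 1)")
    return cell_volume_pl / volume_fraction


def max_cell_concentration(min_droplet_volume_pl: float) -> float:
    """Loading concentration (cells/ml) putting one expected cell in the droplet.

    C_max = 1 / V_min: 30.8 pl → 32.5×10⁶ cells/ml.
    """
    if not min_droplet_volume_pl > 0.0:
        raise DomainError(
            f"min_droplet_volume_pl={min_droplet_volume_pl!r} must be positive"
        )
    return PL_PER_ML / min_droplet_volume_pl


def volume_fraction(
    suspension: SuspensionSpec,
    droplet: DropletSpec,
    mode: Literal["expected-total", "per-cell"] = "expected-total",
) -> float:
    """Cell volume as a percentage of droplet volume.

    ``expected-total`` (default) scales the single-cell volume by the
    expected cell count λ, so the fraction grows linearly with
    concentration; ``per-cell`` is the bare ratio V_cell / V_droplet.
    """
    droplet_pl = droplet.droplet_volume_nl * PL_PER_NL
    if mode == "per-cell":
        return 100.0 * suspension.cell_volume_pl / droplet_pl
    if mode == "expected-total":
        lam = expected_cells_per_droplet(suspension, droplet).lam
        return 100.0 * lam * suspension.cell_volume_pl / droplet_pl
    raise DomainError(f"mode={mode!r} must be 'expected-total' or 'per-cell'")


@dataclass(frozen=True)
class SaturationFit:
    """Least-squares fit of occupancy % versus concentration, P(C) = a(1 − e^{−bC})."""

    a: float
    b: float
    r_squared: float
    adj_r_squared: float
    residuals: tuple[float, ...] = field(repr=False)
    n_points: int

    def predict(self, concentration_1e5: float) -> float:
        """Fitted occupancy (%) at a concentration in units of 1e5 cells/ml."""
        return self.a * -math.expm1(-self.b * concentration_1e5)


def fit_saturation_curve(
    concentrations: Sequence[float],
    probabilities: Sequence[float],
    *,
    a0: float | None = None,
    b0: float = 0.5,
    xtol: float = 1e-10,
    max_iter: int = 500,
) -> SaturationFit:
    """Fit P(C) = a(1 − e^{−bC}) to occupancy percentages.

    Concentrations are in units of 1e5 cells/ml, probabilities in percent.
    Deterministic: Levenberg–Marquardt from a₀ = 1.5 × max(P), b₀ = 0.5,
    converged when the parameter step falls below ``xtol``.  Raises
    :class:`ConvergenceError` if the iteration budget is exhausted.
    """
    c = np.asarray(concentrations, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if c.shape != p.shape or c.ndim != 1:
        raise DomainError("concentrations and probabilities must be 1-D and equal length")
    if c.size < 3:
        raise DomainError(f"need at least 3 points to fit, got {c.size}")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(p))):
        raise DomainError("non-finite values in fit input")
    if not np.all(c > 0.0):
        raise DomainError("concentrations must be strictly positive")
    if np.unique(c).size != c.size:
        raise DomainError("concentrations must be distinct")

    if a0 is None:
        a0 = 1.5 * float(p.max())

    def residual(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        return p - a * -np.expm1(-b * c)

    result = least_squares(
        residual,
        x0=np.array([a0, b0]),
        method="lm",
        xtol=xtol,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iter,
    )
    if not result.success or result.status == 0:
        raise ConvergenceError(
            f"saturation fit did not converge within {max_iter} iterations"
        )
    a_hat, b_hat = (float(v) for v in result.x)
    res = p - a_hat * -np.expm1(-b_hat * c)
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    n, k = c.size, 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else float("nan")
    return SaturationFit(
        a=a_hat,
        b=b_hat,
        r_squared=r2,
        adj_r_squared=adj_r2,
        residuals=tuple(float(r) for r in res),
        n_points=int(n),
    )
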