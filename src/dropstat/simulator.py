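"""Seeded Monte Carlo simulation of droplet arrays.

Generates one printed array of droplets from a heterogeneous suspension:
per droplet an independent total cell count X_c ~ Poisson(λ) with
λ = concentration × droplet volume, and a target count
X_t | X_c ~ Binomial(X_c, F) — the binomial thinning whose marginal is
Poisson(λF).  Droplets are laid out row-major on the DropletSpec grid; the
layout is cosmetic (droplets are exchangeable) but fixed so outputs are
byte-identical under a seed.

Randomness contract: NumPy's PCG64 ``default_rng`` seeded from a single
integer via ``SeedSequence``; replicate streams are spawned children of the
root sequence, so replicate k is reproducible in isolation.

An ``occupancy_override`` lets the zero/nonzero indicator follow an
empirically measured occupancy instead of 1 − e^{−λ} (measured occupancy can
exceed the Poisson prediction); occupied droplets then draw their count from
the zero-truncated Poisson, the minimal departure that keeps the conditional
cell-count law intact.  Cell settling and aggregation are deliberately not
modeled: droplets are independent draws from a well-mixed reservoir.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .encapsulation_design import DropletSpec, SuspensionSpec, expected_cells_per_droplet
from .errors import DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .estimation import CountSummary

__all__ = ["DropletArray", "SimulationDesign", "replicate_experiment", "simulate_droplet_array"]


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to reproduce one simulated experiment."""

    suspension: SuspensionSpec
    droplet: DropletSpec = DropletSpec()
    n_droplets: int | None = None
    seed: int = 0
    occupancy_override: float | None = None

    def __post_init__(self) -> None:
        if self.n_droplets is None:
            object.__setattr__(self, "n_droplets", self.droplet.n_droplets)
        if not isinstance(self.n_droplets, int) or self.n_droplets < 1:
            raise DomainError(f"n_droplets={self.n_droplets!r} must be a positive integer")
        if self.occupancy_override is not None and not 0.0 <= self.occupancy_override <= 1.0:
            raise DomainError(
                f"occupancy_override={self.occupancy_override!r} must lie in [0, 1]"
            )

    @property
    def rates(self):
        return expected_cells_per_droplet(self.suspension, self.droplet)


@dataclass(frozen=True, eq=False)
class DropletArray:
    """One realized droplet array: per-droplet total and target cell counts."""

    row: np.ndarray
    col: np.ndarray
    total_cells: np.ndarray
    target_cells: np.ndarray
    design: SimulationDesign | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        n = len(self.total_cells)
        if not (len(self.row) == len(self.col) == len(self.target_cells) == n):
            raise DomainError("droplet array columns must have equal length")
        if n and (np.any(self.total_cells < 0) or np.any(self.target_cells < 0)):
            raise DomainError("cell counts must be nonnegative")
        if n and np.any(self.target_cells > self.total_cells):
            raise DomainError("target_cells may not exceed total_cells")
        if n:
            cells = set(zip(self.row.tolist(), self.col.tolist()))
            if len(cells) != n:
                raise DomainError("grid positions must be unique")

    @property
    def n_droplets(self) -> int:
        return len(self.total_cells)


def _grid_layout(n: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return idx // cols, idx % cols


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Inverse-CDF draw from Poisson(λ) conditioned on being ≥ 1."""
    p0 = math.exp(-lam)
    u = rng.random(size)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)


def _simulate_with_rng(design: SimulationDesign, rng: np.random.Generator) -> DropletArray:
    n = design.n_droplets
    lam = design.rates.lam
    fraction = design.suspension.target_fraction

    if design.occupancy_override is None:
        total = rng.poisson(lam, size=n)
    else:
        if lam == 0.0 and design.occupancy_override > 0.0:
            raise DomainError("occupancy_override > 0 requires a positive loading rate")
        occupied = rng.random(n) < design.occupancy_override
        total = np.zeros(n, dtype=np.int64)
        n_occ = int(occupied.sum())
        if n_occ:
            total[occupied] = _zero_truncated_poisson(rng, lam, n_occ)

    target = rng.binomial(total, fraction) if fraction > 0.0 else np.zeros(n, dtype=np.int64)
    row, col = _grid_layout(n, design.droplet.grid_cols)
    return DropletArray(
        row=row,
        col=col,
        total_cells=total.astype(np.int64),
        target_cells=np.asarray(target, dtype=np.int64),
        design=design,
    )


def simulate_droplet_array(design: SimulationDesign) -> DropletArray:
    """Draw one droplet array, fully reproducible from ``design.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    return _simulate_with_rng(design, rng)


def replicate_experiment(design: SimulationDesign, n_replicates: int) -> list["CountSummary"]:
    """Independent replicate arrays, summarized, in replicate order.

    Replicate k draws from the k-th spawned child of the root seed
    sequence, so the list is deterministic and each entry reproducible on
    its own.
    """
    from .estimation import summarize_array  # deferred: estimation imports this module

    if not isinstance(n_replicates, int) or n_replicates < 1:
        raise DomainError(f"n_replicates={n_replicates!r} must be a positive integer")
    children = np.random.SeedSequence(design.seed).spawn(n_replicates)
    return [
        summarize_array(_simulate_with_rng(design, np.random.default_rng(child)))
        for child in children
    ]
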