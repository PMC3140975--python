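"""File I/O, run configuration, and the end-to-end pipeline.

Droplet tables travel as plain CSV with the fixed header
``droplet_id,row,col,total_cells,target_cells``; reports and config echoes
are JSON with sorted keys and floats normalized to 12 significant digits,
so identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .encapsulation_design import (
    DEFAULT_CELL_VOLUME_PL,
    DropletSpec,
    SuspensionSpec,
    expected_cells_per_droplet,
    max_cell_concentration,
    min_droplet_volume,
    occupancy_probability,
    volume_fraction,
)
from .errors import DropletTableError
from .estimation import (
    estimate_lambda,
    model_fit_error,
    single_target_model_check,
    summarize_array,
)
from .sampling_design import SamplingDesign, sampling_fraction
from .simulator import DropletArray, SimulationDesign, simulate_droplet_array

__all__ = [
    "DROPLET_HEADER",
    "RunConfig",
    "dump_json",
    "droplet_frame",
    "read_droplet_table",
    "run_pipeline",
    "write_droplet_table",
]

DROPLET_HEADER = ["droplet_id", "row", "col", "total_cells", "target_cells"]


def droplet_frame(array: DropletArray) -> pd.DataFrame:
    """Tabular view of an array in the canonical column order."""
    return pd.DataFrame(
        {
            "droplet_id": np.arange(array.n_droplets),
            "row": array.row,
            "col": array.col,
            "total_cells": array.total_cells,
            "target_cells": array.target_cells,
        }
    )


def write_droplet_table(array: DropletArray, path: str | Path) -> None:
    droplet_frame(array).to_csv(path, index=False)


def read_droplet_table(path: str | Path) -> DropletArray:
    """Read and validate a droplet CSV; violations are reported with line numbers.

    A header-only file yields a valid zero-droplet array (rejected later by
    any operation that needs n ≥ 1).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DropletTableError(f"{path}: file is empty (expected header {DROPLET_HEADER})")
    if list(frame.columns) != DROPLET_HEADER:
        raise DropletTableError(
            f"{path}: header {list(frame.columns)} does not match {DROPLET_HEADER}"
        )
    for column in DROPLET_HEADER:
        bad = frame.index[pd.to_numeric(frame[column], errors="coerce").isna()]
        if len(bad):
            raise DropletTableError(
                f"{path}: line {bad[0] + 2}: non-numeric value in column {column!r}"
            )
    counts = frame[["total_cells", "target_cells"]].to_numpy()
    negative = np.where((counts < 0).any(axis=1))[0]
    if negative.size:
        raise DropletTableError(f"{path}: line {negative[0] + 2}: negative cell count")
    excess = np.where(counts[:, 1] > counts[:, 0])[0]
    if excess.size:
        raise DropletTableError(
            f"{path}: line {excess[0] + 2}: target_cells exceeds total_cells"
        )
    duplicated = frame.index[frame["droplet_id"].duplicated()]
    if len(duplicated):
        raise DropletTableError(
            f"{path}: line {duplicated[0] + 2}: duplicate droplet_id"
        )
    return DropletArray(
        row=frame["row"].to_numpy(dtype=np.int64),
        col=frame["col"].to_numpy(dtype=np.int64),
        total_cells=frame["total_cells"].to_numpy(dtype=np.int64),
        target_cells=frame["target_cells"].to_numpy(dtype=np.int64),
    )


def _normalize(obj: Any) -> Any:
    """Recursively round floats to 12 significant digits and de-numpy scalars."""
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, dict):
        return {str(k): _normalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_normalize(v) for v in obj]
    return obj


def dump_json(obj: Any, path: str | Path | None = None) -> str:
    """Serialize with sorted keys and fixed float formatting (byte-stable)."""
    text = json.dumps(_normalize(obj), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters for one end-to-end pipeline run.

    Unit-suffixed field names are deliberate: every number carries its unit.
    """

    concentration_per_ml: float = 1.0e5
    target_fraction: float = 0.1
    cell_volume_pl: float = DEFAULT_CELL_VOLUME_PL
    droplet_volume_nl: float = 7.7
    reservoir_volume_ml: float = 0.1
    grid_rows: int = 10
    grid_cols: int = 10
    n_droplets: int | None = None
    occupancy_override: float | None = None
    seed: int = 42
    p_design: float = 0.6
    tolerance: float = 0.15
    confidence: float = 0.90
    saturation_volume_fraction: float = 0.017

    def simulation_design(self) -> SimulationDesign:
        return SimulationDesign(
            suspension=SuspensionSpec(
                concentration_per_ml=self.concentration_per_ml,
                target_fraction=self.target_fraction,
                cell_volume_pl=self.cell_volume_pl,
            ),
            droplet=DropletSpec(
                droplet_volume_nl=self.droplet_volume_nl,
                reservoir_volume_ml=self.reservoir_volume_ml,
                grid_rows=self.grid_rows,
                grid_cols=self.grid_cols,
            ),
            n_droplets=self.n_droplets,
            seed=self.seed,
            occupancy_override=self.occupancy_override,
        )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """simulate → summarize → estimate → design-check, in one deterministic pass.

    Returns a JSON-ready report embedding the tool version, the fully
    resolved configuration, and the seed; two invocations with the same
    config serialize to identical bytes.
    """
    design = config.simulation_design()
    array = simulate_droplet_array(design)
    summary = summarize_array(array)
    lam_est = estimate_lambda(summary)
    lam, lam_target = design.rates
    p_occ_model = occupancy_probability(lam)

    from scipy import stats as _stats  # local: only the Poisson PMF is needed here

    support = np.arange(len(summary.pmf_cells))
    model_pmf = _stats.poisson.pmf(support, lam_est.estimate)
    single_check = single_target_model_check(summary, design)
    sampling = SamplingDesign.plan(config.p_design, config.tolerance, 1.0 - config.confidence)
    v_min = min_droplet_volume(config.cell_volume_pl, config.saturation_volume_fraction)

    report = {
        "tool": {"name": "dropstat", "version": __version__},
        "config": asdict(config),
        "design": {
            "lambda": lam,
            "lambda_target": lam_target,
            "occupancy_model": p_occ_model,
            "volume_fraction_pct": volume_fraction(
                design.suspension, design.droplet, mode="expected-total"
            ),
            "v_min_pl": v_min,
            "c_max_per_ml": max_cell_concentration(v_min),
            "sampling_fraction_pct": sampling_fraction(
                design.n_droplets, config.droplet_volume_nl, config.reservoir_volume_ml
            ),
        },
        "sample_size": {
            "p": sampling.p_worst,
            "tolerance": sampling.tolerance,
            "confidence": sampling.confidence,
            "n_min": sampling.n_min,
            "bound_at_n_min": sampling.bound_at_n_min,
        },
        "summary": {
            "n_droplets": summary.n_droplets,
            "p_d_hat": summary.p_d_hat,
            "lambda_hat": summary.lambda_hat,
            "lambda_ci": [lam_est.ci_low, lam_est.ci_high],
            "lambda_target_hat": summary.lambda_target_hat,
            "p_single_hat": summary.p_single_hat,
            "p_single_strict_hat": summary.p_single_strict_hat,
            "pmf_cells": summary.pmf_cells,
            "pmf_targets": summary.pmf_targets,
        },
        "model_checks": {
            "occupancy_error_pp": 100.0 * abs(summary.p_d_hat - p_occ_model),
            "cells_pmf_max_error_pp": model_fit_error(summary.pmf_cells, model_pmf),
            "single_target": {
                "empirical_pct": single_check.empirical_pct,
                "combined_pct": single_check.combined_pct,
                "marginal_pct": single_check.marginal_pct,
                "error_combined_pp": single_check.error_combined_pp,
                "error_marginal_pp": single_check.error_marginal_pp,
            },
        },
    }
    return report
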