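"""Algorithmic planning of dilution series for calibration standards.

Standards spanning several orders of magnitude are traditionally prepared by
manual serial dilution, where pipetting errors accumulate with each step.
The planner here turns a sorted vector of target concentrations into
column-wise pipetting instructions for an (R x C) microtiter-plate grid,
subject to a maximum working volume per well and minimum/maximum transfer
volumes.  Dilution directly from the stock solution is prioritized; a column
falls back to serial dilution from an already-planned column only when the
stock transfer volume would be below the pipettable minimum, which keeps the
serial-dilution depth minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np

__all__ = [
    "DilutionPlanRequest",
    "DilutionStep",
    "DilutionPlanResult",
    "plan_dilutions",
    "inoculation_concentration",
    "InfeasibleColumnError",
]

VOLUME_RESOLUTION = 0.1  # µL; realistic liquid-handler resolution


class InfeasibleColumnError(ValueError):
    """No source yields transfer volumes within the pipettable window."""

    def __init__(self, column: int, msg: str):
        self.column = column
        super().__init__(f"column {column}: {msg}")


@dataclass(frozen=True)
class DilutionPlanRequest:
    """Targets + geometry + volume constraints for a dilution plan.

    targets       : sorted ascending concentrations, length R*C
    R, C          : grid rows/columns
    stock         : stock concentration (same units as targets)
    vmax_well     : working volume per well (µL)
    vmin_transfer : smallest pipettable transfer (µL)
    vmax_transfer : largest pipettable transfer (µL)
    """

    targets: Sequence[float]
    R: int
    C: int
    stock: float
    vmax_well: float = 1000.0
    vmin_transfer: float = 10.0
    vmax_transfer: float = 950.0

    def __post_init__(self) -> None:
        t = np.asarray(self.targets, dtype=float)
        if t.size != self.R * self.C:
            raise ValueError(f"need R*C={self.R * self.C} targets, got {t.size}")
        if np.any(np.diff(t) < 0):
            raise ValueError("targets must be sorted ascending")
        if np.max(t) > self.stock:
            raise ValueError("targets cannot exceed the stock concentration")
        if not 0 < self.vmin_transfer <= self.vmax_transfer <= self.vmax_well:
            raise ValueError("require 0 < vmin_transfer <= vmax_transfer <= vmax_well")


@dataclass
class DilutionStep:
    """One column operation: per-row transfers from a common source."""

    column: int
    source: Union[str, int]  # "stock" or index of a previously planned column
    transfer_volumes: np.ndarray  # µL, one per row
    diluent_volumes: np.ndarray  # µL, one per row


@dataclass
class DilutionPlanResult:
    achieved: np.ndarray  # (R, C) realized concentrations
    target_grid: np.ndarray  # (R, C) requested concentrations
    steps: List[DilutionStep] = field(default_factory=list)
    max_relative_error: float = 0.0

    def to_frame(self):
        """Tabular plan, one row per column operation."""
        import pandas as pd

        return pd.DataFrame(
            {
                "column": [s.column for s in self.steps],
                "source": [s.source for s in self.steps],
                "transfer_uL": [";".join(f"{v:.1f}" for v in s.transfer_volumes) for s in self.steps],
                "diluent_uL": [";".join(f"{v:.1f}" for v in s.diluent_volumes) for s in self.steps],
                "achieved_concentrations": [
                    ";".join(f"{c:.6g}" for c in self.achieved[:, s.column]) for s in self.steps
                ],
            }
        )


def _round_volume(v: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(v, dtype=float) / VOLUME_RESOLUTION) * VOLUME_RESOLUTION


def _column_volumes(targets, sources, req):
    """Per-row (transfer, diluent) to realize ``targets`` from ``sources``.

    Uses the full working volume unless the transfer would exceed the
    pipettable maximum, in which case the total volume is scaled down.
    Returns None when any transfer falls outside the window.
    """
    factor = sources / targets  # dilution factor >= 1
    if np.any(factor < 1 - 1e-12):
        return None
    factor = np.maximum(factor, 1.0)
    transfer = np.minimum(req.vmax_well / factor, req.vmax_transfer)
    diluent = transfer * (factor - 1.0)
    transfer = _round_volume(transfer)
    diluent = _round_volume(diluent)
    if np.any(transfer < req.vmin_transfer - 1e-9):
        return None
    if np.any(transfer > req.vmax_transfer + 1e-9):
        return None
    if np.any(transfer + diluent > req.vmax_well + 1e-9):
        return None
    return transfer, diluent


def plan_dilutions(req: DilutionPlanRequest) -> DilutionPlanResult:
    """Plan column-wise pipetting instructions for a standards grid.

    The sorted targets are reshaped column-major so that each grid column
    holds a contiguous concentration block; columns are planned in descending
    concentration order so that serial sources always exist before use.
    Among feasible serial sources the one with the smallest dilution factor
    (largest transfer volumes) is chosen, minimizing relative pipetting
    error.  Volumes are rounded to 0.1 µL and the realized concentrations
    follow exactly from mass balance of the rounded volumes.
    """
    targets = np.asarray(req.targets, dtype=float)
    # descending column-major grid: column 0 holds the largest concentrations
    grid = targets[::-1].reshape((req.C, req.R)).T
    achieved = np.full_like(grid, np.nan)
    steps: List[DilutionStep] = []

    for col in range(req.C):
        tgt = grid[:, col]
        # 1) stock is prioritized
        stock_src = np.full(req.R, req.stock)
        vols = _column_volumes(tgt, stock_src, req)
        if vols is not None:
            src, sources = "stock", stock_src
        else:
            # 2) serial from a planned column, minimizing the dilution factor
            best = None
            for j in range(col):
                v = _column_volumes(tgt, achieved[:, j], req)
                if v is None:
                    continue
                fac = float(np.max(achieved[:, j] / tgt))
                if best is None or fac < best[0]:
                    best = (fac, j, v)
            if best is None:
                raise InfeasibleColumnError(
                    col, "no source satisfies the transfer-volume window"
                )
            _, j, vols = best
            src, sources = j, achieved[:, j]
        transfer, diluent = vols
        total = transfer + diluent
        achieved[:, col] = sources * transfer / total
        steps.append(
            DilutionStep(column=col, source=src, transfer_volumes=transfer, diluent_volumes=diluent)
        )

    rel_err = float(np.max(np.abs(achieved - grid) / grid))
    return DilutionPlanResult(
        achieved=achieved, target_grid=grid, steps=steps, max_relative_error=rel_err
    )


def inoculation_concentration(
    v_inoculum: float, c_inoculum: float, v_medium: float
) -> float:
    """Concentration after inoculating ``v_medium`` with ``v_inoculum`` of culture.

    Plain mass balance, e.g. 20 µL of a 10 g/L culture into 780 µL medium
    gives 10 * 20 / 800 = 0.25 g/L.
    """
    return c_inoculum * v_inoculum / (v_inoculum + v_medium)
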