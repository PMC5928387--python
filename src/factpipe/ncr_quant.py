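"""Per-cell NCR quantification and well/condition aggregation.

For each segmented cell the reporter signal is averaged over the nucleus and
over the cytoplasm (cell minus nucleus); their ratio is the cell's
nuclear-to-cytoplasmic ratio (NCR).  An optional one-pixel boundary erosion
shrinks the nucleus and pushes the cytoplasm away from the nuclear rim to
guard against blur bleed-through at the compartment boundary.  Cells whose
cytoplasm mean falls at or below a small epsilon are excluded with a reason
code rather than producing unbounded ratios.

Transfected cells are gated on whole-cell mean reporter intensity against the
image background (mean + k*sd).  The median NCR over a well's transfected
cells is the well NCR; the arithmetic mean of the six replicate well medians
is the condition NCR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabelMaps

__all__ = [
    "CellRecord",
    "WellNCR",
    "ConditionResult",
    "compute_cell_ncr",
    "compute_all_cells",
    "estimate_background",
    "gate_transfected",
    "well_ncr",
    "condition_ncr",
    "cells_table",
]

logger = logging.getLogger(__name__)

#: minimum admissible cytoplasm mean (intensity units)
EPSILON = 1.0


@dataclass
class CellRecord:
    well_id: str
    label: int
    nuclear_mean: float
    cytoplasm_mean: float
    ncr: float | None  # None when excluded
    total_mean: float  # whole-cell reporter mean, used by the transfection gate
    transfected: bool | None = None
    excluded_reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.excluded_reason is None


@dataclass
class WellNCR:
    well_id: str
    condition_id: str
    median_ncr: float | None
    n_cells: int  # transfected cells entering the median
    valid: bool = True


@dataclass
class ConditionResult:
    condition_id: str
    mean_ncr: float
    sd_ncr: float
    well_medians: list[float]
    n_wells: int


def compute_cell_ncr(
    maps: LabelMaps,
    reporter: np.ndarray,
    label: int,
    *,
    well_id: str = "",
    boundary_erosion: int = 2,
    cell_boundary_erosion: int = 3,
    eps: float = EPSILON,
) -> CellRecord:
    """NCR of a single labelled cell from the (enhanced) reporter channel."""
    cell_mask = maps.cell_labels == label
    if not cell_mask.any():
        raise ValueError(f"label {label} not present in cell map")
    nuc_mask = maps.nucleus_labels == label
    if not nuc_mask.any():
        raise ValueError(f"label {label} has no nucleus pixels")
    return _cell_record(
        reporter, cell_mask, nuc_mask, label, well_id, boundary_erosion,
        cell_boundary_erosion, eps,
    )


def _cell_record(
    reporter: np.ndarray,
    cell_mask: np.ndarray,
    nuc_mask: np.ndarray,
    label: int,
    well_id: str,
    boundary_erosion: int,
    cell_boundary_erosion: int,
    eps: float,
) -> CellRecord:
    total_mean = float(reporter[cell_mask].mean())
    nuc_core = nuc_mask
    cyto_base = cell_mask
    if cell_boundary_erosion > 0:
        # the segmented cell outline rides the blurred intensity edge, so the
        # outermost pixels under-represent true cytoplasm signal
        shrunk = ndimage.binary_erosion(cell_mask, iterations=cell_boundary_erosion)
        if (shrunk & ~nuc_mask).any():
            cyto_base = shrunk
    cyto_mask = cyto_base & ~nuc_mask
    if boundary_erosion > 0:
        eroded = ndimage.binary_erosion(nuc_mask, iterations=boundary_erosion)
        if eroded.any():
            nuc_core = eroded
        dilated = ndimage.binary_dilation(nuc_mask, iterations=boundary_erosion)
        ring_free = cyto_base & ~dilated
        if ring_free.any():
            cyto_mask = ring_free
    nuclear_mean = float(reporter[nuc_core].mean())
    if not cyto_mask.any():
        return CellRecord(
            well_id, label, nuclear_mean, 0.0, None, total_mean,
            excluded_reason="empty_cytoplasm",
        )
    cytoplasm_mean = float(reporter[cyto_mask].mean())
    if cytoplasm_mean <= eps:
        return CellRecord(
            well_id, label, nuclear_mean, cytoplasm_mean, None, total_mean,
            excluded_reason="cytoplasm_below_epsilon",
        )
    return CellRecord(
        well_id, label, nuclear_mean, cytoplasm_mean, nuclear_mean / cytoplasm_mean,
        total_mean,
    )


def compute_all_cells(
    maps: LabelMaps,
    reporter: np.ndarray,
    *,
    well_id: str = "",
    boundary_erosion: int = 2,
    cell_boundary_erosion: int = 3,
    eps: float = EPSILON,
) -> list[CellRecord]:
    """NCR records for every labelled object, using per-object bounding boxes."""
    records = []
    objects = ndimage.find_objects(maps.cell_labels)
    for i, box in enumerate(objects):
        if box is None:
            continue
        label = i + 1
        # pad the box so erosion/dilation have room at the object border
        pad = max(boundary_erosion, cell_boundary_erosion) + 1
        box = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(box, maps.cell_labels.shape)
        )
        cell_mask = maps.cell_labels[box] == label
        nuc_mask = maps.nucleus_labels[box] == label
        if not nuc_mask.any():
            records.append(
                CellRecord(well_id, label, 0.0, 0.0, None, 0.0,
                           excluded_reason="no_nucleus")
            )
            continue
        records.append(
            _cell_record(
                reporter[box], cell_mask, nuc_mask, label, well_id,
                boundary_erosion, cell_boundary_erosion, eps,
            )
        )
    return records


def estimate_background(reporter: np.ndarray, cell_labels: np.ndarray) -> tuple[float, float]:
    """Mean and sd of the reporter over non-cell pixels."""
    outside = reporter[cell_labels == 0]
    if outside.size == 0:
        return 0.0, 0.0
    return float(outside.mean()), float(outside.std())


def gate_transfected(
    cells: Sequence[CellRecord],
    *,
    background_mean: float = 0.0,
    background_sd: float = 0.0,
    k: float = 5.0,
) -> list[CellRecord]:
    """Flag cells as transfected when whole-cell mean reporter exceeds the gate.

    Gate = background_mean + k * background_sd; a gate of 0 passes every cell.
    Returns the transfected subset (all records keep their updated flag).
    """
    gate = background_mean + k * background_sd
    passed = []
    for cell in cells:
        cell.transfected = cell.total_mean > gate
        if cell.transfected:
            passed.append(cell)
    return passed


def well_ncr(
    cells: Sequence[CellRecord],
    *,
    well_id: str = "",
    condition_id: str = "",
    min_cells: int = 50,
) -> WellNCR:
    """Median NCR over the well's valid transfected cells.

    Wells with fewer than ``min_cells`` usable cells are flagged invalid and
    excluded downstream (with a log entry), not raised.
    """
    ncrs = [
        c.ncr for c in cells if c.valid and c.transfected and c.ncr is not None
    ]
    if len(ncrs) < min_cells:
        logger.warning(
            "well %s: %d transfected cells < minimum %d; flagged invalid",
            well_id, len(ncrs), min_cells,
        )
        return WellNCR(well_id, condition_id, None, len(ncrs), valid=False)
    return WellNCR(well_id, condition_id, float(np.median(ncrs)), len(ncrs))


def condition_ncr(
    wells: Sequence[WellNCR], *, expected_wells: int = 6, min_wells: int = 3
) -> ConditionResult:
    """Mean (and sd) of the valid well medians of one condition."""
    condition_ids = {w.condition_id for w in wells}
    if len(condition_ids) != 1:
        raise ValueError(f"wells span multiple conditions: {sorted(condition_ids)}")
    valid = [w for w in wells if w.valid]
    if len(valid) < min_wells:
        raise ValueError(
            f"condition {condition_ids.pop()!r}: only {len(valid)} valid wells "
            f"(minimum {min_wells})"
        )
    if len(valid) < expected_wells:
        logger.warning(
            "condition %s: %d valid wells, expected %d",
            valid[0].condition_id, len(valid), expected_wells,
        )
    medians = [w.median_ncr for w in valid]
    return ConditionResult(
        condition_id=valid[0].condition_id,
        mean_ncr=float(np.mean(medians)),
        sd_ncr=float(np.std(medians, ddof=1)) if len(medians) > 1 else 0.0,
        well_medians=[float(m) for m in medians],
        n_wells=len(valid),
    )


def cells_table(cells: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": c.well_id,
                "label": c.label,
                "nuclear_mean": c.nuclear_mean,
                "cytoplasm_mean": c.cytoplasm_mean,
                "ncr": c.ncr,
                "total_mean": c.total_mean,
                "transfected": c.transfected,
                "excluded_reason": c.excluded_reason,
            }
            for c in cells
        ]
    )
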