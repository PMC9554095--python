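"""Immunofluorescence gating of detected cells and CTC enumeration.

A circulating tumor cell is a nucleated epithelial cell that is not a
leukocyte: DAPI-positive, cytokeratin-positive, CD45-negative.  Gating
is a total function assigning exactly one of four labels:

* ``CTC``       — DAPI+ and CK+ and CD45-
* ``WBC``       — DAPI+ and CD45+ (regardless of CK)
* ``AMBIGUOUS`` — DAPI+ but CK- and CD45- (nucleated, marker-silent)
* ``REJECTED``  — DAPI- (no nucleus: debris, free stain)

"Positive" means MFI >= threshold and "negative" means MFI < threshold
(half-open), so boundary behavior is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    CellRecord,
    CountClass,
    CountComparator,
    GateLabel,
    GatingThresholds,
    ScoringScheme,
)

__all__ = [
    "gate_cell",
    "gate_cells",
    "gate_frame",
    "enumerate_ctcs",
    "classify_count",
]


def gate_cell(cell: CellRecord, thresholds: GatingThresholds) -> GateLabel:
    """Assign the gate label for a single cell."""
    if cell.mfi_dapi < thresholds.dapi_pos_min:
        return GateLabel.REJECTED
    if cell.mfi_cd45 >= thresholds.cd45_pos_min:
        return GateLabel.WBC
    if cell.mfi_ck >= thresholds.ck_pos_min:
        return GateLabel.CTC
    return GateLabel.AMBIGUOUS


def gate_cells(
    cells: Iterable[CellRecord], thresholds: GatingThresholds
) -> list[CellRecord]:
    """Return new records with ``gate_label`` assigned."""
    return [replace(c, gate_label=gate_cell(c, thresholds)) for c in cells]


def gate_frame(cells: pd.DataFrame, thresholds: GatingThresholds) -> pd.DataFrame:
    """Vectorized gating for cohort-scale cell tables.

    Adds a ``gate_label`` column; the result is identical to applying
    :func:`gate_cell` row by row.
    """
    dapi = cells["mfi_dapi"].to_numpy(float)
    ck = cells["mfi_ck"].to_numpy(float)
    cd45 = cells["mfi_cd45"].to_numpy(float)
    label = np.full(len(cells), GateLabel.AMBIGUOUS.value, dtype=object)
    nucleated = dapi >= thresholds.dapi_pos_min
    label[~nucleated] = GateLabel.REJECTED.value
    wbc = nucleated & (cd45 >= thresholds.cd45_pos_min)
    label[wbc] = GateLabel.WBC.value
    ctc = nucleated & ~wbc & (ck >= thresholds.ck_pos_min)
    label[ctc] = GateLabel.CTC.value
    out = cells.copy()
    out["gate_label"] = label
    return out


def enumerate_ctcs(cells: Sequence[CellRecord], sample_id: str) -> int:
    """Count CTC-gated cells belonging to ``sample_id``.

    An unknown sample id yields 0 with a warning rather than an error:
    a sample in which nothing was detected is a legitimate (and
    clinically meaningful) outcome.
    """
    seen = False
    count = 0
    for cell in cells:
        if cell.sample_id != sample_id:
            continue
        seen = True
        if cell.gate_label is None:
            raise ValueError(
                f"cell {cell.cell_id} has not been gated; run gate_cells first"
            )
        if cell.gate_label is GateLabel.CTC:
            count += 1
    if not seen:
        warnings.warn(
            f"sample {sample_id!r} has no cells; reporting a count of 0",
            stacklevel=2,
        )
    return count


def classify_count(count: int, scheme: ScoringScheme) -> CountClass:
    """Dichotomize a CTC count into HIGH/LOW per the scheme's cutoff.

    Both comparator conventions are first-class: ``GE`` (HIGH iff count
    >= cutoff, the diagnostic/prognostic convention) and ``GT`` (HIGH
    iff count > cutoff).
    """
    count = int(count)
    if count < 0:
        raise ValueError("count must be non-negative")
    if scheme.count_comparator is CountComparator.GE:
        high = count >= scheme.count_cutoff
    else:
        high = count > scheme.count_cutoff
    return CountClass.HIGH if high else CountClass.LOW
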