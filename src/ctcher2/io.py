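"""Reading and writing of cell tables, patient tables and reports.

All delimited files are UTF-8 CSV with a header row. Missing clinical
fields are written as the explicit token ``NA`` (never the empty
string) so that "not measured" is distinguishable from a parse failure.
Reports are JSON with sorted keys, so serializing the same results
twice yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    BestResponse,
    CellRecord,
    FishResult,
    Group,
    IhcScore,
    PatientRecord,
    SchemaError,
    TissueHer2,
    ValidationError,
)

__all__ = [
    "CELL_COLUMNS",
    "PATIENT_COLUMNS",
    "read_cells",
    "write_cells",
    "read_patients",
    "write_patients",
    "cells_to_frame",
    "patients_to_frame",
    "write_report",
]

CELL_COLUMNS = (
    "sample_id",
    "cell_id",
    "mfi_dapi",
    "mfi_ck",
    "mfi_cd45",
    "mfi_her2",
)

PATIENT_COLUMNS = (
    "patient_id",
    "group",
    "ihc_score",
    "fish",
    "best_response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
)

NA = "NA"


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_cells(path, delimiter: str = ",") -> list[CellRecord]:
    """Parse a cell-level CSV into :class:`CellRecord` objects.

    Raises :class:`SchemaError` if a channel column is absent and
    :class:`ValidationError` (citing the offending row) if an intensity
    is negative or non-numeric.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, CELL_COLUMNS, path)
    records: list[CellRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                CellRecord(
                    sample_id=str(row.sample_id),
                    cell_id=str(row.cell_id),
                    mfi_dapi=float(row.mfi_dapi),
                    mfi_ck=float(row.mfi_ck),
                    mfi_cd45=float(row.mfi_cd45),
                    mfi_her2=float(row.mfi_her2),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return records


def cells_to_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "cell_id": c.cell_id,
                "mfi_dapi": c.mfi_dapi,
                "mfi_ck": c.mfi_ck,
                "mfi_cd45": c.mfi_cd45,
                "mfi_her2": c.mfi_her2,
            }
            for c in cells
        ],
        columns=list(CELL_COLUMNS),
    )


def write_cells(cells: Iterable[CellRecord], path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def _opt(value: str):
    return None if value == NA or value == "" else value


def read_patients(path, delimiter: str = ",") -> list[PatientRecord]:
    """Parse a patient-level CSV.

    ``tissue_her2`` is always recomputed from (ihc_score, fish); if the
    file carries a ``tissue_her2`` column the provided value is
    cross-checked and an inconsistent triple raises
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, PATIENT_COLUMNS, path)
    has_tissue = "tissue_her2" in df.columns
    records: list[PatientRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    group=Group(row["group"]),
                    ihc_score=IhcScore(row["ihc_score"]),
                    fish=FishResult(row["fish"]),
                    tissue_her2=TissueHer2(row["tissue_her2"]) if has_tissue else TissueHer2.NA,
                    best_response=BestResponse(row["best_response"]),
                    pfs_months=_opt(row["pfs_months"]),
                    pfs_event=None if _opt(row["pfs_event"]) is None else bool(int(row["pfs_event"])),
                    os_months=_opt(row["os_months"]),
                    os_event=None if _opt(row["os_event"]) is None else bool(int(row["os_event"])),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return records


def patients_to_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "group": p.group.value,
                "ihc_score": p.ihc_score.value,
                "fish": p.fish.value,
                "tissue_her2": p.tissue_her2.value,
                "best_response": p.best_response.value,
                "pfs_months": NA if p.pfs_months is None else p.pfs_months,
                "pfs_event": NA if p.pfs_event is None else int(p.pfs_event),
                "os_months": NA if p.os_months is None else p.os_months,
                "os_event": NA if p.os_event is None else int(p.os_event),
            }
        )
    return pd.DataFrame(rows, columns=list(PATIENT_COLUMNS) + ["tissue_her2"])


def write_patients(patients: Iterable[PatientRecord], path) -> None:
    patients_to_frame(patients).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if hasattr(obj, "value") and isinstance(obj, str):  # str-enums
        return obj.value
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    raise TypeError(f"cannot serialize {type(obj)!r} into a report")


def write_report(results: dict, path) -> None:
    """Serialize an analysis report to JSON, deterministically.

    Keys are sorted and floats written with full repr precision;
    identical results always produce byte-identical files.
    """
    path = Path(path)
    payload = json.dumps(_jsonable(results), sort_keys=True, indent=2)
    path.write_text(payload + "\n", encoding="utf-8")
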