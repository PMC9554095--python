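"""Domain types shared by every stage of the CTC/HER2 pipeline.

The pipeline operates on two granularities:

* cell level — one record per detected cell carrying the four
  immunofluorescence channel intensities (DAPI nuclear stain,
  cytokeratins, CD45 leukocyte marker, HER2), all in arbitrary units;
* patient level — clinical metadata (tissue HER2 category from IHC/FISH,
  best RECIST response, PFS/OS follow-up) plus the quantities the
  pipeline derives (CTC count, HER2 bin occupancy, CTC-HER2 status).

``ScoringScheme`` collects every tunable that parameterizes the
classification: the three MFI bin edges separating the four HER2
staining levels, the HER2(2+) ratio cutoff for the per-patient call, and
the CTC count cutoff used for diagnosis/prognosis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GateLabel",
    "Her2Bin",
    "Group",
    "TissueHer2",
    "IhcScore",
    "FishResult",
    "CtcHer2Status",
    "BestResponse",
    "CountClass",
    "CountComparator",
    "CellRecord",
    "PatientRecord",
    "SurvivalRecord",
    "ScoringScheme",
    "GatingThresholds",
    "ContingencyTable",
    "derive_tissue_her2",
    "ValidationError",
    "SchemaError",
]


class ValidationError(ValueError):
    """A record or table violates a stated invariant."""


class SchemaError(ValueError):
    """An input file does not have the expected columns."""


class GateLabel(str, enum.Enum):
    CTC = "CTC"
    WBC = "WBC"
    AMBIGUOUS = "AMBIGUOUS"
    REJECTED = "REJECTED"


class Her2Bin(str, enum.Enum):
    """Semi-quantitative HER2 staining level of a single CTC."""

    H0 = "H0"  # no / barely perceptible staining
    H1 = "H1"  # faint staining
    H2 = "H2"  # moderate staining
    H3 = "H3"  # strong staining


HER2_BINS: tuple[Her2Bin, ...] = (Her2Bin.H0, Her2Bin.H1, Her2Bin.H2, Her2Bin.H3)


class Group(str, enum.Enum):
    PATIENT = "PATIENT"
    HEALTHY = "HEALTHY"


class TissueHer2(str, enum.Enum):
    NEG = "NEG"
    LOW = "LOW"
    POS = "POS"
    NA = "NA"


class IhcScore(str, enum.Enum):
    S0 = "0"
    S1 = "1+"
    S2 = "2+"
    S3 = "3+"
    NA = "NA"


class FishResult(str, enum.Enum):
    POS = "POS"
    NEG = "NEG"
    NA = "NA"


class CtcHer2Status(str, enum.Enum):
    POS = "POS"
    NEG = "NEG"
    UNEVALUABLE = "UNEVALUABLE"


class BestResponse(str, enum.Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NA = "NA"


class CountClass(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"


class CountComparator(str, enum.Enum):
    GE = "GE"  # HIGH iff count >= cutoff
    GT = "GT"  # HIGH iff count > cutoff


#: The only (IHC, FISH) combinations that occur in the clinic table.
#: 3+ is positive outright; 2+ is resolved by FISH; 1+ is HER2-low; 0 is
#: negative.  Any other combination is rejected rather than guessed at.
_TISSUE_MAP: dict[tuple[IhcScore, FishResult], TissueHer2] = {
    (IhcScore.S3, FishResult.NA): TissueHer2.POS,
    (IhcScore.S2, FishResult.POS): TissueHer2.POS,
    (IhcScore.S2, FishResult.NEG): TissueHer2.LOW,
    (IhcScore.S1, FishResult.NA): TissueHer2.LOW,
    (IhcScore.S0, FishResult.NA): TissueHer2.NEG,
}


def derive_tissue_her2(ihc: IhcScore | str, fish: FishResult | str) -> TissueHer2:
    """Map an (IHC score, FISH result) pair to the tissue HER2 category.

    Raises :class:`ValidationError` for combinations outside the five
    clinically meaningful ones (e.g. IHC 2+ without a FISH result).
    A fully missing pair (both NA) maps to ``TissueHer2.NA`` so that
    healthy donors can be represented.
    """
    ihc = IhcScore(ihc)
    fish = FishResult(fish)
    if ihc is IhcScore.NA and fish is FishResult.NA:
        return TissueHer2.NA
    try:
        return _TISSUE_MAP[(ihc, fish)]
    except KeyError:
        raise ValidationError(
            f"unmappable (IHC, FISH) combination: ({ihc.value}, {fish.value})"
        ) from None


def _check_intensity(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass
class CellRecord:
    """One detected cell: four channel MFIs plus gating/scoring results."""

    sample_id: str
    cell_id: str
    mfi_dapi: float
    mfi_ck: float
    mfi_cd45: float
    mfi_her2: float
    gate_label: Optional[GateLabel] = None
    her2_bin: Optional[Her2Bin] = None

    def __post_init__(self) -> None:
        for name in ("mfi_dapi", "mfi_ck", "mfi_cd45", "mfi_her2"):
            setattr(self, name, _check_intensity(name, getattr(self, name)))
        if self.gate_label is not None:
            self.gate_label = GateLabel(self.gate_label)
        if self.her2_bin is not None:
            self.her2_bin = Her2Bin(self.her2_bin)
            if self.gate_label is not GateLabel.CTC:
                raise ValidationError(
                    "her2_bin may only be set on CTC-gated cells "
                    f"(cell {self.cell_id} has gate_label={self.gate_label})"
                )


@dataclass
class ScoringScheme:
    """Every tunable of the CTC-HER2 classification in one place.

    Parameters
    ----------
    bin_edges
        The three MFI thresholds (a.u.) separating the four HER2
        staining levels; bins are half-open on the left edge, so with
        the defaults H0 = [0, 100), H1 = [100, 400), H2 = [400, 600),
        H3 = [600, inf).
    ratio_cutoff
        A patient is CTC-HER2+ when the fraction of HER2(2+) CTCs is
        *strictly greater* than this, or at least one CTC is HER2(3+).
    count_cutoff, count_comparator
        CTC count per draw dividing HIGH from LOW count classes; both
        ">= cutoff" and "> cutoff" conventions are supported, default
        ">= 3".
    blood_volume_ml
        Collection volume the counts refer to; counts are never
        rescaled to other volumes.
    """

    bin_edges: tuple[float, float, float] = (100.0, 400.0, 600.0)
    ratio_cutoff: float = 0.12
    count_cutoff: int = 3
    count_comparator: CountComparator = CountComparator.GE
    blood_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        self.bin_edges = tuple(float(e) for e in self.bin_edges)  # type: ignore[assignment]
        if len(self.bin_edges) != 3:
            raise ValidationError("bin_edges must hold exactly three thresholds")
        if not all(e > 0 for e in self.bin_edges):
            raise ValidationError("bin_edges must be positive")
        if not (self.bin_edges[0] < self.bin_edges[1] < self.bin_edges[2]):
            raise ValidationError("bin_edges must be strictly increasing")
        if not 0.0 < self.ratio_cutoff < 1.0:
            raise ValidationError("ratio_cutoff must lie strictly between 0 and 1")
        self.count_cutoff = int(self.count_cutoff)
        if self.count_cutoff < 1:
            raise ValidationError("count_cutoff must be >= 1")
        self.count_comparator = CountComparator(self.count_comparator)
        if not self.blood_volume_ml > 0:
            raise ValidationError("blood_volume_ml must be positive")

    def to_dict(self) -> dict:
        return {
            "bin_edges": list(self.bin_edges),
            "ratio_cutoff": self.ratio_cutoff,
            "count_cutoff": self.count_cutoff,
            "count_comparator": self.count_comparator.value,
            "blood_volume_ml": self.blood_volume_ml,
        }


@dataclass
class GatingThresholds:
    """Channel positivity thresholds for the DAPI+/CK+/CD45- gate.

    The identification rule itself is fixed; the numeric thresholds are
    an artifact parameter (the original assay called cells by visual
    review) and default to 50 a.u. on the synthetic intensity scale.
    A channel is "positive" when its MFI is >= the threshold and
    "negative" when it is < the threshold.
    """

    dapi_pos_min: float = 50.0
    ck_pos_min: float = 50.0
    cd45_pos_min: float = 50.0

    def __post_init__(self) -> None:
        for name in ("dapi_pos_min", "ck_pos_min", "cd45_pos_min"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0")
            setattr(self, name, v)

    def to_dict(self) -> dict:
        return {
            "dapi_pos_min": self.dapi_pos_min,
            "ck_pos_min": self.ck_pos_min,
            "cd45_pos_min": self.cd45_pos_min,
        }


@dataclass
class PatientRecord:
    """Clinical metadata plus the pipeline's per-patient results.

    ``ctc_count``, ``her2_bin_counts`` and ``ctc_her2_status`` start
    unset and are filled in by enumeration/phenotyping; ``validate()``
    enforces the cross-field invariants once they are present.
    """

    patient_id: str
    group: Group = Group.PATIENT
    ihc_score: IhcScore = IhcScore.NA
    fish: FishResult = FishResult.NA
    tissue_her2: TissueHer2 = TissueHer2.NA
    ctc_count: Optional[int] = None
    her2_bin_counts: Optional[dict[Her2Bin, int]] = None
    ctc_her2_status: Optional[CtcHer2Status] = None
    best_response: BestResponse = BestResponse.NA
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.ihc_score = IhcScore(self.ihc_score)
        self.fish = FishResult(self.fish)
        self.best_response = BestResponse(self.best_response)
        if self.ctc_her2_status is not None:
            self.ctc_her2_status = CtcHer2Status(self.ctc_her2_status)
        if self.her2_bin_counts is not None:
            self.her2_bin_counts = {
                Her2Bin(k): int(v) for k, v in self.her2_bin_counts.items()
            }
        derived = derive_tissue_her2(self.ihc_score, self.fish)
        given = TissueHer2(self.tissue_her2)
        if given is not TissueHer2.NA and given is not derived:
            raise ValidationError(
                f"patient {self.patient_id}: tissue_her2 given as {given.value} "
                f"but (IHC {self.ihc_score.value}, FISH {self.fish.value}) "
                f"derives {derived.value}"
            )
        self.tissue_her2 = derived
        for name in ("pfs_months", "os_months"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not (math.isfinite(v) and v >= 0):
                    raise ValidationError(
                        f"patient {self.patient_id}: {name} must be finite and >= 0"
                    )
                setattr(self, name, v)
        self.validate()

    def validate(self) -> None:
        if self.ctc_count is not None:
            if self.ctc_count < 0:
                raise ValidationError(
                    f"patient {self.patient_id}: negative ctc_count"
                )
            if self.her2_bin_counts is not None:
                total = sum(self.her2_bin_counts.values())
                if any(v < 0 for v in self.her2_bin_counts.values()):
                    raise ValidationError(
                        f"patient {self.patient_id}: negative her2_bin_counts"
                    )
                if total != self.ctc_count:
                    raise ValidationError(
                        f"patient {self.patient_id}: her2_bin_counts sum to "
                        f"{total} but ctc_count is {self.ctc_count}"
                    )
            if self.ctc_her2_status is not None:
                unevaluable = self.ctc_her2_status is CtcHer2Status.UNEVALUABLE
                if unevaluable != (self.ctc_count == 0):
                    raise ValidationError(
                        f"patient {self.patient_id}: ctc_her2_status must be "
                        "UNEVALUABLE exactly when ctc_count is 0"
                    )


@dataclass
class SurvivalRecord:
    """One subject's follow-up: time on study, event flag, group label."""

    patient_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        self.time = float(self.time)
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValidationError(
                f"patient {self.patient_id}: survival time must be finite and >= 0"
            )
        self.event = bool(self.event)


class ContingencyTable:
    """A small labeled table of non-negative integer counts."""

    def __init__(
        self,
        counts: Sequence[Sequence[int]] | np.ndarray,
        row_labels: Optional[Sequence[str]] = None,
        col_labels: Optional[Sequence[str]] = None,
    ) -> None:
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2x2")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValidationError("counts must be integers")
            arr = rounded.astype(np.int64)
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = arr.astype(np.int64)
        r, c = self.counts.shape
        self.row_labels = list(row_labels) if row_labels is not None else [
            f"row{i}" for i in range(r)
        ]
        self.col_labels = list(col_labels) if col_labels is not None else [
            f"col{j}" for j in range(c)
        ]
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValidationError("label lengths must match the table shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, self.col_labels, self.row_labels)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "row_labels": self.row_labels,
            "col_labels": self.col_labels,
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ContingencyTable({self.counts.tolist()}, rows={self.row_labels}, "
            f"cols={self.col_labels})"
        )
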