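"""Semi-quantitative HER2 scoring of CTCs and the per-patient call.

Each CTC's HER2 mean fluorescence intensity is assigned to one of four
staining levels, by analogy with tissue IHC scoring::

    H0  [0, 100)      no / barely perceptible staining
    H1  [100, 400)    faint staining
    H2  [400, 600)    moderate staining
    H3  [600, inf)    strong staining

(with the default edges; intervals are half-open on the left edge so
binning is a total, deterministic function of MFI).

A patient with at least one CTC is called CTC-HER2 positive when the
fraction of H2 CTCs strictly exceeds the ratio cutoff (default 12%) or
at least one CTC is H3; patients with zero CTCs are UNEVALUABLE, not
negative.  The ratio cutoff itself can be re-derived from a calibration
cohort by maximizing Youden's J over observed H2 ratios.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    CellRecord,
    CtcHer2Status,
    GateLabel,
    Her2Bin,
    HER2_BINS,
    PatientRecord,
    ScoringScheme,
    ValidationError,
)

__all__ = [
    "bin_her2",
    "bin_her2_array",
    "call_ctc_her2",
    "CutoffResult",
    "derive_ratio_cutoff",
    "phenotype_cohort",
    "phenotype_frame",
]


def bin_her2(mfi: float, scheme: ScoringScheme) -> Her2Bin:
    """Map one HER2 MFI (a.u.) to its staining level."""
    mfi = float(mfi)
    if not mfi >= 0:
        raise ValidationError(f"HER2 MFI must be non-negative, got {mfi!r}")
    e1, e2, e3 = scheme.bin_edges
    if mfi < e1:
        return Her2Bin.H0
    if mfi < e2:
        return Her2Bin.H1
    if mfi < e3:
        return Her2Bin.H2
    return Her2Bin.H3


def bin_her2_array(mfi: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    """Vectorized :func:`bin_her2`; returns an array of bin value strings."""
    mfi = np.asarray(mfi, dtype=float)
    if (mfi < 0).any() or not np.isfinite(mfi).all():
        raise ValidationError("HER2 MFIs must be finite and non-negative")
    idx = np.searchsorted(np.asarray(scheme.bin_edges), mfi, side="right")
    return np.array([b.value for b in HER2_BINS], dtype=object)[idx]


def call_ctc_her2(
    bin_counts: Mapping[Her2Bin, int] | Mapping[str, int], scheme: ScoringScheme
) -> CtcHer2Status:
    """Per-patient CTC-HER2 status from the patient's bin occupancy.

    POS iff (H2 count / total) strictly exceeds ``scheme.ratio_cutoff``
    or at least one H3 CTC; a ratio of exactly the cutoff is NEG.
    Zero CTCs -> UNEVALUABLE.
    """
    counts = {Her2Bin(k): int(v) for k, v in bin_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValidationError("bin counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        return CtcHer2Status.UNEVALUABLE
    if counts.get(Her2Bin.H3, 0) >= 1:
        return CtcHer2Status.POS
    if counts.get(Her2Bin.H2, 0) / total > scheme.ratio_cutoff:
        return CtcHer2Status.POS
    return CtcHer2Status.NEG


@dataclass
class CutoffResult:
    """Outcome of the ratio-cutoff derivation."""

    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


def derive_ratio_cutoff(
    ratios: Sequence[float], labels: Sequence[int] | Sequence[bool]
) -> CutoffResult:
    """Derive the H2-ratio cutoff separating two calibration classes.

    Parameters
    ----------
    ratios
        Per-patient H2 CTC ratios in [0, 1].
    labels
        1 for the higher-expression class (IHC 2+), 0 for the lower
        class (IHC 0/1+).  A patient is classified positive when its
        ratio is *strictly greater* than the threshold, matching the
        convention of :func:`call_ctc_her2`.

    Returns the observed ratio value maximizing Youden's
    J = sensitivity + specificity - 1, ties broken toward the smaller
    threshold.  Raises ``ValueError`` when only one class is present or
    no threshold separates the classes at all (J <= 0 everywhere).
    """
    r = np.asarray(ratios, dtype=float)
    y = np.asarray(labels).astype(bool)
    if r.shape != y.shape or r.ndim != 1 or len(r) == 0:
        raise ValueError("ratios and labels must be equal-length 1-D sequences")
    if (r < 0).any() or (r > 1).any():
        raise ValueError("ratios must lie in [0, 1]")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cutoff underdetermined: both classes must be represented")
    best: CutoffResult | None = None
    for t in np.unique(r):
        pred = r > t
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(t), j, sens, spec)
    assert best is not None
    if best.youden_j <= 0:
        raise ValueError(
            "cutoff underdetermined: no threshold separates the classes (J <= 0)"
        )
    return best


def _bin_counts_from_cells(cells: Iterable[CellRecord], scheme: ScoringScheme):
    counts = Counter({b: 0 for b in HER2_BINS})
    binned = []
    for c in cells:
        b = bin_her2(c.mfi_her2, scheme)
        counts[b] += 1
        binned.append(replace(c, her2_bin=b))
    return dict(counts), binned


def phenotype_cohort(
    cells: Sequence[CellRecord],
    patients: Sequence[PatientRecord],
    scheme: ScoringScheme,
) -> tuple[list[CellRecord], list[PatientRecord]]:
    """Score every CTC and call the CTC-HER2 status of every patient.

    Cells must already be gated.  Cells whose ``sample_id`` matches no
    patient are an error (orphan samples are listed); patients without
    cells simply get a count of 0 and an UNEVALUABLE status.

    Returns (cells with ``her2_bin`` filled on CTCs, updated patients).
    """
    by_patient: dict[str, list[CellRecord]] = {p.patient_id: [] for p in patients}
    orphans = sorted(
        {c.sample_id for c in cells if c.sample_id not in by_patient}
    )
    if orphans:
        raise ValidationError(
            "cells reference sample ids with no patient metadata: "
            + ", ".join(orphans)
        )
    for c in cells:
        if c.gate_label is None:
            raise ValueError(f"cell {c.cell_id} has not been gated")
        by_patient[c.sample_id].append(c)

    out_cells: list[CellRecord] = []
    out_patients: list[PatientRecord] = []
    for p in patients:
        ctcs = [c for c in by_patient[p.patient_id] if c.gate_label is GateLabel.CTC]
        counts, binned = _bin_counts_from_cells(ctcs, scheme)
        out_cells.extend(
            [c for c in by_patient[p.patient_id] if c.gate_label is not GateLabel.CTC]
        )
        out_cells.extend(binned)
        q = replace(
            p,
            ctc_count=len(ctcs),
            her2_bin_counts=counts,
            ctc_her2_status=call_ctc_her2(counts, scheme),
        )
        q.validate()
        out_patients.append(q)
    return out_cells, out_patients


def phenotype_frame(
    gated_cells: pd.DataFrame, patients: pd.DataFrame, scheme: ScoringScheme
) -> pd.DataFrame:
    """Cohort-scale version of :func:`phenotype_cohort` on data frames.

    ``gated_cells`` needs columns ``sample_id``, ``mfi_her2`` and
    ``gate_label``; ``patients`` needs ``patient_id``.  Returns the
    patient frame with ``ctc_count``, ``n_h0``..``n_h3`` and
    ``ctc_her2_status`` columns appended.
    """
    known = set(patients["patient_id"])
    orphans = sorted(set(gated_cells["sample_id"]) - known)
    if orphans:
        raise ValidationError(
            "cells reference sample ids with no patient metadata: "
            + ", ".join(str(o) for o in orphans)
        )
    ctc = gated_cells[gated_cells["gate_label"] == GateLabel.CTC.value].copy()
    ctc["her2_bin"] = bin_her2_array(ctc["mfi_her2"].to_numpy(), scheme)
    occ = (
        ctc.pivot_table(
            index="sample_id", columns="her2_bin", values="cell_id", aggfunc="count"
        )
        .reindex(columns=[b.value for b in HER2_BINS], fill_value=0)
        .fillna(0)
        .astype(int)
    )
    out = patients.copy()
    for b in HER2_BINS:
        col = occ[b.value] if b.value in occ.columns else pd.Series(0, index=occ.index)
        out[f"n_{b.value.lower()}"] = (
            out["patient_id"].map(col).fillna(0).astype(int)
        )
    out["ctc_count"] = (
        out[[f"n_{b.value.lower()}" for b in HER2_BINS]].sum(axis=1).astype(int)
    )
    out["ctc_her2_status"] = [
        call_ctc_her2(
            {b: row[f"n_{b.value.lower()}"] for b in HER2_BINS}, scheme
        ).value
        for _, row in out.iterrows()
    ]
    return out
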