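"""Synthetic cohort generation.

Emulates the statistical structure of a single-draw CTC study on
advanced breast cancer: 52 patients (15 tissue-HER2-negative, 13
HER2-low, 24 HER2-positive, the composition of the study population)
plus 10 healthy donors; heavily right-skewed zero-inflated CTC counts
per 2.0 ml draw; class-conditional HER2 MFI distributions with overlap
between tissue classes (and no CTC-HER2 positivity at all in the
tissue-negative class); treatment response probabilities that depend on
the patient's CTC-HER2 status; and exponential PFS/OS with a planted
count-class hazard ratio.

Design notes
------------
* Counts are zero-inflated negative binomial, drawn per class by
  stratified inverse-CDF (Latin-hypercube) sampling: marginals are
  exactly the planted distribution, and a finite cohort tracks the
  planted zero fraction and mean closely — appropriate for a generator
  whose purpose is to realize fixed study conditions, at the price of
  counts being exchangeable rather than independent across patients.
* Each patient's true CTC-HER2 status is assigned first: within every
  tissue class the planted positivity rate is realized exactly over the
  evaluable (count > 0) patients, positives placed at random — the rate
  is a study condition, not a sampling target.  The HER2 bin occupancy
  is then drawn from class- and status-conditional multinomial weights and
  minimally repaired so the realized bins always encode the drawn
  status (a designated negative never holds an H3 cell or an excess H2
  ratio, a designated positive always triggers the call).  Planted
  rates are therefore exact, not emergent.
* Per-cell MFIs are log-normal, truncated to the bin's intensity range,
  so bin occupancy is exact by construction.
* All randomness flows from a single numpy Generator seeded once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    CountClass,
    CountComparator,
    CtcHer2Status,
    Group,
    Her2Bin,
    HER2_BINS,
    ScoringScheme,
    TissueHer2,
    ValidationError,
)

__all__ = [
    "CountModel",
    "BinIntensity",
    "ClassMfiModel",
    "OutcomeModel",
    "SurvivalModel",
    "CohortSpec",
    "SimulatedCohort",
    "generate_cohort",
]


@dataclass
class CountModel:
    """Zero-inflated negative binomial CTC count model for one class."""

    pi_zero: float  # structural-zero probability
    mean: float  # NB mean (of the non-inflated component)
    dispersion: float  # NB size parameter r; variance = mu + mu^2 / r

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_zero <= 1.0:
            raise ValidationError("pi_zero must lie in [0, 1]")
        if self.pi_zero < 1.0 and not self.mean > 0:
            raise ValidationError("NB mean must be positive")
        if not self.dispersion > 0:
            raise ValidationError("NB dispersion must be positive")

    @property
    def _nb_p(self) -> float:
        return self.dispersion / (self.dispersion + self.mean)

    def pmf(self, k: np.ndarray, cap: int) -> np.ndarray:
        """ZINB pmf on 0..cap with the tail mass folded onto the cap."""
        if self.pi_zero == 1.0:
            out = np.zeros(cap + 1)
            out[0] = 1.0
            return out
        base = (1 - self.pi_zero) * stats.nbinom.pmf(k, self.dispersion, self._nb_p)
        base[0] += self.pi_zero
        base[-1] += (1 - self.pi_zero) * float(
            stats.nbinom.sf(cap, self.dispersion, self._nb_p)
        )
        return base

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Inverse CDF of the ZINB (before capping)."""
        out = np.zeros(len(u), dtype=int)
        if self.pi_zero == 1.0:
            return out
        mask = u >= self.pi_zero
        out[mask] = stats.nbinom.ppf(
            (u[mask] - self.pi_zero) / (1 - self.pi_zero), self.dispersion, self._nb_p
        ).astype(int)
        return out


@dataclass
class BinIntensity:
    """Log-normal HER2 MFI component for one staining bin (truncated to
    the bin's intensity range when sampling)."""

    median: float
    sigma: float


@dataclass
class ClassMfiModel:
    """Status-conditional HER2 bin-weight templates for one tissue class.

    ``positive_rate`` is the planted probability that an evaluable
    patient of this class is CTC-HER2+.  ``neg_weights``/``pos_weights``
    are H0..H3 multinomial weights used for designated negative /
    positive patients.  Negative templates must put zero weight on H3
    (one H3 cell alone makes a patient positive).
    """

    positive_rate: float
    neg_weights: tuple[float, float, float, float]
    pos_weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_rate <= 1.0:
            raise ValidationError("positive_rate must lie in [0, 1]")
        for name in ("neg_weights", "pos_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if w.shape != (4,) or (w < 0).any() or w.sum() <= 0:
                raise ValidationError(f"{name} must be 4 non-negative weights")
            setattr(self, name, tuple(w / w.sum()))
        if self.neg_weights[3] > 0:
            raise ValidationError(
                "infeasible spec: negative template puts weight on H3, but a "
                "single H3 cell forces a positive call"
            )
        if self.positive_rate > 0 and (self.pos_weights[2] + self.pos_weights[3]) == 0:
            raise ValidationError(
                "infeasible spec: positive_rate > 0 requires H2/H3 weight in "
                "the positive template"
            )


@dataclass
class OutcomeModel:
    """Objective-response probabilities for treated (tissue HER2+)
    patients, by baseline count class and CTC-HER2 status."""

    p_response_low_count: float = 0.833
    p_response_high_pos: float = 0.60
    p_response_high_neg: float = 0.0
    p_cr_given_response: float = 0.1
    p_sd_given_no_response: float = 9 / 11

    def response_prob(self, count_class: CountClass, status: CtcHer2Status) -> float:
        if count_class is CountClass.LOW:
            return self.p_response_low_count
        if status is CtcHer2Status.POS:
            return self.p_response_high_pos
        return self.p_response_high_neg


@dataclass
class SurvivalModel:
    """Exponential PFS/OS with a planted LOW-vs-HIGH count hazard ratio.

    Default PFS median for the high-count class is 9.2 months with
    HR(low vs high) = 0.387; OS hazards are smaller (medians typically
    beyond follow-up) with the same planted ratio.  Follow-up is
    administratively censored uniformly on [12, 30] months.
    """

    pfs_median_high: float = 9.2
    pfs_hr_low_vs_high: float = 0.387
    os_median_high: float = 36.0
    os_hr_low_vs_high: float = 0.387
    followup_min: float = 12.0
    followup_max: float = 30.0

    def __post_init__(self) -> None:
        for name in ("pfs_hr_low_vs_high", "os_hr_low_vs_high"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    def rates(self, endpoint: str, count_class: CountClass) -> float:
        if endpoint == "pfs":
            base, hr = math.log(2) / self.pfs_median_high, self.pfs_hr_low_vs_high
        else:
            base, hr = math.log(2) / self.os_median_high, self.os_hr_low_vs_high
        return base if count_class is CountClass.HIGH else base * hr


_DEFAULT_COUNTS: dict[TissueHer2, CountModel] = {
    TissueHer2.NEG: CountModel(pi_zero=1 / 15, mean=35.0, dispersion=1.0),
    TissueHer2.LOW: CountModel(pi_zero=4 / 13, mean=12.0, dispersion=1.0),
    TissueHer2.POS: CountModel(pi_zero=5 / 24, mean=55.0, dispersion=1.0),
}

_DEFAULT_MFI: dict[TissueHer2, ClassMfiModel] = {
    # tissue-negative: never CTC-HER2+, all staining below the H2 range
    TissueHer2.NEG: ClassMfiModel(0.0, (0.80, 0.20, 0.0, 0.0), (0.5, 0.3, 0.15, 0.05)),
    # observed positivity 4/9 among evaluable HER2-low patients
    TissueHer2.LOW: ClassMfiModel(4 / 9, (0.70, 0.24, 0.06, 0.0), (0.40, 0.30, 0.25, 0.05)),
    # observed positivity 10/19 among evaluable HER2+ patients
    TissueHer2.POS: ClassMfiModel(10 / 19, (0.55, 0.35, 0.10, 0.0), (0.25, 0.30, 0.30, 0.15)),
}

_DEFAULT_BIN_INTENSITY: dict[Her2Bin, BinIntensity] = {
    Her2Bin.H0: BinIntensity(median=45.0, sigma=0.6),
    Her2Bin.H1: BinIntensity(median=200.0, sigma=0.45),
    Her2Bin.H2: BinIntensity(median=490.0, sigma=0.12),
    Her2Bin.H3: BinIntensity(median=800.0, sigma=0.35),
}


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort."""

    n_patients_by_class: dict[TissueHer2, int] = field(
        default_factory=lambda: {TissueHer2.NEG: 15, TissueHer2.LOW: 13, TissueHer2.POS: 24}
    )
    n_healthy: int = 10
    count_models: dict[TissueHer2, CountModel] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTS)
    )
    count_cap: int = 683
    healthy_count_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.7, 1: 0.2, 2: 0.1}
    )
    mfi_models: dict[TissueHer2, ClassMfiModel] = field(
        default_factory=lambda: dict(_DEFAULT_MFI)
    )
    bin_intensity: dict[Her2Bin, BinIntensity] = field(
        default_factory=lambda: dict(_DEFAULT_BIN_INTENSITY)
    )
    wbc_mean_per_sample: float = 40.0
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, n in self.n_patients_by_class.items():
            if n < 0:
                raise ValidationError(f"negative patient count for class {cls}")
        if self.n_healthy < 0:
            raise ValidationError("n_healthy must be >= 0")
        if self.count_cap < 1:
            raise ValidationError("count_cap must be >= 1")
        total = sum(self.healthy_count_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValidationError("healthy_count_probs must sum to 1")

    def scaled(self, n_patients: int) -> "CohortSpec":
        """Same model, cohort size scaled to ~``n_patients`` with the
        class composition preserved."""
        total = sum(self.n_patients_by_class.values())
        new = {
            cls: int(round(n * n_patients / total))
            for cls, n in self.n_patients_by_class.items()
        }
        return replace(self, n_patients_by_class=new)

    # -- planted quantities -------------------------------------------------

    def planted_count_stats(self) -> tuple[float, float]:
        """(zero fraction, mean) of the planted patient count
        distribution, cap included, weighted by class composition."""
        ks = np.arange(self.count_cap + 1)
        total = sum(self.n_patients_by_class.values())
        zero, mean = 0.0, 0.0
        for cls, n in self.n_patients_by_class.items():
            pmf = self.count_models[cls].pmf(ks, self.count_cap)
            zero += n / total * pmf[0]
            mean += n / total * float(ks @ pmf)
        return zero, mean

    def planted_positive_rate(self, cls: TissueHer2) -> float:
        """Planted CTC-HER2+ probability among evaluable patients."""
        return self.mfi_models[cls].positive_rate


def _stratified_uniforms(n: int, rng: np.random.Generator) -> np.ndarray:
    u = (np.arange(n) + rng.random(n)) / n
    return rng.permutation(u)


def _truncated_lognormal(
    n: int, comp: BinIntensity, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal(median, sigma) conditioned on [lo, hi)."""
    if n == 0:
        return np.zeros(0)
    mu = math.log(comp.median)
    dist = stats.lognorm(s=comp.sigma, scale=math.exp(mu))
    a, b = dist.cdf(lo), dist.cdf(hi) if np.isfinite(hi) else 1.0
    if b - a <= 0:
        # component entirely outside the bin: fall back to uniform in-bin
        upper = hi if np.isfinite(hi) else max(lo * 2, lo + 1)
        return rng.uniform(lo, upper, n)
    x = dist.ppf(a + rng.random(n) * (b - a))
    return np.clip(x, lo, np.nextafter(hi, -np.inf) if np.isfinite(hi) else x.max() + 1)


def _repair_bins(
    bins: np.ndarray, positive: bool, ratio_cutoff: float
) -> np.ndarray:
    """Minimally adjust a drawn H0..H3 occupancy so it encodes the
    designated status."""
    bins = bins.copy()
    total = int(bins.sum())
    if total == 0:
        return bins
    max_h2_neg = math.floor(ratio_cutoff * total)
    if not positive:
        excess = bins[2] - max_h2_neg
        if excess > 0:  # demote surplus H2 cells to H1
            bins[2] -= excess
            bins[1] += excess
        bins[1] += bins[3]  # defensive; neg templates carry no H3 weight
        bins[3] = 0
    else:
        if bins[3] == 0 and bins[2] <= max_h2_neg:
            donor = int(np.argmax(bins[:3]))  # promote one cell to H3
            bins[donor] -= 1
            bins[3] += 1
    return bins


@dataclass
class SimulatedCohort:
    cells: pd.DataFrame  # sample_id, cell_id, four MFIs, true_identity
    patients: pd.DataFrame  # clinical schema plus true_* columns
    spec: CohortSpec
    seed: int

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import CELL_COLUMNS, PATIENT_COLUMNS

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells[list(CELL_COLUMNS)].to_csv(outdir / "cells.csv", index=False)
        cols = [c for c in PATIENT_COLUMNS if c in self.patients.columns]
        self.patients[cols].to_csv(outdir / "patients.csv", index=False)


_IHC_ALLOC = {
    # (ihc, fish) composition within each tissue class, in study proportions
    TissueHer2.NEG: ((("0", "NA"), 1.0),),
    TissueHer2.LOW: ((("2+", "NEG"), 8 / 13), (("1+", "NA"), 5 / 13)),
    TissueHer2.POS: ((("3+", "NA"), 18 / 24), (("2+", "POS"), 6 / 24)),
}


def _allocate_ihc(cls: TissueHer2, n: int) -> list[tuple[str, str]]:
    alloc = _IHC_ALLOC[cls]
    counts = [int(round(frac * n)) for _, frac in alloc]
    counts[0] += n - sum(counts)
    out: list[tuple[str, str]] = []
    for (pair, _), c in zip(alloc, counts):
        out.extend([pair] * c)
    return out


def generate_cohort(
    spec: CohortSpec, seed: Optional[int] = None
) -> SimulatedCohort:
    """Draw a complete synthetic cohort (cells + patients + outcomes).

    Identical spec and seed produce identical output frames.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    scheme = spec.scheme
    edges = (0.0,) + scheme.bin_edges + (np.inf,)

    patient_rows: list[dict] = []
    cell_rows: list[dict] = []

    def add_cells(sample_id: str, identity: str, dapi, ck, cd45, her2) -> None:
        start = len(cell_rows)
        for i in range(len(dapi)):
            cell_rows.append(
                {
                    "sample_id": sample_id,
                    "cell_id": f"{sample_id}-c{start + i:04d}",
                    "mfi_dapi": float(dapi[i]),
                    "mfi_ck": float(ck[i]),
                    "mfi_cd45": float(cd45[i]),
                    "mfi_her2": float(her2[i]),
                    "true_identity": identity,
                }
            )

    def ctc_channels(n: int):
        dapi = rng.lognormal(math.log(500), 0.3, n)
        ck = rng.lognormal(math.log(300), 0.4, n)
        cd45 = rng.uniform(0.0, 30.0, n)
        return dapi, ck, cd45

    def wbc_channels(n: int):
        dapi = rng.lognormal(math.log(400), 0.3, n)
        ck = rng.uniform(0.0, 30.0, n)
        cd45 = rng.lognormal(math.log(300), 0.4, n)
        return dapi, ck, cd45

    pid_counter = 0
    for cls in (TissueHer2.NEG, TissueHer2.LOW, TissueHer2.POS):
        n_cls = spec.n_patients_by_class.get(cls, 0)
        if n_cls == 0:
            continue
        cm = spec.count_models[cls]
        counts = np.minimum(
            cm.ppf(_stratified_uniforms(n_cls, rng)), spec.count_cap
        )
        mfi_model = spec.mfi_models[cls]
        # realize the planted positivity rate exactly among evaluable
        # patients: round(rate * n_evaluable) positives, randomly placed
        positive = np.zeros(n_cls, dtype=bool)
        evaluable_idx = np.flatnonzero(counts > 0)
        n_pos = int(round(mfi_model.positive_rate * len(evaluable_idx)))
        if n_pos:
            chosen = rng.choice(evaluable_idx, size=n_pos, replace=False)
            positive[chosen] = True
        ihc = _allocate_ihc(cls, n_cls)

        for i in range(n_cls):
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            n_ctc = int(counts[i])
            is_pos = bool(positive[i]) and n_ctc > 0
            weights = mfi_model.pos_weights if is_pos else mfi_model.neg_weights
            bins = rng.multinomial(n_ctc, weights) if n_ctc else np.zeros(4, int)
            bins = _repair_bins(bins, is_pos, scheme.ratio_cutoff)

            her2 = np.concatenate(
                [
                    _truncated_lognormal(
                        int(bins[k]),
                        spec.bin_intensity[HER2_BINS[k]],
                        edges[k],
                        edges[k + 1],
                        rng,
                    )
                    for k in range(4)
                ]
            )
            her2 = rng.permutation(her2)
            dapi, ck, cd45 = ctc_channels(n_ctc)
            add_cells(pid, "CTC", dapi, ck, cd45, her2)

            n_wbc = int(rng.poisson(spec.wbc_mean_per_sample))
            wd, wk, wc = wbc_channels(n_wbc)
            wher2 = rng.lognormal(math.log(30), 0.5, n_wbc)
            add_cells(pid, "WBC", wd, wk, wc, wher2)

            if n_ctc == 0:
                status = CtcHer2Status.UNEVALUABLE
            elif is_pos:
                status = CtcHer2Status.POS
            else:
                status = CtcHer2Status.NEG
            high = (
                n_ctc >= scheme.count_cutoff
                if scheme.count_comparator is CountComparator.GE
                else n_ctc > scheme.count_cutoff
            )
            count_class = CountClass.HIGH if high else CountClass.LOW

            # treated (tissue HER2+) patients carry a best response
            if cls is TissueHer2.POS:
                p_resp = spec.outcome_model.response_prob(count_class, status)
                if rng.random() < p_resp:
                    resp = (
                        "CR"
                        if rng.random() < spec.outcome_model.p_cr_given_response
                        else "PR"
                    )
                else:
                    resp = (
                        "SD"
                        if rng.random() < spec.outcome_model.p_sd_given_no_response
                        else "PD"
                    )
            else:
                resp = "NA"

            followup = rng.uniform(
                spec.survival_model.followup_min, spec.survival_model.followup_max
            )
            t_pfs = rng.exponential(1 / spec.survival_model.rates("pfs", count_class))
            t_os = rng.exponential(1 / spec.survival_model.rates("os", count_class))
            pfs_event = t_pfs <= followup
            os_event = t_os <= followup

            patient_rows.append(
                {
                    "patient_id": pid,
                    "group": Group.PATIENT.value,
                    "ihc_score": ihc[i][0],
                    "fish": ihc[i][1],
                    "tissue_her2": cls.value,
                    "best_response": resp,
                    "pfs_months": round(min(t_pfs, followup), 3),
                    "pfs_event": int(pfs_event),
                    "os_months": round(min(t_os, followup), 3),
                    "os_event": int(os_event),
                    "true_ctc_count": n_ctc,
                    "true_ctc_her2_status": status.value,
                    "true_count_class": count_class.value,
                }
            )

    healthy_levels = np.array(sorted(spec.healthy_count_probs))
    healthy_p = np.array([spec.healthy_count_probs[k] for k in healthy_levels])
    for i in range(spec.n_healthy):
        pid = f"H{i + 1:04d}"
        n_ctc = int(rng.choice(healthy_levels, p=healthy_p))
        # the few epithelial cells in donors stain like tissue-negative CTCs
        her2 = _truncated_lognormal(
            n_ctc, spec.bin_intensity[Her2Bin.H0], 0.0, scheme.bin_edges[0], rng
        )
        dapi, ck, cd45 = ctc_channels(n_ctc)
        add_cells(pid, "CTC", dapi, ck, cd45, her2)
        n_wbc = int(rng.poisson(spec.wbc_mean_per_sample))
        wd, wk, wc = wbc_channels(n_wbc)
        add_cells(pid, "WBC", wd, wk, wc, rng.lognormal(math.log(30), 0.5, n_wbc))
        patient_rows.append(
            {
                "patient_id": pid,
                "group": Group.HEALTHY.value,
                "ihc_score": "NA",
                "fish": "NA",
                "tissue_her2": TissueHer2.NA.value,
                "best_response": "NA",
                "pfs_months": "NA",
                "pfs_event": "NA",
                "os_months": "NA",
                "os_event": "NA",
                "true_ctc_count": n_ctc,
                "true_ctc_her2_status": (
                    CtcHer2Status.UNEVALUABLE.value
                    if n_ctc == 0
                    else CtcHer2Status.NEG.value
                ),
                "true_count_class": CountClass.LOW.value,
            }
        )

    cells = pd.DataFrame(
        cell_rows,
        columns=[
            "sample_id",
            "cell_id",
            "mfi_dapi",
            "mfi_ck",
            "mfi_cd45",
            "mfi_her2",
            "true_identity",
        ],
    )
    patients = pd.DataFrame(patient_rows)
    return SimulatedCohort(cells=cells, patients=patients, spec=spec, seed=seed)
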