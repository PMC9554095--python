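"""Diagnostic-accuracy statistics: ROC/AUC, sensitivity/specificity with
Wilson score intervals, and the simple two-sample comparisons.

Conventions
-----------
* ROC assumes "higher score = more positive"; a subject is predicted
  positive when its score is >= the threshold.
* AUC is computed by the Mann-Whitney identity (ties count 1/2) and its
  CI by the Hanley-McNeil standard error.
* Proportion CIs use the Wilson score interval with z = 1.959964.
* All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "wilson_interval",
    "ROCResult",
    "roc_curve",
    "DiagnosticMetrics",
    "diagnostic_metrics",
    "welch_t",
    "pearson_r",
]

Z_95 = 1.959964  # two-sided 95% normal quantile, to the precision used throughout


def wilson_interval(k: int, n: int, z: float = Z_95) -> tuple[float, float]:
    """Wilson score 95% CI for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # the interval is exactly [*, 1] at k = n and [0, *] at k = 0;
    # guard against floating-point shrinkage there
    lo = 0.0 if k == 0 else max(0.0, float(center - half))
    hi = 1.0 if k == n else min(1.0, float(center + half))
    return (lo, hi)


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending; predict positive when score >= threshold
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def youden_optimal(self) -> tuple[float, float]:
        """(threshold, J) maximizing Youden's J; ties toward smaller threshold."""
        j = self.sensitivity + self.specificity - 1.0
        best = len(j) - 1 - int(np.argmax(j[::-1]))  # last index = smallest threshold
        return float(self.thresholds[best]), float(j[best])

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
        }


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return (max(0.0, auc - Z_95 * se), min(1.0, auc + Z_95 * se))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC of ``scores`` against binary ``labels``.

    Thresholds are the unique observed scores (descending) plus a
    sentinel above the maximum, so the curve runs from (0, 0) to (1, 1)
    in (FPR, TPR) space.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])

    # Mann-Whitney identity: AUC = (R1 - n1(n1+1)/2) / (n1 n2), midranks for ties
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=_hanley_mcneil_ci(auc, n_pos, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass
class DiagnosticMetrics:
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "sensitivity_ci": None if self.sensitivity_ci is None else list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": None if self.specificity_ci is None else list(self.specificity_ci),
            "note": self.note,
        }


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> DiagnosticMetrics:
    """Sensitivity and specificity with Wilson 95% CIs.

    A zero denominator makes the corresponding metric None with an
    explanatory note instead of raising.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    notes = []
    if tp + fn > 0:
        sens = tp / (tp + fn)
        sens_ci = wilson_interval(tp, tp + fn)
    else:
        sens, sens_ci = None, None
        notes.append("sensitivity NA: no positive subjects (tp + fn = 0)")
    if tn + fp > 0:
        spec = tn / (tn + fp)
        spec_ci = wilson_interval(tn, tn + fp)
    else:
        spec, spec_ci = None, None
        notes.append("specificity NA: no negative subjects (tn + fp = 0)")
    return DiagnosticMetrics(
        sens, sens_ci, spec, spec_ci, note="; ".join(notes) or None
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired t-test with Welch's correction.

    Returns (t statistic, Welch-Satterthwaite df, two-sided p).  Two
    zero-variance samples with equal means give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), float(
            len(x) + len(y) - 2
        ), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("correlation undefined for a constant sample")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
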