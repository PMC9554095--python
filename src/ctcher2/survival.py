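"""Kaplan-Meier estimation, the log-rank (Mantel-Cox) test and the
Mantel-Haenszel hazard ratio.

The Kaplan-Meier curve is fit with lifelines.  The log-rank machinery
is implemented here directly from the pooled event-time risk tables,
because the hazard ratio is reported in the Mantel-Haenszel O/E form
HR = (O1/E1) / (O2/E2) with a log-rank-based CI — the convention of
the classic clinical-graphing packages — rather than via Cox
regression (which is out of scope).

Ties at event times are handled by the standard pooled (Breslow-style)
counting: all events at a time are compared against the full risk set
at that time.  Subjects with zero follow-up time are excluded with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .records import SurvivalRecord

__all__ = [
    "KaplanMeierEstimate",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "HazardRatioResult",
    "hazard_ratio",
]

Z_95 = 1.959964


def _split(records: Sequence[SurvivalRecord]):
    kept = [r for r in records if r.time > 0]
    dropped = len(records) - len(kept)
    if dropped:
        warnings.warn(
            f"excluded {dropped} record(s) with zero follow-up time", stacklevel=3
        )
    return kept


@dataclass
class KaplanMeierEstimate:
    """Product-limit estimate: a right-continuous step function."""

    times: np.ndarray  # event times where the curve steps
    survival: np.ndarray  # S(t) just after each step
    median: Optional[float]  # earliest t with S(t) <= 0.5; None = not reached
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t) for any t >= 0 (S = 1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "median": self.median,
            "n": self.n,
            "n_events": self.n_events,
        }


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator over one group.

    The median is the earliest time at which the curve reaches 0.5 or
    below; if the curve never does (heavy censoring), the median is
    reported as not reached (None).
    """
    records = _split(records)
    if not records:
        raise ValueError("no usable survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    event_times = np.unique(times[events])
    surv = np.array([float(sf.loc[t].iloc[0]) for t in event_times])
    median = float(kmf.median_survival_time_)
    return KaplanMeierEstimate(
        times=event_times,
        survival=surv,
        median=None if np.isinf(median) else median,
        n=len(records),
        n_events=int(events.sum()),
    )


def _risk_tables(records: Sequence[SurvivalRecord]):
    """Per-event-time observed/expected/variance sums over groups."""
    groups = sorted({r.group for r in records})
    g_index = {g: i for i, g in enumerate(groups)}
    k = len(groups)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    gidx = np.array([g_index[r.group] for r in records])

    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int((events & (times == t)).sum())
        n_g = np.array([int((at_risk & (gidx == i)).sum()) for i in range(k)])
        d_g = np.array(
            [int((events & (times == t) & (gidx == i)).sum()) for i in range(k)]
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            var += v
    return groups, observed, expected, var


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    groups: list[str]
    observed: dict[str, float]
    expected: dict[str, float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "observed": self.observed,
            "expected": self.expected,
            "degenerate": self.degenerate,
        }


def logrank_test(records: Sequence[SurvivalRecord]) -> LogrankResult:
    """Mantel-Cox log-rank test across the groups labeled in ``records``.

    The chi-square statistic has (number of groups - 1) degrees of
    freedom.  With no events at all the test is degenerate: statistic
    0, p = 1.
    """
    records = _split(records)
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if not any(r.event for r in records):
        return LogrankResult(
            0.0, 1.0, len(groups) - 1, groups,
            {g: 0.0 for g in groups}, {g: 0.0 for g in groups}, degenerate=True,
        )
    groups, observed, expected, var = _risk_tables(records)
    z = (observed - expected)[:-1]
    v = var[:-1, :-1]
    stat = float(z @ np.linalg.pinv(v) @ z)
    df = len(groups) - 1
    p = float(stats.chi2.sf(stat, df))
    return LogrankResult(
        stat,
        p,
        df,
        list(groups),
        {g: float(o) for g, o in zip(groups, observed)},
        {g: float(e) for g, e in zip(groups, expected)},
    )


@dataclass
class HazardRatioResult:
    hr: float
    ci: tuple[Optional[float], Optional[float]]
    group_a: str
    group_b: str
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "hr": self.hr,
            "ci": list(self.ci),
            "group_a": self.group_a,
            "group_b": self.group_b,
            "observed": {self.group_a: self.o_a, self.group_b: self.o_b},
            "expected": {self.group_a: self.e_a, self.group_b: self.e_b},
            "warning": self.warning,
        }


def hazard_ratio(
    records: Sequence[SurvivalRecord],
    group_a: Optional[str] = None,
    group_b: Optional[str] = None,
) -> HazardRatioResult:
    """Mantel-Haenszel hazard ratio of ``group_a`` relative to ``group_b``.

    HR = (O_a / E_a) / (O_b / E_b) with the 95% CI
    exp(log HR +/- z * sqrt(1/E_a + 1/E_b)).  When one group has zero
    observed events the ratio degenerates (0 or inf); the finite CI
    bound is still reported, with a warning.
    """
    records = _split(records)
    groups = sorted({r.group for r in records})
    if len(groups) != 2 and (group_a is None or group_b is None):
        raise ValueError("hazard_ratio needs exactly two groups (or explicit names)")
    if group_a is None:
        group_a, group_b = groups
    keep = [r for r in records if r.group in (group_a, group_b)]
    if not any(r.event for r in keep):
        raise ValueError("hazard ratio undefined with zero events")
    names, observed, expected, _ = _risk_tables(keep)
    idx = {g: i for i, g in enumerate(names)}
    o_a, e_a = observed[idx[group_a]], expected[idx[group_a]]
    o_b, e_b = observed[idx[group_b]], expected[idx[group_b]]
    warning = None
    se = float(np.sqrt(1 / e_a + 1 / e_b))
    if o_a == 0 or o_b == 0:
        hr = 0.0 if o_a == 0 else float("inf")
        warning = "zero events in one group; hazard ratio degenerate, CI one-sided"
        ci = (None, None)
    else:
        hr = float((o_a / e_a) / (o_b / e_b))
        ci = (hr * float(np.exp(-Z_95 * se)), hr * float(np.exp(Z_95 * se)))
    return HazardRatioResult(
        hr, ci, group_a, group_b, float(o_a), float(e_a), float(o_b), float(e_b),
        warning=warning,
    )
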