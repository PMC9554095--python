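"""Exact contingency-table inference and agreement measures.

Fisher's exact test and its R x C generalization (Freeman-Halton) are
implemented by full enumeration of all tables sharing the observed
margins.  The two-sided p-value follows the point-probability rule: it
is the total (multivariate hypergeometric) probability of every
same-margin table whose point probability does not exceed that of the
observed table.  This is the rule that reproduces the printed p-values
of standard statistical packages for small clinical tables.

Numerics: point probabilities are evaluated in log space via
log-gamma, but the "does not exceed" comparison is performed on exact
big-integer products of cell factorials (P(T) is proportional to
1 / prod(n_ij!) once the margins are fixed), so ties are resolved
exactly rather than by a floating-point tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .records import BestResponse, ContingencyTable, ValidationError

__all__ = [
    "CapacityError",
    "FisherResult",
    "fisher_exact_2x2",
    "fisher_freeman_halton",
    "cohen_kappa",
    "concordance_rate",
    "ResponseRates",
    "response_rates",
]

MAX_DIM = 4
MAX_N = 200
MAX_TABLES = 5_000_000


class CapacityError(ValueError):
    """The table is too large for exhaustive enumeration."""


@lru_cache(maxsize=512)
def _factorial(n: int) -> int:
    return math.factorial(n)


def _enumerate_tables(
    rows: tuple[int, ...], cols: tuple[int, ...]
) -> Iterator[tuple[int, ...]]:
    """Yield every non-negative integer table with the given margins,
    flattened row-major."""
    n_rows, n_cols = len(rows), len(cols)

    def fill(row_idx: int, remaining_cols: tuple[int, ...], acc: tuple[int, ...]):
        if row_idx == n_rows - 1:
            # last row forced by the column margins
            yield acc + remaining_cols
            return
        r = rows[row_idx]

        def fill_row(col_idx: int, left: int, row_acc: tuple[int, ...]):
            if col_idx == n_cols - 1:
                if left <= remaining_cols[col_idx]:
                    yield row_acc + (left,)
                return
            hi = min(left, remaining_cols[col_idx])
            # leave enough for the rest of the row
            lo = max(0, left - sum(remaining_cols[col_idx + 1 :]))
            for v in range(lo, hi + 1):
                yield from fill_row(col_idx + 1, left - v, row_acc + (v,))

        for row in fill_row(0, r, ()):
            rem = tuple(c - v for c, v in zip(remaining_cols, row))
            yield from fill(row_idx + 1, rem, acc + row)

    yield from fill(0, cols, ())


def _table_count_bound(rows: Sequence[int], cols: Sequence[int]) -> int:
    bound = 1
    for r in rows[:-1]:
        for c in cols[:-1]:
            bound *= min(r, c) + 1
            if bound > MAX_TABLES:
                return bound
    return bound


def _exact_p(table: ContingencyTable) -> tuple[float, bool]:
    """Point-probability two-sided p by enumeration.

    Returns (p, degenerate); degenerate is True when a margin is zero,
    in which case p = 1 by convention (no evidence against independence
    is obtainable from a collapsed table).
    """
    counts = table.counts
    rows = tuple(int(v) for v in counts.sum(axis=1))
    cols = tuple(int(v) for v in counts.sum(axis=0))
    if min(rows) == 0 or min(cols) == 0:
        return 1.0, True
    r_dim, c_dim = counts.shape
    n = sum(rows)
    if r_dim > MAX_DIM or c_dim > MAX_DIM or n > MAX_N:
        raise CapacityError(
            f"{r_dim}x{c_dim} table with N={n} exceeds the enumeration limits "
            f"({MAX_DIM}x{MAX_DIM}, N<={MAX_N})"
        )
    if _table_count_bound(rows, cols) > MAX_TABLES:
        raise CapacityError(
            "margins admit too many tables for exhaustive enumeration"
        )

    log_k = (
        sum(gammaln(r + 1) for r in rows)
        + sum(gammaln(c + 1) for c in cols)
        - gammaln(n + 1)
    )
    obs_denom = math.prod(_factorial(int(v)) for v in counts.ravel())
    terms = []
    for flat in _enumerate_tables(rows, cols):
        denom = math.prod(_factorial(v) for v in flat)
        if denom >= obs_denom:  # exact: P(T) <= P(observed)
            log_p = log_k - float(sum(gammaln(v + 1) for v in flat))
            terms.append(math.exp(log_p))
    return min(1.0, math.fsum(terms)), False


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: Optional[float] = None
    degenerate: bool = False
    haldane_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "odds_ratio": self.odds_ratio,
            "degenerate": self.degenerate,
            "haldane_corrected": self.haldane_corrected,
        }


def fisher_exact_2x2(table: ContingencyTable) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The odds ratio is the sample odds ratio ad/bc, with the Haldane
    correction (+0.5 to every cell) when any cell is zero.  A table
    with a zero margin returns p = 1 flagged degenerate.
    """
    if table.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    p, degenerate = _exact_p(table)
    a, b = table.counts[0]
    c, d = table.counts[1]
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    odds = float(a * d / (b * c))
    return FisherResult(p, odds, degenerate=degenerate, haldane_corrected=corrected)


def fisher_freeman_halton(table: ContingencyTable) -> FisherResult:
    """Freeman-Halton exact test on an R x C table (R, C <= 4, N <= 200).

    On 2x2 input it coincides with :func:`fisher_exact_2x2` (same
    enumeration).  No chi-square fallback exists: tables beyond the
    enumeration limits raise :class:`CapacityError`.
    """
    p, degenerate = _exact_p(table)
    return FisherResult(p, None, degenerate=degenerate)


def cohen_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa for a square agreement table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal fraction and
    p_e the chance agreement from the margins.  Non-square input is
    refused: callers must collapse categories explicitly so that the
    collapse is a visible, auditable choice.
    """
    r, c = table.shape
    if r != c:
        raise ValidationError(
            "kappa requires a square table; collapse categories explicitly first"
        )
    n = table.n
    if n == 0:
        raise ValidationError("kappa undefined for an empty table")
    p_o = float(np.trace(table.counts)) / n
    p_e = float(table.row_margins() @ table.col_margins()) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def concordance_rate(
    table: ContingencyTable, concordant_cells: Sequence[tuple[int, int]]
) -> tuple[float, int, int]:
    """Fraction of subjects in the designated concordant cells.

    Returns (rate, numerator, denominator).
    """
    n = table.n
    if n == 0:
        raise ValidationError("concordance undefined for an empty table")
    r, c = table.shape
    seen = set()
    num = 0
    for i, j in concordant_cells:
        if not (0 <= i < r and 0 <= j < c):
            raise ValidationError(f"cell index ({i}, {j}) outside the table")
        if (i, j) in seen:
            continue
        seen.add((i, j))
        num += int(table.counts[i, j])
    return num / n, num, n


@dataclass
class ResponseRates:
    orr: float  # objective response rate, (CR + PR) / n
    dcr: float  # disease control rate, (CR + PR + SD) / n
    n: int
    n_excluded: int  # NA responses left out of the denominator

    def to_dict(self) -> dict:
        return {"orr": self.orr, "dcr": self.dcr, "n": self.n, "n_excluded": self.n_excluded}


def response_rates(responses: Sequence[BestResponse | str]) -> ResponseRates:
    """ORR and DCR over RECIST best-response categories.

    NA entries are excluded from the denominator and their count is
    reported.
    """
    cats = [BestResponse(r) for r in responses]
    usable = [r for r in cats if r is not BestResponse.NA]
    n_excluded = len(cats) - len(usable)
    if not usable:
        raise ValidationError("no evaluable responses")
    n = len(usable)
    obj = sum(r in (BestResponse.CR, BestResponse.PR) for r in usable)
    ctrl = obj + sum(r is BestResponse.SD for r in usable)
    return ResponseRates(obj / n, ctrl / n, n, n_excluded)
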