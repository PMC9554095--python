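"""Exact contingency-table tests, kappa, concordance and response rates."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher
from sklearn.metrics import cohen_kappa_score

from ctcher2 import (
    CapacityError,
    ContingencyTable,
    ValidationError,
    cohen_kappa,
    concordance_rate,
    fisher_exact_2x2,
    fisher_freeman_halton,
    response_rates,
)


def exact_tables(rows, cols):
    """Independent oracle enumeration: brute force over cell values via
    itertools, not the package's margin-constrained recursion."""
    n_r, n_c = len(rows), len(cols)
    free = [(i, j) for i in range(n_r - 1) for j in range(n_c - 1)]
    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free]
    for combo in itertools.product(*ranges):
        t = np.zeros((n_r, n_c), dtype=int)
        for (i, j), v in zip(free, combo):
            t[i, j] = v
        t[:-1, -1] = rows[:-1] - t[:-1, :-1].sum(axis=1)
        t[-1, :] = cols - t[:-1, :].sum(axis=0)
        if (t >= 0).all():
            yield t


def oracle_p(table: np.ndarray) -> Fraction:
    """Exact rational point-probability two-sided p."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    denom_const = Fraction(
        math.prod(math.factorial(int(r)) for r in rows)
        * math.prod(math.factorial(int(c)) for c in cols),
        math.factorial(n),
    )

    def prob(t):
        return denom_const / math.prod(math.factorial(int(v)) for v in t.ravel())

    p_obs = prob(table)
    return sum(prob(t) for t in exact_tables(rows, cols) if prob(t) <= p_obs)


class TestFisher2x2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[5, 1], [0, 5]], 7 / 462),  # = 0.015 printed
            ([[1, 1], [1, 1]], 1.0),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[5, 1], [6, 10]], None),  # checked against scipy below
        ],
    )
    def test_point_probability_rule(self, table, expected):
        res = fisher_exact_2x2(ContingencyTable(table))
        ref = expected if expected is not None else scipy_fisher(table)[1]
        assert res.p_value == pytest.approx(ref, abs=1e-12)

    def test_zero_margin_degenerate(self):
        res = fisher_exact_2x2(ContingencyTable([[0, 0], [3, 4]]))
        assert res.p_value == 1.0
        assert res.degenerate

    def test_haldane_odds_ratio_on_zero_cell(self):
        res = fisher_exact_2x2(ContingencyTable([[5, 0], [2, 3]]))
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx((5.5 * 3.5) / (0.5 * 2.5))

    def test_plain_odds_ratio(self):
        res = fisher_exact_2x2(ContingencyTable([[6, 2], [3, 9]]))
        assert res.odds_ratio == pytest.approx(9.0)
        assert not res.haldane_corrected

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_transpose_and_double_swap(self, cells):
        a, b, c, d = cells
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        base = fisher_exact_2x2(ContingencyTable([[a, b], [c, d]])).p_value
        transposed = fisher_exact_2x2(ContingencyTable([[a, c], [b, d]])).p_value
        swapped = fisher_exact_2x2(ContingencyTable([[d, c], [b, a]])).p_value
        assert transposed == pytest.approx(base, abs=1e-12)
        assert swapped == pytest.approx(base, abs=1e-12)

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(0, 16, (2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            ours = fisher_exact_2x2(ContingencyTable(t)).p_value
            assert ours == pytest.approx(scipy_fisher(t)[1], abs=1e-10)


class TestFreemanHalton:
    def test_agreement_table_p(self):
        """The tissue-vs-CTC HER2 agreement table gives p = 0.002."""
        res = fisher_freeman_halton(ContingencyTable([[14, 5, 9], [0, 4, 10]]))
        assert res.p_value == pytest.approx(0.002, abs=5e-4)

    def test_independence_table_p_one(self):
        # outer product of margins / N: the most probable table
        res = fisher_freeman_halton(ContingencyTable([[2, 4, 6], [1, 2, 3]]))
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_reduces_to_2x2(self, rng):
        for _ in range(30):
            t = rng.integers(0, 12, (2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_freeman_halton(ContingencyTable(t)).p_value == pytest.approx(
                fisher_exact_2x2(ContingencyTable(t)).p_value, abs=1e-12
            )

    def test_capacity_error_instead_of_approximation(self):
        with pytest.raises(CapacityError):
            fisher_freeman_halton(ContingencyTable(np.full((2, 2), 60)))
        with pytest.raises(CapacityError):
            # 5x5: beyond the supported table family
            fisher_freeman_halton(ContingencyTable(np.ones((5, 5), dtype=int)))

    def test_matches_exact_rational_oracle(self, rng):
        """Oracle equivalence on random R x C tables (N <= 60):
        p agreement to 1e-10 against Fraction-exact brute force."""
        checked = 0
        while checked < 60:
            shape = [(2, 2), (2, 3), (3, 3)][int(rng.integers(0, 3))]
            t = rng.integers(0, 7, shape)
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0 or t.sum() > 60:
                continue
            ours = fisher_freeman_halton(ContingencyTable(t)).p_value
            assert ours == pytest.approx(float(oracle_p(t)), abs=1e-10)
            checked += 1

    def test_enumerated_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            t = rng.integers(1, 6, (2, 3))
            rows, cols = t.sum(axis=1), t.sum(axis=0)
            total = sum(
                Fraction(
                    math.prod(math.factorial(int(r)) for r in rows)
                    * math.prod(math.factorial(int(c)) for c in cols),
                    math.factorial(int(t.sum())),
                )
                / math.prod(math.factorial(int(v)) for v in tab.ravel())
                for tab in exact_tables(rows, cols)
            )
            assert total == 1


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ContingencyTable([[5, 0], [0, 7]])) == pytest.approx(1.0)

    def test_chance_agreement(self):
        # outer product of margins: kappa = 0
        assert cohen_kappa(ContingencyTable([[4, 4], [4, 4]])) == pytest.approx(0.0)

    def test_collapsed_agreement_table(self):
        # tissue non-HER2+ vs HER2+ against the CTC call
        assert cohen_kappa(ContingencyTable([[19, 4], [9, 10]])) == pytest.approx(
            0.361, abs=5e-4
        )

    def test_non_square_refused(self):
        with pytest.raises(ValidationError, match="square"):
            cohen_kappa(ContingencyTable([[1, 2, 3], [4, 5, 6]]))

    def test_matches_sklearn_on_expanded_labels(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, (3, 3))
            if t.sum() == 0 or np.trace(t) == t.sum():
                continue
            a = np.repeat(np.arange(3), t.sum(axis=1))
            b = np.concatenate([np.repeat(np.arange(3), row) for row in t])
            assert cohen_kappa(ContingencyTable(t)) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    @given(st.lists(st.integers(0, 10), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_one(self, cells):
        t = np.array(cells).reshape(2, 2)
        if t.sum() == 0:
            return
        k = cohen_kappa(ContingencyTable(t))
        assert k <= 1.0 + 1e-12
        if k == pytest.approx(1.0):
            assert t[0, 1] == t[1, 0] == 0


class TestConcordance:
    def test_agreement_table_rate(self):
        rate, num, den = concordance_rate(
            ContingencyTable([[14, 5, 9], [0, 4, 10]]), [(0, 0), (0, 1), (1, 2)]
        )
        assert (num, den) == (29, 42)
        assert rate == pytest.approx(29 / 42)

    def test_diagonal_is_total(self):
        rate, _, _ = concordance_rate(
            ContingencyTable([[3, 0], [0, 4]]), [(0, 0), (1, 1)]
        )
        assert rate == 1.0

    def test_single_off_diagonal_is_zero(self):
        rate, _, _ = concordance_rate(ContingencyTable([[0, 5], [0, 0]]), [(0, 0)])
        assert rate == 0.0


class TestResponseRates:
    def test_study_composition(self):
        rr = response_rates(["PR"] * 11 + ["SD"] * 9 + ["PD"] * 2)
        assert rr.orr == pytest.approx(0.50)
        assert rr.dcr == pytest.approx(20 / 22)

    def test_extremes_and_na_exclusion(self):
        assert response_rates(["PD", "PD"]).orr == 0.0
        assert response_rates(["CR", "CR"]).orr == 1.0
        rr = response_rates(["CR", "NA", "PD"])
        assert (rr.n, rr.n_excluded) == (2, 1)
        assert rr.orr == pytest.approx(0.5)
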