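"""Kaplan-Meier, log-rank and Mantel-Haenszel hazard-ratio machinery."""

import numpy as np
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from lifelines.statistics import multivariate_logrank_test

from ctcher2 import SurvivalRecord, hazard_ratio, km_estimate, logrank_test


def recs(times, events, group="A", prefix="p"):
    return [
        SurvivalRecord(patient_id=f"{group}{prefix}{i}", time=t, event=e, group=group)
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        km = km_estimate(recs([1, 2, 3, 4], [1, 1, 1, 1]))
        assert km.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(recs([5, 6, 7], [0, 0, 0]))
        assert km.at(100) == 1.0
        assert km.median is None  # not reached

    def test_hand_product_limit_with_censoring(self):
        # times {1, 2+, 3}: S(1) = 2/3, S(3) = 0
        km = km_estimate(recs([1, 2, 3], [1, 0, 1]))
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_nonincreasing_right_continuous(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50).astype(bool)
        km = km_estimate(recs(times, events))
        assert (np.diff(km.survival) <= 1e-12).all()
        assert km.at(0) == 1.0

    def test_no_censoring_matches_ecdf_random(self, rng):
        times = np.round(rng.exponential(5, 40), 2)
        km = km_estimate(recs(times, np.ones(40, bool)))
        for t in [0.5, 2.0, 5.0, 20.0]:
            assert km.at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_zero_followup_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero follow-up"):
            km = km_estimate(recs([0, 1, 2], [1, 1, 1]))
        assert km.n == 2


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = recs([1, 2, 3, 4], [1, 1, 0, 1], "A")
        b = recs([1, 2, 3, 4], [1, 1, 0, 1], "B")
        res = logrank_test(a + b)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_significant(self):
        a = recs(np.arange(1, 11), np.ones(10), "A")
        b = recs(np.arange(20, 30), np.ones(10), "B")
        assert logrank_test(a + b).p_value < 0.01

    def test_no_events_degenerate(self):
        res = logrank_test(recs([1, 2], [0, 0], "A") + recs([3], [0], "B"))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_hand_computed_observed_expected(self):
        # A: 1, 2, 3 (all events); B: 2, 4, 5 (all events)
        # event times 1,2,3,4,5 with risk sets 6,5,3,2,1:
        # E_A = 3/6 + 2*(2/5) + 1/3 = 1.6333...; O_A = 3
        res = logrank_test(recs([1, 2, 3], [1, 1, 1], "A") + recs([2, 4, 5], [1, 1, 1], "B"))
        assert res.observed["A"] == 3.0
        assert res.expected["A"] == pytest.approx(3 / 6 + 4 / 5 + 1 / 3)
        assert res.observed["B"] == 3.0
        assert res.expected["B"] == pytest.approx(6 - (3 / 6 + 4 / 5 + 1 / 3))

    def test_matches_lifelines_two_groups(self, rng):
        for _ in range(20):
            ta, tb = rng.exponential(10, 15), rng.exponential(6, 12)
            ea, eb = rng.integers(0, 2, 15), rng.integers(0, 2, 12)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(recs(ta, ea, "A") + recs(tb, eb, "B"))
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_matches_lifelines_three_groups(self, rng):
        times = rng.exponential(8, 45)
        events = np.ones(45, bool)
        groups = np.repeat(["A", "B", "C"], 15)
        records = [
            SurvivalRecord(patient_id=str(i), time=t, event=e, group=g)
            for i, (t, e, g) in enumerate(zip(times, events, groups))
        ]
        res = logrank_test(records)
        ref = multivariate_logrank_test(times, groups, events)
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_invariant_to_relabeling(self, rng):
        ta, tb = rng.exponential(10, 12), rng.exponential(5, 12)
        a = recs(ta, np.ones(12), "A") + recs(tb, np.ones(12), "B")
        b = recs(ta, np.ones(12), "B") + recs(tb, np.ones(12), "A")
        assert logrank_test(a).statistic == pytest.approx(
            logrank_test(b).statistic, abs=1e-10
        )


class TestHazardRatio:
    def test_exchangeable_groups_hr_one(self):
        a = recs([1, 2, 3, 4, 6], [1, 1, 1, 0, 1], "A")
        b = recs([1, 2, 3, 4, 6], [1, 1, 1, 0, 1], "B")
        assert hazard_ratio(a + b).hr == pytest.approx(1.0)

    def test_direction_earlier_events_higher_hazard(self):
        a = recs(np.arange(1, 11), np.ones(10), "A")
        b = recs(np.arange(20, 30), np.ones(10), "B")
        assert hazard_ratio(a + b, "A", "B").hr > 1.0

    def test_hand_computed_oe_ratio(self):
        # A: 1, 3 events; B: 2, 4 events (4-vs-4 with two censored each)
        records = recs([1, 3, 5, 6], [1, 1, 0, 0], "A") + recs(
            [2, 4, 7, 8], [1, 1, 0, 0], "B"
        )
        res = hazard_ratio(records, "A", "B")
        # risk sets at times 1,2,3,4: (A,B) = (4,4),(3,4),(3,3),(2,3)
        e_a = 4 / 8 + 3 / 7 + 3 / 6 + 2 / 5
        e_b = 4 - e_a
        assert res.hr == pytest.approx((2 / e_a) / (2 / e_b))

    def test_inversion_symmetry(self, rng):
        records = recs(rng.exponential(10, 20), np.ones(20), "A") + recs(
            rng.exponential(4, 20), np.ones(20), "B"
        )
        ab = hazard_ratio(records, "A", "B").hr
        ba = hazard_ratio(records, "B", "A").hr
        assert ab == pytest.approx(1 / ba, abs=1e-10)

    def test_zero_event_group_flagged(self):
        records = recs([1, 2, 3], [1, 1, 1], "A") + recs([5, 6, 7], [0, 0, 0], "B")
        res = hazard_ratio(records, "B", "A")
        assert res.hr == 0.0
        assert res.warning is not None


class TestPlantedRecovery:
    def test_exponential_hr_04_recovered(self):
        """Exponential arms with planted HR = 0.4 (n = 200/arm): the
        Mantel-Haenszel estimate lands in (0.3, 0.53) and the log-rank
        test is decisive."""
        rng = np.random.default_rng(1234)
        a = recs(rng.exponential(1 / 0.4, 200), np.ones(200), "low")
        b = recs(rng.exponential(1.0, 200), np.ones(200), "high")
        res = hazard_ratio(a + b, "low", "high")
        assert 0.3 < res.hr < 0.53
        assert logrank_test(a + b).p_value < 0.001
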