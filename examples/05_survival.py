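"""Kaplan-Meier curves, log-rank test and Mantel-Haenszel hazard ratio
for progression-free survival by baseline CTC count class.
"""

import numpy as np

from ctcher2 import SurvivalRecord, hazard_ratio, km_estimate, logrank_test

rng = np.random.default_rng(1)
# low-count patients progress at ~0.387x the hazard of high-count ones,
# with follow-up censored administratively between 12 and 30 months
lam_high = np.log(2) / 9.2


def arm(rate, n, name):
    t = rng.exponential(1 / rate, n)
    cens = rng.uniform(12, 30, n)
    return [
        SurvivalRecord(f"{name}{i}", min(a, b), bool(a <= b), name)
        for i, (a, b) in enumerate(zip(t, cens))
    ]


low = arm(lam_high * 0.387, 16, "low")
high = arm(lam_high, 36, "high")

for name, grp in (("<3 CTCs", low), (">=3 CTCs", high)):
    km = km_estimate(grp)
    med = "not reached" if km.median is None else f"{km.median:.1f} months"
    print(f"  {name}: n = {km.n}, events = {km.n_events}, median PFS {med}")

lr = logrank_test(low + high)
hr = hazard_ratio(low + high, "low", "high")
print(f"log-rank chi2 = {lr.statistic:.2f}, p = {lr.p_value:.3f}")
print(f"HR (<3 vs >=3) = {hr.hr:.3f}, 95% CI ({hr.ci[0]:.3f}, {hr.ci[1]:.3f})")
# HR < 1 means the low-count group progresses more slowly; at n = 52
# the CI is wide — single-draw counts are prognostic but imprecise.
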