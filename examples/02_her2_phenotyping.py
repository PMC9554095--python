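"""Score CTC HER2 staining and call a patient's CTC-HER2 status.

Each CTC's HER2 MFI falls into one of four staining levels
(H0 < 100 <= H1 < 400 <= H2 < 600 <= H3, a.u.).  A patient is
CTC-HER2+ when more than 12% of their CTCs are H2 or at least one is
H3; the 12% cutoff itself can be re-derived from a calibration cohort
by maximizing Youden's J.
"""

from ctcher2 import ScoringScheme, bin_her2, call_ctc_her2, derive_ratio_cutoff

scheme = ScoringScheme()

for mfi in (50, 250, 500, 700):
    print(f"  MFI {mfi:>4} a.u. -> {bin_her2(mfi, scheme).value}")

examples = [
    ("mostly dim, one strong cell", {"H0": 49, "H1": 0, "H2": 0, "H3": 1}),
    ("20% moderately stained", {"H0": 8, "H1": 0, "H2": 2, "H3": 0}),
    ("exactly 12% moderate", {"H0": 22, "H1": 0, "H2": 3, "H3": 0}),
    ("no CTCs detected", {"H0": 0, "H1": 0, "H2": 0, "H3": 0}),
]
for label, counts in examples:
    print(f"  {label}: {call_ctc_her2(counts, scheme).value}")
# one H3 cell or >12% H2 cells makes the patient positive; exactly 12%
# does not (the comparison is strict); zero CTCs are unevaluable.

# re-derive the ratio cutoff from per-patient H2 ratios of a
# low-expression (label 0) vs a higher-expression (label 1) class
ratios = [0.00, 0.04, 0.08, 0.10, 0.15, 0.22, 0.30]
labels = [0, 0, 0, 0, 1, 1, 1]
res = derive_ratio_cutoff(ratios, labels)
print(
    f"derived ratio cutoff {res.threshold:.2f} "
    f"(J = {res.youden_j:.2f}, sens {res.sensitivity:.2f}, spec {res.specificity:.2f})"
)
# the scan lands on the largest low-class ratio (0.10): every threshold
# in (0.10, 0.15) separates the classes perfectly, and ties break low.
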