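# ctcher2

CTC enumeration and semi-quantitative HER2 phenotyping of circulating
tumor cells, with the diagnostic, agreement, response and survival
statistics built on top.

## The problem

In advanced breast cancer, the decision to give anti-HER2 therapy
rests on tissue HER2 status (IHC, resolved by FISH at 2+). Tissue is
sampled once, invasively, and HER2 expression is heterogeneous and
drifts over time — so a blood-based readout is attractive. Captured
circulating tumor cells (CTCs) from a 2.0 ml draw can be immunostained
in four channels (DAPI / cytokeratins / CD45 / HER2), identified as
DAPI+/CK+/CD45− single cells, counted, and scored for HER2.

This package implements that analysis as a tested pipeline for
cell-level MFI tables (and a synthetic imaging front end):

* **Gating & enumeration** — label every detected object CTC / WBC /
  AMBIGUOUS / REJECTED; count CTCs per draw; dichotomize at a count
  cutoff (default ≥ 3 per 2.0 ml).
* **HER2 phenotyping** — bin each CTC's HER2 MFI into four staining
  levels, H0 [0,100), H1 [100,400), H2 [400,600), H3 [600,∞) a.u.;
  call a patient *CTC*-HER2+ when > 12% of CTCs are H2 or ≥ 1 CTC is
  H3 (zero CTCs ⇒ unevaluable); re-derive the ratio cutoff from a
  calibration cohort by maximizing Youden's J.
* **Statistics** — empirical ROC with Mann–Whitney AUC and
  Hanley–McNeil CI; sensitivity/specificity with Wilson score
  intervals; Welch's t; Pearson r; exact 2×2 Fisher and R×C
  Freeman–Halton tests by full same-margin enumeration
  (point-probability two-sided rule); Cohen's κ; concordance and
  RECIST response rates; Kaplan–Meier curves, the log-rank
  (Mantel–Cox) test and the Mantel–Haenszel O/E hazard ratio.
* **Synthetic cohorts** — a seeded generator producing cell- and
  patient-level tables with the study's structure (52 patients in
  three tissue classes + 10 healthy donors, zero-inflated
  negative-binomial counts spanning 0–683 per draw, class-conditional
  HER2 staining, status-dependent response, exponential survival with
  a planted count-class hazard ratio of 0.387), so every stage is
  testable without patient data.

See `docs/methods.md` for conventions, parameter defaults, and what
the synthetic data does and does not emulate.

## Worked example

```python
from ctcher2 import (
    CellRecord, GatingThresholds, ScoringScheme,
    gate_cells, enumerate_ctcs, call_ctc_her2, fisher_exact_2x2, ContingencyTable,
)

cells = [
    CellRecord("S1", "c1", 520.0, 310.0, 4.0, 650.0),
    CellRecord("S1", "c2", 480.0, 250.0, 8.0, 90.0),
    CellRecord("S1", "c3", 450.0, 280.0, 2.0, 450.0),
    CellRecord("S1", "c4", 510.0, 10.0, 420.0, 30.0),   # leukocyte
]
gated = gate_cells(cells, GatingThresholds())
print(enumerate_ctcs(gated, "S1"))
# 3
print(call_ctc_her2({"H0": 1, "H1": 0, "H2": 1, "H3": 1}, ScoringScheme()).value)
# POS        (one H3 CTC suffices)
res = fisher_exact_2x2(ContingencyTable([[0, 6], [6, 4]]))
print(round(res.p_value, 3))
# 0.034      (responses concentrated in the CTC-HER2+ group)
```

The `examples/` directory holds one short script per capability —
gating, phenotyping, exact tests, ROC, survival, a full simulated
cohort run, the imaging round-trip, and the worked-example
reproduction. Each prints its numbers with a note on what they mean;
for instance `python examples/06_synthetic_cohort_pipeline.py` prints

```
52 patients, 10 donors; detection rate 78.8%, 39 patients at >=3 CTCs
tissue-vs-CTC agreement: Freeman-Halton p = 0.0016, concordance 28/41
CTC-HER2+ rate by tissue class: {'NEG': 0.0, 'LOW': 0.5, 'POS': 0.526}
treated patients: ORR 41.7%, DCR 91.7% (n = 24)
PFS HR (HIGH vs LOW) = 3.583
```

— a simulated cohort in which no tissue-HER2-negative patient is ever
called CTC-HER2+, responses concentrate in the CTC-HER2+ stratum, and
the high-count class progresses ~3.6× faster.

A thin CLI wraps the same calls:

```bash
ctcher2 simulate --seed 7 --out cohort/
ctcher2 phenotype --cells cohort/cells.csv --patients cohort/patients.csv --out report.json
ctcher2 exact --table agreement.csv
ctcher2 reproduce
```

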