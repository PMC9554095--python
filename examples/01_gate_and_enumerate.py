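"""Gate a handful of stained cells and enumerate CTCs.

A circulating tumor cell is DAPI+/CK+/CD45-: nucleated, epithelial,
not a leukocyte.  The count per 2.0 ml draw is then dichotomized at the
>=3 cutoff that separates HIGH from LOW count classes.
"""

from ctcher2 import (
    CellRecord,
    GatingThresholds,
    ScoringScheme,
    classify_count,
    enumerate_ctcs,
    gate_cells,
)

cells = [
    #          sample  id    DAPI   CK   CD45  HER2
    CellRecord("S1", "c1", 520.0, 310.0, 4.0, 650.0),   # CTC, strong HER2
    CellRecord("S1", "c2", 480.0, 250.0, 8.0, 90.0),    # CTC, barely stained
    CellRecord("S1", "c3", 450.0, 280.0, 2.0, 450.0),   # CTC, moderate HER2
    CellRecord("S1", "c4", 510.0, 10.0, 420.0, 30.0),   # leukocyte (CD45+)
    CellRecord("S1", "c5", 20.0, 900.0, 1.0, 800.0),    # debris: no nucleus
    CellRecord("S1", "c6", 400.0, 12.0, 9.0, 55.0),     # nucleated, marker-silent
]

gated = gate_cells(cells, GatingThresholds())
for c in gated:
    print(f"  {c.cell_id}: {c.gate_label.value}")

count = enumerate_ctcs(gated, "S1")
cls = classify_count(count, ScoringScheme())
print(f"sample S1: {count} CTCs -> count class {cls.value}")
# 3 of the 6 objects pass the CTC gate; 3 CTCs meets the >=3 cutoff, so
# this draw falls in the HIGH (worse-prognosis) count class.
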