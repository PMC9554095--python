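"""Render a synthetic four-channel field and quantify the cells back.

Cells are flat-topped discs over constant background plus Gaussian
noise; nuclei are segmented on the DAPI channel (Otsu + connected
components) and each object's per-channel MFI is its mean intensity
minus the background median.
"""

from ctcher2.imaging import FieldSpec, PlantedCell, quantify_cells, render_field

cells = [
    PlantedCell(center=(40, 40), radius=6, amplitudes=(420, 300, 5, 650)),  # HER2-strong CTC
    PlantedCell(center=(40, 100), radius=5, amplitudes=(400, 280, 5, 80)),  # HER2-dim CTC
    PlantedCell(center=(100, 70), radius=7, amplitudes=(380, 8, 350, 20), identity="WBC"),
]
spec = FieldSpec(shape=(144, 144), cells=cells, background_level=10, noise_sd=3)
field = render_field(spec, seed=4)

records = quantify_cells(field)
print(f"planted {len(cells)} cells, recovered {len(records)} objects")
for r in records:
    print(
        f"  {r.cell_id}: DAPI {r.mfi_dapi:.0f}, CK {r.mfi_ck:.0f}, "
        f"CD45 {r.mfi_cd45:.0f}, HER2 {r.mfi_her2:.0f} a.u."
    )
# recovered MFIs sit within a few percent of the planted amplitudes, so
# the downstream gate (CK vs CD45) and HER2 bins see faithful values;
# the third object shows the leukocyte pattern (CK-, CD45+).
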