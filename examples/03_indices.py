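"""Per-inflorescence indices: floral peak, VLI, seed set s, SLI and weight w.

VLI (visit lateness) is the mean day-of-year of an inflorescence's visit
images minus its floral peak (midpoint of last-floret emergence and
first-floret senescence). SLI (seed lateness) is the median percentile
position of its seeded florets (0 = basal, 100 = apical; ties -> higher
middle). w = 0.25 - |s - 0.25| down-weights heads whose SLI is poorly
determined because almost no or almost all florets seeded.
"""

from cloverwatch import build_index_table, paperlike_preset, simulate_season

bundle, _ = simulate_season(paperlike_preset(), seed=42)
idx = build_index_table(bundle)

cols = ["visited_any", "n_visit_images", "peak_doy", "vli", "s", "sli", "w"]
print(idx[cols].round(3).to_string())
print()
both = idx[idx["vli"].notna() & idx["sli"].notna()]
print(f"{len(both)} heads have both a defined VLI (visited on camera) and a "
      f"defined SLI (>= 1 seeded floret) and can enter the lateness regression")
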