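"""Simulate one camera-surveilled red-clover season and look at the tables.

The default preset emulates the field design: 9 focused cameras (1-min
frames, 12.00-15.00 and 01.00-03.00) and 6 continuous cameras (5-min
frames, always on) watching ~36 inflorescences over a 23 June - 15 August
season.
"""

from cloverwatch import paperlike_preset, simulate_season

bundle, truth = simulate_season(paperlike_preset(), seed=42)

print(f"frames recorded:        {len(bundle.frames):>8}")
print(f"visit images captured:  {len(bundle.visits):>8}")
print(f"inflorescences watched: {len(bundle.phenology):>8}")
print(f"florets dissected:      {len(bundle.dissection):>8}")
print()
print("visit images by taxon:", bundle.visits["taxon"].value_counts().to_dict())
print("true visits (detected or not):", len(truth.visits))
print()
# the camera sees only a sample: frames bound detection, durations decide
# how many frames a visit spans
detected = truth.visits["n_frames_detected"] > 0
print(f"detected {detected.sum()} of {len(truth.visits)} true visits "
      f"({100 * detected.mean():.0f}%)")
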