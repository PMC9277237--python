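"""The three statistical analyses on a simulated season with a strong effect.

1. Do camera-visited heads set more seed? (two-group linear model)
2. Does counting moth visits, not just bumblebees, explain seed set
   better? (AIC comparison of the two visitor definitions)
3. Do later visits shift seeds toward later-opening florets? (weighted
   least squares of SLI on VLI)
"""

from cloverwatch import (
    build_index_table,
    compare_visitor_definitions,
    simulate_season,
    sli_vli_regression,
    strong_effect_config,
)

bundle, _ = simulate_season(strong_effect_config(), seed=5)
idx = build_index_table(bundle)

cmp = compare_visitor_definitions(idx)
a, b = cmp["any_visit"], cmp["bumblebee_only"]
print(f"any-visit grouping:     F_1,{a.df[1]} = {a.F:.2f}, p = {a.p_value:.3g}, "
      f"R2 = {a.r_squared:.3f}; visited heads +{a.mean_difference_pct:.1f} "
      f"percentage points of seed set")
print(f"bumblebee-only:         F_1,{b.df[1]} = {b.F:.2f}, p = {b.p_value:.3g}, "
      f"R2 = {b.r_squared:.3f}")
print(f"delta AIC = {cmp['delta_aic']:.2f} "
      f"({'all-visitor' if cmp['delta_aic'] > 0 else 'bumblebee-only'} "
      f"definition preferred)")
print()
for weighted in (True, False):
    fit = sli_vli_regression(idx, weighted=weighted)
    kind = "weighted" if weighted else "unweighted"
    print(f"SLI ~ VLI ({kind:10s}): slope = {fit.slope:+.2f} percentile points "
          f"per day, d.f. = {fit.df_residual}, F = {fit.F:.2f}, p = {fit.p_value:.3g}")
print()
print("a positive slope means late-visited heads carry their seeds in "
      "late-opening (apical) florets — the signature of pollination driving "
      "the seed pattern")
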