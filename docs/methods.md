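# Methods

## Observation model

The unit of visitation is the **visit image**: a time-lapse frame in which a
forager is present on a focal inflorescence. Counts and shares are computed
over images; **events** (maximal runs of consecutive annotated frames for
one visitor class on one inflorescence) are a derived view whose duration is
reported only as the lower bound `(n_frames − 1) × frame interval`, because
presence between frames is unobserved. Two annotations merge into one event
only when their frames are adjacent in the camera's frame log *and* spaced
by the nominal interval; a jump across a focused-window boundary therefore
never merges, and annotations of different classes never merge (an event is
one forager).

Two camera regimes are modelled: *focused* (1-min frames, active only
12.00–15.00 and 01.00–03.00 local time) and *continuous* (5-min frames,
always active). Raw diel histograms of visit images conflate insect activity
with camera activity, so the diel summary also bins **effort** (frames
recorded per clock bin) and reports `rate = count / effort`, undefined — not
zero — in bins without frames. Timestamps are ISO 8601 local clock time
throughout; the diel windows are defined in clock hours, so no timezone or
solar correction is applied. Day-of-year values are fractional
(date + clock/24) so that nocturnal visits near midnight do not alias by a
day when averaged.

## Indices

Per inflorescence: floral peak = midpoint of last-floret emergence and
first-floret senescence (days, possibly fractional); VLI = mean fractional
DOY of visit images − peak, undefined with zero visits; seed set
s = seeds/(2·florets); SLI = median percentile position of seeded florets
with the higher-middle tie rule; weight w = 0.25 − |s − 0.25|.

Two deliberate readings of ambiguous definitions:

- **"Seeded floret" is floret-level**: a two-seed floret enters the SLI
  median once. A seed-level variant (each floret repeated by its seed count)
  is available via `sli_from_percentiles(..., seed_level=True)` without any
  claim about which convention underlies published values.
- **Seed set above 0.5** is arithmetically possible when double-seeded
  florets outnumber empty ones; field data make this rare. `seed_set`
  returns the exact formula value in [0, 1] and the weight tent is clipped
  at zero outside [0, 0.5], which also keeps weighted regression weights
  non-negative.
- When `dissection.csv` lacks percentile positions they are filled from
  ranks as `100·(rank − 1)/(n − 1)` (single floret → 50), matching the
  basal ≈ 0%, apical = 100% endpoints.

## Inference

- **Two-group seed-set model**: OLS of s on a binary visitation indicator,
  restricted to fully recorded heads with measurable seed set; the F
  statistic (df 1, n−2) equals the squared pooled two-sample t, which the
  tests verify on thousands of random datasets.
- **Visitor-definition comparison**: both groupings fitted to the identical
  observation set; AIC = n·ln(RSS/n) + 2k with k = 3 (intercept, group
  effect, error variance). The dropped constants cancel in ΔAIC for
  equal-k models, so ΔAIC = n·ln(RSS_bee/RSS_any); positive values favour
  counting all visitor classes.
- **SLI ~ VLI**: weighted least squares over heads with defined VLI and
  SLI. Observations with w = 0 contribute nothing; n and the residual
  degrees of freedom (n − 2) count w > 0 observations, which is equivalent
  to carrying them with zero weight. R² is computed from weighted sums of
  squares about the weighted mean. The unweighted variant defaults to the
  same membership (w > 0) for comparability; `include_zero_weight=True`
  re-admits the extremes.
- **Co-occurrence**: Pearson χ² on the 2×2 moth-visited × bumblebee-visited
  table, d.f. = 1, Yates correction off by default (selectable); a zero
  margin raises rather than reporting a vacuous statistic. All recorded
  heads are used by default; restriction to fully recorded heads is a flag.
- p-values come from the F distribution at the stated degrees of freedom;
  no small-sample corrections and no multiplicity adjustment across the
  three analyses.

## Simulator

`simulate_season` draws, per camera (9 focused + 6 continuous by default),
Poisson(2.4) inflorescences; each gets a Normal(188, 7) flowering start
(DOY), a truncated-Normal(80, 15, ≥10) floret count, deterministic
basal→apical floret opening evenly spread over 6 days, and an 8-day
per-floret receptivity window. The emitted phenology rows follow: last
emergence = start + 6, first senescence = start + 8 (the config validator
requires opening span ≤ receptivity so these stay ordered); `fully_recorded`
is true when the whole flowering interval lies inside the 23 June – 15
August season.

Visits are independent inhomogeneous Poisson processes per head, simulated
by thinning a homogeneous candidate stream against the bloom envelope (the
fraction of florets currently open): bumblebees and "other" visitors
uniform over a fixed 06.00–21.00 daylight window (constant rather than
latitude-derived — the analysis never uses sunrise/sunset), moths uniform
over the 22.00–03.00 nocturnal window, wrapping midnight. Rates are
expected visits per head-day (or head-night) at full bloom.
`visit_shift_days` translates the thinning envelope in time to emulate
phenological mismatch; it is the knob behind the comparative-statics tests
(earlier visits ⇒ lower mean VLI and lower mean SLI).

Pollination is instantaneous at the visit start: each currently open,
receptive, unpollinated floret is pollinated with probability
`p_pollinate`; a pollinated floret sets Binomial(2, `q_seed`) seeds.
Detection is separate: the visit's exponential duration determines which
camera frames fall inside `[start, start + duration]`, and each such frame
becomes one annotation row. This separation (biology at a point, observation
over an interval) is what lets the same mechanism produce both the seed
tables and the camera tables. One `numpy` Generator seeded from the config
drives everything, so equal seeds give byte-identical CSV bundles.
`null_pollination` replaces the visit pathway with independent per-floret
pollination at `base_pollination_prob`, severing seeds from visits while
leaving visitation untouched — the type-I calibration regime.

### Presets and their calibration

`paperlike_preset()` commits rates and durations chosen so the simulated
magnitudes sit near the field study's: across replicate seasons it yields
≈36 heads, ≈43 visit images per season, a moth share of ≈34%, a visited
fraction of ≈0.59, and mean seed set ≈0.27 (p_pollinate = 0.15,
q_seed = 0.45 place mean s near 26% with rare double seeding, as dissection
data show). These rates are calibrated to those coarse magnitudes only and
are not asserted as field-realistic visit frequencies.

`strong_effect_config()` is the power regime: sparse visits
(bee 0.10/day, moth 0.06/night, so heads differ sharply in true visit
count), long durations (4/6 min, so cameras detect a large share of
visits), and efficient pollination (p_pollinate = 0.8, q_seed = 0.4).
Under it the any-visit two-group test rejects in ≈87–89% of seasons and the
weighted VLI→SLI slope is positive in ≈98–100%; under `null_config()` the
rejection rate sits at the nominal 5%.

### What the generator does not emulate

Weather, seed predation (weevils), genotype effects, visitor misclassification,
annotation error, camera failure, and within-window diel structure (intensity
is uniform inside each activity window). Passing recovery tests therefore
show the pipeline correctly extracts a signal *of the assumed form*; they do
not certify robustness to these real-data complications.

## Numerical and scale choices

- Monte-Carlo studies use 500 replicate seasons in the test suite and 400
  (plus 200 preset seasons) in the reproduction script; at ≈0.1 s per
  simulated season these sizes give percentage summaries with ≈1–2 point
  Monte-Carlo error while keeping full runs to a few minutes.
- Per-replicate seeds are spawned from one base seed via
  `numpy.random.SeedSequence`, keeping every study reproducible from a
  single integer.
- `detection_probability` integrates over a midpoint grid of start times
  (step 0.01 min) against the exact frame grid, so window-boundary mass
  (a visit straddling a focused window edge always contains the edge
  frame) is captured without Monte-Carlo noise.
- Degenerate inputs raise typed errors rather than returning NaN statistics:
  empty groups, zero-variance responses, zero 2×2 margins, all-zero
  weights, n < 3 regressions. The pipeline-level report catches these and
  marks the section undefined instead of aborting the season.
- Reported precision follows ecological convention: integer percent for
  taxon shares, two significant figures for the visit-image fraction, one
  decimal for seed-set percentage points.

## Known limitations

Duration-weighted VLI: because the VLI averages *images*, visits
contributing more frames weigh more; relative to a per-visit mean this is an
error-in-variables effect (see the recovery test's direction-of-regression
note in `tests/test_simulate.py`). Cover is modelled as a simple linear
function of open florets per camera, adequate for peak-date logic but not
for absolute cover values. The co-occurrence test treats heads as
independent, ignoring camera-level clustering; a mixed model is out of
scope.
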