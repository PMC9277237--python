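# cloverwatch

Analysis pipeline for **day-and-night time-lapse pollinator surveillance of
red clover** (*Trifolium pratense*), plus a generative simulator of the whole
observation chain.

Red clover needs insect pollen transfer to set seed, and pollination studies
of it have overwhelmingly watched bees — by day. Around-the-clock time-lapse
cameras change what can be asked: *who* visits (including nocturnal moths),
*when* they visit relative to each inflorescence's flowering, and whether
visit timing leaves a fingerprint in *where* seeds develop within the seed
head. `cloverwatch` turns camera-frame annotations and floret dissection
records into those answers. It is written for pollination ecologists working
with image-annotation tables rather than raw images.

## The quantities at its core

For each inflorescence (flower head of many florets that open basally →
apically):

- **Floral peak** — midpoint of the day the last floret emerged and the day
  the first floret senesced.
- **VLI, visit lateness index** — mean (fractional) day-of-year of the visit
  images minus the floral peak; negative = visited before peak. Undefined if
  never seen visited.
- **Seed set** `s = seeds / (2 · florets)` — each floret carries two ovules.
- **SLI, seed lateness index** — median percentile position (0 basal, 100
  apical) of the seeded florets; on an even count, the higher middle value.
  Low SLI = seeds in early-opening florets.
- **Weight** `w = 0.25 − |s − 0.25|` — SLI is noisy when s ≈ 0 and pinned
  near 50 when s ≈ 0.5, so regressions weight heads by this tent function.

Inference layer: a two-group linear model of `s` on a visitation indicator
(any visitor class vs bumblebee-only, compared by ΔAIC = n·ln(RSS₁/RSS₂) for
the equal-parameter models), a Pearson χ² test of moth × bumblebee
co-occurrence, and weighted least squares of SLI on VLI — a positive slope is
the signature of pollination, not a confounder, driving seed set.

The simulator generates the five input tables from an explicit mechanism
(inhomogeneous Poisson visits scaled by the bloom envelope, per-visit
pollination of open receptive florets, Binomial(2, q) seeds, frame-grid
detection), with ground truth for parameter-recovery tests and a null switch
that decouples seeds from visits.

## Worked example

```sh
python examples/04_inference.py
```

prints (seed 5 of the strong-effect configuration):

```
any-visit grouping:     F_1,38 = 17.18, p = 0.000183, R2 = 0.311; visited heads +16.9 percentage points of seed set
bumblebee-only:         F_1,38 = 6.03, p = 0.0187, R2 = 0.137
delta AIC = 9.03 (all-visitor definition preferred)

SLI ~ VLI (weighted  ): slope = +3.43 percentile points per day, d.f. = 17, F = 36.36, p = 1.35e-05
SLI ~ VLI (unweighted): slope = +4.28 percentile points per day, d.f. = 17, F = 49.14, p = 2.1e-06
```

Heads seen visited set ~17 percentage points more of their ovule capacity
than unseen heads; counting all visitor classes explains seed set markedly
better than bumblebees alone (ΔAIC ≈ 9); and each day of later visitation
shifts the seed median ~3 percentile positions toward apical florets.
`examples/01–05` walk the remaining capabilities (simulation, event
assembly and diel effort correction, index tables, the full pipeline).

The same machinery is scriptable from a shell:

```sh
cloverwatch simulate --out season/ --seed 42
cloverwatch analyze --inputs season/
cloverwatch run --out results/ --seed 42   # pipeline + figures + manifest
```

Five CSV inputs are expected for real data: `frames.csv` (camera_id,
timestamp, regime), `visits.csv` (camera_id, inflorescence_id, timestamp,
taxon), `phenology.csv`, `dissection.csv`, `cover.csv` — schemas in
`cloverwatch/tables.py`.

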