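# Methods

## Model

`trapsurvey` simulates an insect outbreak dispersing through a fixed network
of attractive traps and tracks, day by day, the probability that the survey
has captured an individual.

**Dispersal.** Each of the N insects performs an independent, unbiased
Gaussian random walk on the unbounded plane with one step per day. Daily
per-axis increments are iid N(0, (4·√D)²), so the per-axis position standard
deviation after *t* days is exactly σ(t) = 4·√(D·t) — the dispersal law the
closed-form analytics (`sigma`, `quantile_distance`, `days_to_quantile`)
expose directly. This is the unique iid-Gaussian walk consistent with that
law. Insects are never removed, reflected, or bounded: egress beyond the
survey grid is possible by construction, which the containment experiments
require. There is no natality or mortality — the cohort reflects a first or
second generation early in an outbreak over a short (30-day) survey.

**Outbreak location.** One epicenter per Monte-Carlo iteration, drawn
uniformly from the central square-mile core cell (side 1,609.34 m) and shared
by the whole cohort; it is redrawn every iteration. Randomizing the epicenter
across iterations is equivalent in expectation to pre-drawing a fixed panel
of outbreak locations, and keeps iterations exchangeable.

**Capture.** A trap at distance *d* captures a responsive insect within one
day with probability p(d) = exp(−λd), where 1/λ (m) is the attraction
length — the distance at which the single-trap daily capture probability has
fallen to e⁻¹ ≈ 0.37. Traps act multiplicatively (no interference beyond
independence): one-day escape at position x is Πⱼ (1 − p(dⱼ)). Capture is
evaluated once per day at the end-of-day position; at these parameter scales
the start-of-day alternative differs by less than the Monte-Carlo CI.

**Aggregation.** Per insect, cumulative escape through day *t* is the product
of its daily escape probabilities. Per iteration, the population p(escape)
series is the arithmetic mean over insects (not the product — the metric is
the mean per-individual capture probability, which makes the expectation
insensitive to N; the product would be the probability of capturing *zero*
insects and would depend strongly on N). Across iterations the series is
averaged, with a normal-approximation 95 % half-width 1.96·s/√iterations.
Insects are not removed on "capture": the engine tracks probabilities, so one
capture is indistinguishable from ten.

## Grid construction

* **Square banded grids** use square-mile cells (1,609.34 m side; 2.58999 km²)
  on an odd cell lattice so a unique central core cell exists. Band *b* is the
  ring of cells at Chebyshev distance *b* − 1 from the core. Per-cell trap
  count is round(density × cell area); traps sit on a centred k×m sub-lattice
  (k·m = count, k the largest divisor ≤ √count) with half-spacing offsets from
  the cell edges. The bundled presets reproduce the published trap totals
  exactly: 900 (uniform 8-km grid) and 1,660 = 100+392+400+480+288 (variable
  14.5-km grid). Rectangular in-cell lattices (e.g. 20 = 4×5) preserve counts
  and band symmetry but not exact 4-fold symmetry of the point set; square
  counts (36 = 6×6, 100 = 10×10) are exactly symmetric.
* **Circular banded grids** place each band's traps on a square lattice of
  spacing 1000/√density metres, centred on the origin with half-spacing
  offsets (no trap exactly at the centre), keeping a point iff its radius lies
  in [r_inner, r_outer). Counts track density × area with a lattice-clipping
  error within ±3 % for the bundled densities, with a √N floor where boundary
  cells dominate (small discs, sparse lattices). Default radii: core disc to
  0.8 km, annuli to 2.4 and 4.0 km, mirroring the square core's half-width.
* **Perimeter rings** are a single annulus [inner, inner + width) with a
  trap-free interior, used for egress testing. The bundled containment
  presets use a 1.6-km-wide ring just outside each standard grid (inner
  radius 4.0 km for the leek moth, 7.24 km for Medfly) with deliberately high
  attractiveness (1/λ = 30 m) so that any insect reaching the ring is very
  likely to register.

## Parameters

| parameter | units | leek moth | Medfly | meaning |
|---|---|---|---|---|
| D | m²/day | 500 | 5,000 | daily areal spread; sets the walk step 4·√D |
| 1/λ | m | 20 (alt. 10) | 10 | single-trap attraction length |
| N | insects | 50 | 50 | outbreak cohort size (expectation-neutral) |
| t | days | 30 | 30 | survey duration |
| iterations | – | 1,000 (200 desk-scale) | | Monte-Carlo replication |
| unit cost | $/trap/30 d | 28 | 26 | purchase + servicing |

ROI is reported as capture percentage points per $1,000:
100·p(capture)/(cost/1000). The standard-design budgets use the published
trap totals (900; 1,700) rather than the constructed counts (900; 1,660) so
the dollar figures match the published $25,200 and $44,200; the comparison
table carries both counts.

## Numerical choices

* Escape products are accumulated in log space (`log1p(−exp(−d/ℓ))`), exact
  at d = 0 (−∞ → escape 0) and immune to underflow near traps.
* Trap–insect pairs beyond 46 attraction lengths are pruned with a k-d tree;
  the neglected per-pair capture probability is < 1e-20, below double
  precision on the log sums. Verified against a dense brute-force computation
  to 1e-16.
* Per-iteration RNG substreams are spawned from a single `SeedSequence`, so a
  run is fully determined by its seed, and layouts compared under a common
  seed see identical trajectories (common random numbers) — this makes
  monotonicity comparisons (more traps, stronger lures, longer surveys) exact
  rather than statistical.
* Monte-Carlo CIs are normal-approximation half-widths across iteration
  means; with a single iteration the CI is reported as NaN rather than 0.

## Desk-scale replication

The bundled reproduction run (`trapsurvey paper-run`) and the acceptance
script use 200 iterations instead of 1,000, which puts the 95 % CI of a
capture probability near ±0.005 and keeps the full bundle under two minutes
on one CPU. Iteration counts are flags everywhere.

## What the generator emulates — and what it does not

The grid builders and the dispersal model *are* the data generators: there is
no external data. They emulate idealized survey conditions — flat, featureless
terrain, perfectly placed and serviced traps of identical attractiveness,
weather-independent movement, a closed cohort with no births or deaths, and a
single localized outbreak. Passing tests therefore demonstrate internal
consistency of the model and pipeline, not field performance: real surveys
face host-plant structure, wind, trap degradation, and operational placement
constraints, all outside this model's scope (as is area-wide delimitation of
widely dispersed outbreaks).

## Known limitations

* **Reference capture probabilities are not reproduced.** Previously reported
  evaluations of these two standard designs give markedly higher capture
  probabilities (e.g. 0.86 for the leek-moth grid, 0.71 for the Medfly grid,
  0.67 for the Medfly core band alone) than this model computes under the
  same documented parameters (≈ 0.65, 0.36 and 0.19 respectively; the
  `paper-run` manifest's self-audit computes and flags these side by side).
  Our analysis indicates the discrepancy cannot be closed within the
  documented model family: the uniform-density reference values imply an
  effective daily capture area of ≈ 11.6·(1/λ)² (this kernel yields at most
  2π·ζ(3)·(1/λ)² ≈ 7.6·(1/λ)²), while the reported core/outer-band
  decomposition additionally implies a 30-day spread several times smaller
  than σ = 4·√(D·t). Those two requirements cannot be met simultaneously by
  rescaling the kernel, subdividing the daily step, evaluating capture along
  path segments, or re-drawing positions independently each day; we therefore
  implement the documented equations exactly and report the difference rather
  than calibrating to the reference outputs.
* The Medfly time-inversion analytic (time for the 95th-percentile spread to
  reach 7,250 m) evaluates to ≈ 243 days by direct inversion of the dispersal
  law; a previously reported value of 253 days does not satisfy the same
  inversion. The implementation follows the law exactly.
* Trap interference (overlapping attraction plumes competing) is not
  modelled beyond multiplicative independence; at high densities this
  overstates capture.
* Within-day movement is not resolved: an insect that crosses a trap's
  attraction zone between two end-of-day positions accrues no capture
  probability from the crossing.
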