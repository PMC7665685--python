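# Methods

This note documents the models, conventions and numerical choices behind
`peskas`, and what the synthetic-fishery tests do and do not demonstrate
about real monitoring data.

## Weight estimation and quality control

Record weight is `n · a · L^b / 1000` kg with taxon-specific `a`, `b` in
the cm→gram convention. The engine validates `a > 0` and `1 ≤ b ≤ 5`
(fish allometric exponents cluster near 3; values outside that band are
data errors, not biology).

QC is *flag-and-suppress*: each of six independent rules attaches a flag
code; a record may carry several; flagged records are excluded from every
aggregate but retained in storage for curation. Flags are recomputed from
scratch on every pass, which makes filtering idempotent by construction.
Rules and defaults:

* **LENGTH_OOB / PRICE_OOB** — per-taxon plausibility bands carried in the
  species table. Length bands may be set at species or group level; the
  engine is agnostic, it reads whatever band accompanies the taxon code.
* **COUNT_OOB / WEIGHT_OOB** — global caps (`QCBounds`, defaults 1,000
  individuals and 5,000 kg per record). Deliberately generous: they catch
  an extra digit or a swapped field, not a genuinely big catch.
* **PRICE_OOB conversion** — prices recorded per fish are converted to an
  implied per-kg price (`price · n / est_weight`) before checking, and the
  check is skipped when no weight is available.
* **FORMAT_ERROR** — unknown taxon or missing/nonpositive length, count or
  effort fields.
* **INVALID_GEAR_HABITAT** — trip-level check against an editable gear ×
  habitat validity matrix (a packaged CSV default is provided, e.g.
  gleaning is valid on shore/mangrove/reef only). The flag propagates to
  every landing of the trip, and suppression drops the whole trip: if the
  gear/habitat pair is nonsense, the trip's effort attribution is not
  trusted either. Trips that merely lose individual records keep their
  clean landings and still contribute effort.

## Effort, CPUE and the raising estimator

Effort is fisher-hours (duration × crew). Stratified CPUE defaults to the
ratio-of-totals Σcatch/Σeffort, which is effort-weighted and dimensionally
consistent with the raising formula; a mean-of-per-trip-ratios variant is
available (`method="mean"`) for sensitivity checks. Strata with zero
effort are excluded with a warning rather than yielding infinities.

The national monthly catch is `C = Σ_b CPUE_b · EPT_b · VAC_b · N_b ·
0.001` tonnes over canoe and motor boats; shore-based fishing is parsed
and summarised but excluded from raising. EPT is the exact sample median
of per-trip effort (mean of the middle two for even n — stated explicitly
because it feeds the headline estimate). VAC is trips per tracked boat per
month; the default denominator is the month's *active* roster (units with
at least one track that month), configurable to a fixed instrumented
roster in which idle boats count as zeros, and the per-boat statistic is
the mean by default (median by option). Boat types with no tracked boats
yield no VAC; the caller must supply a fallback rather than receive a
silent guess.

In a fishery where every boat's every trip is observed and tracked and
effort per trip is constant, the estimator is algebraically exact:
CPUE · EPT · VAC · N collapses to total catch. With variable effort the
only bias is the median-vs-mean effort term (`e^{-σ²/2}` for lognormal
durations), which is what the recovery tests isolate — they use σ = 0.1 so
that this known discrepancy, not Monte-Carlo noise, dominates.

CPUE trend display uses a cubic smoothing spline weighted by trip effort
(`scipy.interpolate.make_smoothing_spline`), with a `spar ∈ [0, 1]`
slider-style parameter mapped to the penalty as λ = 256^(3·spar − 1) on
times rescaled to [0, 1]. The λ→∞ limit of this spline is the weighted
*linear* least-squares fit (the penalty annihilates curvature, not slope);
a constant series is reproduced exactly at any setting. Fewer than four
points is an error advising raw display.

The effort heat map bins ping coordinates on an equirectangular grid over
the tracks' bounding box; at a fixed ping cadence the count per cell is
proportional to time spent there. Cell sums always equal the ping count;
a degenerate single-point bounding box yields a 1×1 grid.

## Trip classification

Each track is summarised by 10 positions at even time intervals from first
to last ping, linearly interpolated between bracketing pings, expressed in
km via the equirectangular projection x = Δlon·cos(lat₀)·111.32,
y = Δlat·110.57 about a shared reference origin. At trip scale in the
tropics the projection error is negligible, and distances are invariant to
origin translation to first order (the cos(lat₀) scale drifts ~0.15% per
degree of latitude at 8.5°S). The feature is the 20-dim position vector by
default; a displacement-vector reading (9 successive differences, encoding
shape but not location) is available via `mode="displacements"`.

Donor assignment is the argmin of the full 20-dim Euclidean norm —
explicitly *not* a per-point average distance — with labels copied only
when the donor is nearer than 0.20 km; ties break to the lowest donor
trip id. The search is an exhaustive vectorised distance matrix: donor
pools here are hundreds of trips, and exhaustiveness makes the oracle
equivalence trivial to state. Validation repeatedly splits the linked set
80/20, scores the queries, and reports mean and SD over iterations;
unassigned queries count as incorrect (the conservative reading — an
unassigned trip yields no usable label). Splits come from a single seeded
`numpy` Generator, so per-iteration tables are reproducible bit for bit.
Degenerate single-class label sets still run but are noted in the result.

## The synthetic fishery

The generator emulates the study conditions end to end: a fleet of canoes
and motorboats (default 6 + 4), each boat making a fixed number of trips
per month (default 4, so the true VAC is known exactly), each trip working
one gear's fishing ground and landing 1–3 species-group records whose
realised weight tracks a per-gear mean CPUE (default 0.6–1.2 kg per
fisher-hour with 30% lognormal scatter around a 5 h, 2–3 crew trip).
Lengths are lognormal, recorded to the nearest cm, and truncated inside
the taxon's plausibility band so baseline data never trips QC. Tracks are
out-and-back paths home → ground → home at 5 s cadence (10 min default
duration) with Gaussian GPS jitter (2 m).

Fishing grounds are Gaussian patches keyed to gear and habitat;
between-ground separation (default 5 km) and within-ground spread are
independent dials. The default spread is 0.05 km because real artisanal
fishing spots — anchored FADs, named reef holes — are revisited within
tens of metres, which is precisely what makes a 0.20 km donor cutoff
workable; widening the spread degrades assignment rates smoothly and is
the intended stress axis.

QC violations are injected by corrupting a configurable fraction of
records, each corruption crafted to fire exactly one rule (e.g. a length
set to 1.5× the taxon maximum with the count dropped to 1 so the weight
cap does not also fire). Truth totals are computed over non-injected
records only — a corrupted record no longer has a meaningful true weight —
which is what makes "QC report = injection list" and estimator recovery
exact simultaneously. All randomness flows from one seed through named
substreams (species, trips, tracks, flags, split).

What the generator does **not** emulate: weather and seasonality, fish
population dynamics, enumerator recording error other than the injected
violations, tracker dropout or irregular cadence (a timing-jitter knob
exists but cadence gaps are never missing wholesale), and multi-day trips.
Passing tests therefore demonstrate the correctness of the arithmetic and
the self-consistency of the pipeline under known conditions — not that
real-world imputation will reach any particular accuracy, which depends
entirely on how site-faithful real fleets are.

## Problem sizes and determinism

Tests and the acceptance script run fisheries of 40–270 trips and
30–80-thousand-ping track sets — small enough to regenerate from scratch
in seconds, large enough that stratified aggregates, hold-out validation
(100 iterations) and multinomial heat-map checks are meaningful. Pipeline
outputs are deterministic: rows are sorted on stable keys, floats are
written with round-trip precision, inputs are re-read with
`float_precision="round_trip"`, and no timestamps or environment state
enter any file, so re-running on the same inputs is byte-identical.
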