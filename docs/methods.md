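# Methods

## Setting and data model

The package analyses room-level co-location in a bounded residential unit:
a roster of residents, each assigned to one shared bedroom, moving among
zones (bedrooms, common areas, transitional spaces, other rooms).  The raw
observable is a second-by-second stream of `(device_id, timestamp, zone_id)`
records from an indoor positioning system; devices map one-to-one to
residents.  Timestamps are integer epoch seconds and all intervals are
half-open `[start, end)`.

Because whole-network (sociocentric) tracking data from care facilities are
almost never shareable, the package treats a structured facility description
(YAML) plus either a real record stream or the built-in simulator as its
inputs.  The default facility is one residential unit with 48 tracked
residents in four shared-bedroom types — 7 in three-bed rooms, 18 in
four-bed rooms along a corridor, 15 in four-bed rooms facing the common
areas, 8 in five-bed rooms — plus a lounge, a dining room, a corridor and a
nursing station.  Every room keeps at least two tracked residents so each
resident has a roommate.

## Bedroom privacy instrument

Five architectural factors, each scored from the facility description and
summed to a 0–11 total (higher = more privacy):

| factor | coding | default-facility values |
|---|---|---|
| occupancy | 5+ beds = 0; 4 = 1; 3 = 2; ≤2 = 3 | 2 / 1 / 1 / 0 |
| adjacency | public = 0; semi-public = 1; semi-private = 2; private = 3 | 2 / 1 / 0 / 1 |
| transitional spaces | count between bedroom and common area, capped at 3 | 2 / 1 / 0 / 2 |
| visibility | can residents see the common areas? | 0 / 1 / 1 / 0 |
| visual privacy | beds visible from common areas = 0, screened = 1 | 1 / 1 / 0 / 1 |

(Columns: three-bed / four-bed corridor / four-bed common / five-bed;
totals 7 / 5 / 2 / 4.)

Published audit instruments disagree on the *direction* of the visibility
item: scale definitions often code "can see" as a privacy loss (0), while
applied per-room scores treat sight of the common areas as the scored
condition (1).  Both conventions are supported via `visibility_coding`; the
default (`"sees_scores_one"`) reproduces the applied convention.  Occupancy
is scored from the room's bed capacity, not from how many occupants happen
to be study participants.

## Cleaning and interaction detection

- **Cleaning** (`clean_records`): exact duplicates dropped; a device
  registered in two zones in the same second is resolved by majority vote
  over that device's records within ±30 s (`window_s`), ties going to the
  zone of the nearest earlier retained second, then to the lexicographically
  smallest zone id.  Output order is canonical, so all downstream results
  are invariant to input row order.
- **Intervals** (`records_to_intervals`): consecutive same-zone seconds
  merge; same-zone gaps ≤ `max_gap_s` = 60 s are bridged.  The bridge
  absorbs intermittent per-second detection loss (at 85 % detection the
  probability of a >60 s gap in true presence is ~0.15^61 ≈ 0), while
  sampling blackouts — whole unsampled hours, 3 600 s — always exceed the
  bridge, so no interval or event ever spans a blackout; `max_gap_s ≥ 3600`
  is rejected outright.
- **Events** (`detect_interactions`): for each unordered pair and zone, each
  *maximal* co-presence overlap strictly longer than `min_duration_s`
  = 300 s yields one event ("more than 5 minutes" read as a strict
  inequality; configurable).  The implementation is a per-zone boundary
  sweep; it is tested for exact agreement with a brute-force per-second
  pairwise oracle on randomized instances.  An hour-bucketed variant
  (`detect_interactions_hourly`) mirrors hourly-aggregate exports; the
  second-level rule is the default analysis path.
- **Alone episodes** (`count_alone_episodes`): maximal stretches in which a
  resident occupies a zone no other tracked resident shares, longer than
  the same threshold, optionally restricted to a clock-hour window (which
  may wrap midnight, e.g. 22–6) and/or zone classes.

## Networks and features

The two-mode network links residents to zones they visited (edge weight =
number of presence intervals; dwell seconds kept as an attribute).  The
one-mode projection links residents who share at least one event (weight =
event count), conserving total weight = number of events.

Per-resident features stratify by (partner's roommate status × zone class
of the event): roommates in the shared own bedroom, non-roommates in
bedrooms, roommates in common areas, non-roommates in common areas — four
partner-count strata (distinct alters, counted once per stratum) and the
matching four frequency strata plus alone-episode frequency, all expressed
per *sampled* day (`window_days` divisor; no extrapolation to unsampled
hours, an optional ×2 convention would be a caller-side choice).  Two edge
cases are deliberate: a non-roommate event held in the ego's own bedroom
counts in the non-roommate bedroom stratum (the nine-feature layout has no
separate cell for it), and roommates meeting in a third party's bedroom
fall into an "other" bucket counted only in the totals.  Degree centrality
defaults to Freeman-normalized binary degree, distinct partners / (N − 1);
published centrality figures in this literature are not always consistent
with that normalization, which is why the formula is a configuration point
rather than a constant.

Group summaries report unweighted within-group means and a
participant-weighted overall row (equal to the plain mean over residents).
`pooled_mean` exposes the same aggregation for combining already-published
per-group summaries.

## Cluster typology

k-means (Euclidean) runs on the nine features, z-scored by default so the
large frequency scales do not dominate the metric (a raw-scale option is
retained, since published centroid tables are typically raw-scale).  The
sweep covers k = 1…10 with 50 restarts per k and a mandatory seed; the
elbow is the k maximizing the second forward difference of WCSS, ties to
the smallest k, with a manual override because cluster solutions must also
make conceptual sense — on smooth decay curves the pure second-difference
rule favours k = 2.

Typology labels come from raw-scale cluster means, rules applied in order,
each label used once, ties broken to the smallest cluster index and flagged:
Restricted (lowest summed partners *and* lowest summed frequencies), Diverse
common area (highest roommate frequency in common areas), Non-roommate-
focused (highest non-roommate frequency in common areas), Diverse bedroom
(highest roommate frequency in own bedrooms), Roommate-focused
(above-average roommate partners, below-average non-roommate common-area
contact); anything else is `unclassified`.  These rules reproduce the
canonical five-cluster naming on published-style centroids and are invariant
to cluster index permutation.

Reporting marks cluster means at least 0.5 SD from the overall mean; the SD
defaults to the across-resident SD of each feature (the across-cluster SD is
a selectable alternative, as the convention differs between reports).
Contingency tables give within-bedroom-type percentages and flag the
largest share per type.

## Associations

Predictors are the bedroom-level privacy scores (total + five factors)
broadcast to residents; rows within a bedroom therefore share predictor
values, a non-independence the package documents rather than models (no
mixed-effects layer).  The default 9 × 6 table reports zero-order Pearson
correlations with two-sided p-values and `*` (p < 0.05) / `**` (p < 0.01)
tiers, uncorrected by default with an optional Benjamini–Hochberg flag.  A
standardized-OLS mode exists for full-rank designs; with predictors taking
only four distinct values (one per bedroom type) the five factors are
exactly collinear, and the OLS path raises an error naming the redundant
columns (or drops them on request) instead of silently pseudo-inverting.

`null_calibration` measures the test's empirical behaviour against the real
discrete predictor design: each replicate draws an outcome
`y = effect · z(x) + N(0,1)` and records rejections at α = 0.05.  With
`effect = 0` this is the type-I error (expected within the binomial band
around 0.05); with a strong planted negative effect (−1.5 SD per SD) it is
power and sign recovery.  Replicating the full facility simulation per
draw would measure the same thing at enormous cost; the calibration
isolates the inference layer, while the simulator-based recovery checks
(below) cover the mechanical pathway.

## Synthetic data generator

The simulator emulates the data regime of a BLE room-tracking deployment:
second-level records, alternating-hour sampling (12 of 24 h, even hours by
default, phase configurable), 85 % per-second detection, and 2 % cross-talk
duplication in which a *detected* record is copied into a physically
adjacent zone the same second (duplicating only detected records matches
two sensors hearing one device, and is why duplicates surface as resolvable
conflicts rather than interval-splitting singletons).

Movement is a semi-Markov dwell model: staggered 600 s slots in which each
resident stays in their own bedroom, visits a partner's bedroom (partner
drawn with probability ∝ a symmetric affinity matrix), or sits in a common
area, with probabilities set by the behaviour profile of the resident's
planted cluster; nights (22:00–06:00) are spent in bed apart from a small
night-out probability.  Default planted structure: three clusters assigned
by whole bedrooms (rooms round-robin, so bedroom types mix across
clusters) — bedroom-social (own 0.50 / visit 0.45 / common 0.05),
common-area-social (0.42 / 0.03 / 0.55) and restricted (0.96 / 0.01 /
0.03) — with within-cluster affinity 1.0 against 0.05 between.  All
randomness derives from one seed through per-resident sub-streams, so equal
configurations give byte-identical streams.

Ground truth is computed inside the generator by an independent
interval-intersection routine on the noiseless trajectories clipped to
sampled hours, never by the detection module, so "zero noise in, truth out"
is a genuine dual-route check.

What the generator does *not* emulate: radio propagation and RSSI noise
(loss and duplication are i.i.d. per second rather than spatially
correlated), staff and visitors, device charging downtime, circadian
variation beyond the day/night split, and — importantly — the sparsity of
real LTC networks.  Shared common rooms in a 48-person unit make simulated
residents accumulate far more distinct partners than frail older adults do
in reality, so passing tests demonstrate correctness of the pipeline's
accounting and recoverability of planted structure, not realism of network
density.  Published second-entry and hourly-record totals for such
deployments also do not reconcile exactly with roster × duration ×
sampling arithmetic, and the generator makes no attempt to match them.

## Numerical and reporting conventions

- Strict `>` at the 300 s event threshold; half-open intervals everywhere.
- Cleaning ties: previous retained second, then lexicographic smallest.
- Elbow ties: smallest k; WCSS increasing with k triggers a warning.
- z-scoring guards zero-variance features (scale 1); zero-variance columns
  in correlations yield `NaN` cells marked `na`; zero SD produces no
  extremeness flags.
- Display rounding is round-half-up to 2 decimals (internal computation at
  full precision); published tables are themselves not perfectly consistent
  in their last digit, so checks against printed aggregates use one unit of
  the last printed digit where needed.
- Seeds are mandatory for k-means and the simulator; k-means uses
  per-k derived seeds, the simulator per-resident spawned sub-streams.

## Problem sizes

The test-suite and the acceptance script exercise the full 48-resident
facility at 1–2 simulated days (alternating-hour sampling, i.e. 12 sampled
hours per day), 100-seed randomized oracle batches at up to 5 residents ×
2 h, and 1 000-replicate calibration runs — sizes chosen so the entire
verification cycle completes in about a minute on a laptop while every
stage still operates far from trivial regimes (≈1.8 M records, ≈3 000
events per simulated day).  Longer horizons only tighten the frequency
estimates; nothing in the pipeline depends on the one-month horizon of a
real deployment.

## Known limitations

- Privacy predictors vary only at bedroom-type level in the default
  facility: four distinct design points, hence collinear factors and
  within-bedroom dependence (documented, not modelled).
- Interaction direction is unobservable in co-presence data; in/out-degree
  are deliberately absent.
- The co-presence rule cannot distinguish interaction from silent
  co-location; "meaningful interaction" is an operational definition.
- Cluster naming is rule-based on centroid order statistics; genuinely
  novel cluster shapes fall back to `unclassified` rather than forcing a
  label.
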