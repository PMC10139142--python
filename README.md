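# carenet

Spatio-social network analysis of indoor co-location data in long-term care
(LTC) facilities.

Compact LTC facilities house older adults in shared bedrooms whose
architecture — how many beds, what the room adjoins, whether residents can
see and be seen from the common areas — shapes who meets whom.  `carenet`
turns raw room-level indoor-positioning streams (one `device_id, timestamp,
zone_id` record per second, as produced by BLE beacon systems) into social
networks and relates their structure to bedroom privacy.  It is written for
researchers in environmental gerontology and network epidemiology who want a
tested, reproducible pipeline instead of spreadsheet bookkeeping, and it
ships with an agent-based simulator so every stage can be exercised without
access to (typically confidential) resident tracking data.

## The method

1. **Bedroom privacy instrument.**  Each shared bedroom is audited on five
   architectural factors: occupancy (5+ beds = 0 … ≤2 = 3), adjacency
   (public = 0 … private = 3), transitional spaces between bedroom and
   common area (count, capped at 3), visibility (can residents see the
   common areas?) and visual privacy (can their beds be seen? visible = 0).
   The total ∈ [0, 11] rises with privacy.
2. **Meaningful interactions.**  After cleaning (de-duplication and
   majority-vote resolution of conflicting zone fixes) and interval
   compression (gaps ≤ 60 s bridged), two residents co-present in one zone
   for strictly more than 5 minutes generate one dyadic interaction event;
   *k* co-present residents generate all *k(k−1)/2* dyads.
3. **Networks.**  Presence intervals define the two-mode (bipartite)
   resident–location network; events define the one-mode resident–resident
   network with tie strength `w_ij` = event count.  Per-resident features
   stratify partner counts and daily contact frequencies by roommate status
   and zone class, plus Freeman-normalized degree centrality
   `C_D(i) = deg(i) / (N − 1)`.
4. **Typology.**  k-means (Euclidean, best of 50 restarts, k = 1…10) on the
   nine z-scored features; k chosen at the elbow of the WCSS curve (manual
   override supported); clusters named Diverse (common area) / Diverse
   (bedroom) / Non-roommate-focused / Roommate-focused / Restricted by
   centroid comparison; cluster × bedroom-type contingency tables.
5. **Associations.**  A 9-outcome × 6-predictor table of Pearson
   correlations (or standardized OLS) between network features and
   bedroom-level privacy scores broadcast to residents, with `*`/`**`
   significance tiers and Monte-Carlo calibration utilities.

## Worked example

```python
import carenet as cn
from carenet.copresence import (CleaningReport, clean_records,
                                detect_interactions, records_to_intervals)

facility = cn.build_default_facility()          # 48 residents, 4 bedroom types
config = cn.SimulationConfig(facility=facility, n_days=1, rng_seed=42)
records, truth = cn.simulate(config)            # noisy alternating-hour stream

report = CleaningReport()
cleaned = clean_records(records, report=report)
intervals = records_to_intervals(cleaned)
events = detect_interactions(intervals, roster=facility.roster())
print(len(records), report.n_conflict_seconds, len(events), len(truth.true_events))
```

prints `1797570 35086 2921 2925`: one simulated day yields ~1.8 M records
(85 % of 48 × 43 200 sampled seconds, plus cross-talk duplicates), 35 086
seconds needed majority-vote conflict resolution, and the detector recovers
2 921 of the 2 925 interaction events an ideal lossless sensor would have
seen — gap bridging absorbs nearly all of the 15 % per-second detection
loss.  Scoring the same facility's bedrooms
(`cn.assess_facility(facility)`) gives privacy totals of 7 (three-bed), 5
(four-bed corridor), 4 (five-bed) and 2 (four-bed facing common areas):
the most crowded room type is not the least private once adjacency,
buffers and sight lines are counted.

The `examples/` directory walks through each capability (privacy scoring,
simulation + detection, network features, cluster typology, associations) as
short narrative scripts, and the `carenet` command line exposes the same
pipeline (`carenet simulate`, `carenet interactions`, `carenet all …`).

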