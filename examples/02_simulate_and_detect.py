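"""Generate a synthetic location stream and detect meaningful interactions.

One simulated day of second-by-second device-zone records (alternating-hour
sampling, 85% detection, 2% cross-talk duplication) is cleaned, compressed to
presence intervals, and scanned for dyadic co-presence episodes longer than
five minutes.
"""

import carenet as cn
from carenet.copresence import (
    CleaningReport,
    clean_records,
    detect_interactions,
    records_to_intervals,
)

facility = cn.build_default_facility()
config = cn.SimulationConfig(facility=facility, n_days=1, rng_seed=42)
records, truth = cn.simulate(config)
print(f"raw records: {len(records):,}")

report = CleaningReport()
cleaned = clean_records(records, report=report)
intervals = records_to_intervals(cleaned)
events = detect_interactions(intervals, roster=facility.roster())

print(f"conflicting seconds resolved: {report.n_conflict_seconds:,}")
print(f"presence intervals: {len(intervals):,}")
print(f"meaningful interactions detected: {len(events):,} "
      f"(ground truth without sensor noise: {len(truth.true_events):,})")
print(f"median interaction length: {events['duration_s'].median():.0f} s")
print(
    "Detection loss shortens and occasionally splits co-presence episodes, "
    "so the detected count sits a little below the noise-free ground truth."
)
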