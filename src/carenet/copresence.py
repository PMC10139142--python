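"""Cleaning of raw device-zone location streams and detection of
meaningful-interaction events.

The raw input is a stream of second-by-second location records
(``device_id, timestamp, zone_id``) from an indoor positioning system.  Such
streams carry two characteristic noise modes: *loss* (a device goes
undetected for a second) and *duplication* (cross-talk registers a device on
two sensors in the same second).  The pipeline is:

1. :func:`clean_records` — drop malformed/duplicate rows and resolve
   one-device-two-zones conflicts by a majority vote over a sliding context
   window.
2. :func:`records_to_intervals` — compress per-second records into presence
   intervals, bridging short detection gaps (default 60 s) within a zone.
3. :func:`detect_interactions` — emit one dyadic event per maximal co-presence
   overlap of two residents in the same zone that lasts strictly longer than
   ``min_duration_s`` (default 300 s, i.e. "more than 5 minutes").

Timestamps are integer epoch seconds (UTC); intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "EVENT_COLUMNS",
    "CleaningReport",
    "read_records",
    "write_records",
    "clean_records",
    "records_to_intervals",
    "detect_interactions",
    "detect_interactions_hourly",
    "count_alone_episodes",
]

RECORD_COLUMNS = ["device_id", "timestamp", "zone_id"]
INTERVAL_COLUMNS = ["device_id", "zone_id", "start", "end"]
EVENT_COLUMNS = ["resident_a", "resident_b", "zone_id", "start", "end", "duration_s"]


class RosterError(KeyError):
    """A device in the stream is not in the resident roster."""


@dataclass
class CleaningReport:
    """Row accounting for one cleaning pass."""

    n_rows_in: int = 0
    n_malformed: int = 0
    n_exact_duplicates: int = 0
    n_conflict_seconds: int = 0
    n_conflict_rows_dropped: int = 0
    n_rows_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record stream as CSV with header ``device_id,timestamp,zone_id``."""
    out = pd.DataFrame(
        {
            "device_id": records["device_id"].astype(str),
            "timestamp": records["timestamp"].astype(np.int64),
            "zone_id": records["zone_id"].astype(str),
        }
    )
    out.to_csv(path, index=False)


def read_records(path) -> tuple[pd.DataFrame, int]:
    """Read a record CSV; returns ``(records, n_malformed)``.

    Rows with missing fields or non-integer timestamps are counted and
    skipped rather than raising.
    """
    df = pd.read_csv(
        path, dtype={"device_id": str, "zone_id": str}, keep_default_na=False
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file missing columns: {missing}")
    ts = pd.to_numeric(df["timestamp"], errors="coerce")
    bad = (
        ts.isna()
        | (ts != np.floor(ts.fillna(0)))
        | (df["device_id"].astype(str) == "")
        | (df["zone_id"].astype(str) == "")
    )
    n_malformed = int(bad.sum())
    df = df.loc[~bad, RECORD_COLUMNS].copy()
    df["timestamp"] = ts[~bad].astype(np.int64)
    return df.reset_index(drop=True), n_malformed


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def clean_records(
    records: pd.DataFrame,
    window_s: int = 30,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Resolve the stream to exactly one zone per (device, second).

    Exact duplicate rows are dropped first.  A remaining conflict (one device
    in two or more zones at one second) is resolved by majority vote over the
    device's records within ``±window_s`` seconds; ties go to the zone of the
    nearest earlier retained second, else to the lexicographically smallest
    zone id.  Output is sorted by (device, timestamp) — downstream results are
    therefore invariant to input row order.
    """
    if report is None:
        report = CleaningReport()
    report.n_rows_in = len(records)
    df = records[RECORD_COLUMNS].copy()
    df["timestamp"] = df["timestamp"].astype(np.int64)

    n0 = len(df)
    df = df.drop_duplicates()
    report.n_exact_duplicates = n0 - len(df)

    df = df.sort_values(["device_id", "timestamp", "zone_id"], kind="mergesort")
    dup_mask = df.duplicated(["device_id", "timestamp"], keep=False)
    if not dup_mask.any():
        report.n_conflict_seconds = 0
        report.n_rows_out = len(df)
        return df.reset_index(drop=True)

    clean_parts = [df[~dup_mask]]
    conflicts = df[dup_mask]
    report.n_conflict_seconds = int(
        conflicts.groupby(["device_id", "timestamp"], sort=False).ngroups
    )

    resolved_rows: list[tuple[str, int, str]] = []
    for device, dev_conf in conflicts.groupby("device_id", sort=False):
        dev_all = df[df["device_id"] == device]
        # per-zone sorted timestamp arrays for fast windowed counts
        ts_by_zone = {
            z: g["timestamp"].to_numpy()
            for z, g in dev_all.groupby("zone_id", sort=False)
        }
        clean_dev = dev_all[~dev_all.duplicated(["device_id", "timestamp"], keep=False)]
        clean_ts = clean_dev["timestamp"].to_numpy()
        clean_zone = clean_dev["zone_id"].to_numpy()

        chosen: dict[int, str] = {}
        for t, grp in dev_conf.groupby("timestamp", sort=True):
            candidates = sorted(grp["zone_id"].unique())
            counts = {
                z: int(
                    np.searchsorted(ts_by_zone[z], t + window_s, side="right")
                    - np.searchsorted(ts_by_zone[z], t - window_s, side="left")
                )
                for z in candidates
            }
            best = max(counts.values())
            winners = sorted(z for z, c in counts.items() if c == best)
            if len(winners) > 1:
                # tie: zone of the nearest earlier retained second
                prev_zone = None
                i = np.searchsorted(clean_ts, t) - 1
                if i >= 0:
                    prev_zone = clean_zone[i]
                prev_resolved = [tt for tt in chosen if tt < t]
                if prev_resolved:
                    tt = max(prev_resolved)
                    if i < 0 or tt > clean_ts[i]:
                        prev_zone = chosen[tt]
                if prev_zone in winners:
                    pick = prev_zone
                else:
                    pick = winners[0]
            else:
                pick = winners[0]
            chosen[t] = pick
            resolved_rows.append((device, t, pick))

    resolved = pd.DataFrame(resolved_rows, columns=RECORD_COLUMNS)
    resolved["timestamp"] = resolved["timestamp"].astype(np.int64)
    report.n_conflict_rows_dropped = len(conflicts) - len(resolved)
    out = pd.concat(clean_parts + [resolved], ignore_index=True)
    out = out.sort_values(["device_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    report.n_rows_out = len(out)
    return out


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


def records_to_intervals(records: pd.DataFrame, max_gap_s: int = 60) -> pd.DataFrame:
    """Merge consecutive same-zone seconds into presence intervals.

    A gap of up to ``max_gap_s`` seconds within the same zone is bridged (it
    absorbs intermittent detection loss).  Gaps across sampling blackouts are
    never bridged because a blackout (a whole unsampled hour, 3600 s) always
    exceeds any sane ``max_gap_s``; values >= 3600 are rejected for this
    reason.

    Returns a frame with columns ``device_id, zone_id, start, end`` where
    ``end`` is exclusive (a record at second ``t`` covers ``[t, t+1)``).
    """
    if max_gap_s >= 3600:
        raise ValueError("max_gap_s must be < 3600 to respect sampling blackouts")
    if len(records) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    df = records.sort_values(["device_id", "timestamp"], kind="mergesort")
    ts = df["timestamp"].to_numpy(np.int64)
    dev = df["device_id"].to_numpy()
    zone = df["zone_id"].to_numpy()
    new_run = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        same_dev = dev[1:] == dev[:-1]
        same_zone = zone[1:] == zone[:-1]
        small_gap = (ts[1:] - ts[:-1]) <= (max_gap_s + 1)
        new_run[1:] = ~(same_dev & same_zone & small_gap)
    run_id = np.cumsum(new_run)
    out = (
        pd.DataFrame(
            {"device_id": dev, "zone_id": zone, "timestamp": ts, "run": run_id}
        )
        .groupby("run", sort=True)
        .agg(
            device_id=("device_id", "first"),
            zone_id=("zone_id", "first"),
            start=("timestamp", "min"),
            end=("timestamp", "max"),
        )
        .reset_index(drop=True)
    )
    out["end"] = out["end"] + 1  # half-open
    return out[INTERVAL_COLUMNS]


def _merge_touching(intervals: np.ndarray) -> np.ndarray:
    """Union of sorted [start, end) rows, merging overlapping/touching ones."""
    if len(intervals) == 0:
        return intervals
    order = np.argsort(intervals[:, 0], kind="mergesort")
    iv = intervals[order]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------


def _map_devices(
    intervals: pd.DataFrame,
    roster: Mapping[str, str] | Sequence[str] | None,
    on_unknown: str,
) -> pd.DataFrame:
    """Map device ids to resident ids; handle devices outside the roster."""
    if roster is None:
        out = intervals.copy()
        out["resident"] = out["device_id"]
        return out
    if not isinstance(roster, Mapping):
        roster = {r: r for r in roster}
    known = intervals["device_id"].isin(roster.keys())
    if not known.all():
        unknown = sorted(intervals.loc[~known, "device_id"].unique())
        if on_unknown == "raise":
            raise RosterError(f"devices not in roster: {unknown}")
        intervals = intervals[known]
    out = intervals.copy()
    out["resident"] = out["device_id"].map(dict(roster))
    return out


def detect_interactions(
    intervals: pd.DataFrame,
    min_duration_s: int = 300,
    roster: Mapping[str, str] | Sequence[str] | None = None,
    on_unknown: str = "skip",
) -> pd.DataFrame:
    """Detect meaningful dyadic interactions from presence intervals.

    For every unordered resident pair and zone, each *maximal* overlap of the
    two residents' presence with length strictly greater than
    ``min_duration_s`` yields one event; ``k`` residents fully co-present
    yield all ``k*(k-1)/2`` dyadic events.  Events are returned sorted by
    (start, resident_a, resident_b, zone_id) with ``resident_a < resident_b``.

    ``roster`` maps device ids to resident ids (or lists permitted device
    ids); devices outside it are skipped or, with ``on_unknown="raise"``,
    rejected.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    iv = _map_devices(intervals, roster, on_unknown)
    events: list[tuple] = []
    for zone, g in iv.groupby("zone_id", sort=True):
        per_res = {
            r: _merge_touching(rg[["start", "end"]].to_numpy(np.int64))
            for r, rg in g.groupby("resident", sort=True)
        }
        if len(per_res) < 2:
            continue
        # boundary sweep: ends before starts at equal time (half-open)
        bounds: list[tuple[int, int, str]] = []
        for r, arr in per_res.items():
            for s, e in arr:
                bounds.append((int(s), 1, r))
                bounds.append((int(e), 0, r))
        bounds.sort()
        active: set[str] = set()
        open_runs: dict[tuple[str, str], int] = {}
        for t, typ, r in bounds:
            if typ == 1:
                for s in active:
                    pair = (r, s) if r < s else (s, r)
                    open_runs[pair] = t
                active.add(r)
            else:
                active.discard(r)
                for s in list(active):
                    pair = (r, s) if r < s else (s, r)
                    start = open_runs.pop(pair, None)
                    if start is not None and t - start > min_duration_s:
                        events.append((pair[0], pair[1], zone, start, t, t - start))
    out = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return out.sort_values(
        ["start", "resident_a", "resident_b", "zone_id"], kind="mergesort"
    ).reset_index(drop=True)


def detect_interactions_hourly(
    intervals: pd.DataFrame,
    min_duration_s: int = 300,
    roster: Mapping[str, str] | Sequence[str] | None = None,
    on_unknown: str = "skip",
) -> pd.DataFrame:
    """Hour-bucketed variant of the interaction rule.

    Mirrors an hour-by-hour aggregation of the stream: for each clock hour,
    pair and zone, an event is emitted when the pair's total co-presence in
    that zone *within the hour* exceeds ``min_duration_s``.  Provided for
    parity with hourly record exports; the second-level
    :func:`detect_interactions` is the default analysis path.
    """
    if len(intervals) == 0:
        return pd.DataFrame(columns=["resident_a", "resident_b", "zone_id", "hour", "copresence_s"])
    iv = _map_devices(intervals, roster, on_unknown)
    rows: list[tuple] = []
    for zone, g in iv.groupby("zone_id", sort=True):
        per_res = {
            r: _merge_touching(rg[["start", "end"]].to_numpy(np.int64))
            for r, rg in g.groupby("resident", sort=True)
        }
        residents = sorted(per_res)
        for i, a in enumerate(residents):
            for b in residents[i + 1 :]:
                for s, e, _ in _intersect(per_res[a], per_res[b]):
                    h0, h1 = s // 3600, (e - 1) // 3600
                    for h in range(h0, h1 + 1):
                        lo, hi = max(s, h * 3600), min(e, (h + 1) * 3600)
                        rows.append((a, b, zone, h, hi - lo))
    df = pd.DataFrame(
        rows, columns=["resident_a", "resident_b", "zone_id", "hour", "copresence_s"]
    )
    if len(df) == 0:
        return df
    agg = (
        df.groupby(["resident_a", "resident_b", "zone_id", "hour"], sort=True)[
            "copresence_s"
        ]
        .sum()
        .reset_index()
    )
    return agg[agg["copresence_s"] > min_duration_s].reset_index(drop=True)


def _intersect(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int, int]]:
    """Pairwise intersection of two sorted disjoint interval arrays."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((int(s), int(e), int(e - s)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# Alone episodes
# ---------------------------------------------------------------------------


def count_alone_episodes(
    intervals: pd.DataFrame,
    all_residents: Sequence[str],
    min_duration_s: int = 300,
    hour_window: tuple[int, int] | None = None,
    zone_classes: Sequence[str] | None = None,
    facility=None,
    roster: Mapping[str, str] | Sequence[str] | None = None,
) -> pd.Series:
    """Count, per resident, maximal solo-presence episodes longer than
    ``min_duration_s``.

    A resident is *alone* while present in a zone that no other tracked
    resident occupies.  ``hour_window=(h0, h1)`` restricts counting to clock
    hours ``h0 <= hour < h1`` (``h0 > h1`` wraps past midnight, e.g. (22, 6));
    episodes are clipped to the window before the duration test.
    ``zone_classes`` (with ``facility``) restricts to zones of those classes,
    e.g. alone time in common areas only.
    """
    counts = pd.Series(0, index=sorted(all_residents), dtype=int, name="alone_episodes")
    if len(intervals) == 0:
        return counts
    iv = _map_devices(intervals, roster, "skip")
    if zone_classes is not None:
        if facility is None:
            raise ValueError("zone_classes filter requires a facility")
        keep = {
            z.zone_id
            for z in facility.zones.values()
            if z.zone_class.value in set(zone_classes)
        }
        iv = iv[iv["zone_id"].isin(keep)]
    for zone, g in iv.groupby("zone_id", sort=True):
        per_res = {
            r: _merge_touching(rg[["start", "end"]].to_numpy(np.int64))
            for r, rg in g.groupby("resident", sort=True)
        }
        starts: dict[int, list[str]] = {}
        ends: dict[int, list[str]] = {}
        for r, arr in per_res.items():
            for s, e in arr:
                starts.setdefault(int(s), []).append(r)
                ends.setdefault(int(e), []).append(r)
        times = sorted(set(starts) | set(ends))
        active: set[str] = set()
        segments: dict[str, list[tuple[int, int]]] = {r: [] for r in per_res}
        for i, t in enumerate(times):
            for r in ends.get(t, ()):
                active.discard(r)
            for r in starts.get(t, ()):
                active.add(r)
            if len(active) == 1 and i + 1 < len(times):
                r = next(iter(active))
                segments[r].append((t, times[i + 1]))
        for r, segs in segments.items():
            merged = _merge_touching(np.asarray(segs, dtype=np.int64)) if segs else []
            for s, e in merged:
                for cs, ce in _clip_to_hours(int(s), int(e), hour_window):
                    if ce - cs > min_duration_s and r in counts.index:
                        counts[r] += 1
    return counts


def _clip_to_hours(
    start: int, end: int, hour_window: tuple[int, int] | None
) -> list[tuple[int, int]]:
    """Intersect [start, end) with the daily clock-hour window."""
    if hour_window is None:
        return [(start, end)]
    h0, h1 = hour_window
    out = []
    day0 = start // 86400
    day1 = (end - 1) // 86400
    for day in range(day0, day1 + 2):
        base = day * 86400
        if h0 < h1:
            windows = [(base + h0 * 3600, base + h1 * 3600)]
        else:  # wraps midnight
            windows = [(base + h0 * 3600, base + 86400), (base, base + h1 * 3600)]
        for ws, we in windows:
            s, e = max(start, ws), min(end, we)
            if e > s:
                out.append((s, e))
    return sorted(set(out))
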