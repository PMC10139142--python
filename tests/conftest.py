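import numpy as np
import pandas as pd
import pytest

from carenet.facility import (
    AdjacencyClass,
    BedroomType,
    Facility,
    Resident,
    Zone,
    ZoneClass,
)


@pytest.fixture(scope="session")
def tiny_facility() -> Facility:
    """Five residents in two bedrooms plus a lounge and corridor."""
    zones = [
        Zone("B1", ZoneClass.BEDROOM, adjacency_class=AdjacencyClass.SEMI_PRIVATE,
             n_transitional_to_common=2, sees_common=False,
             beds_visible_from_common=False, capacity=3, neighbors=("corridor",)),
        Zone("B2", ZoneClass.BEDROOM, adjacency_class=AdjacencyClass.PUBLIC,
             n_transitional_to_common=0, sees_common=True,
             beds_visible_from_common=True, capacity=4, neighbors=("corridor",)),
        Zone("lounge", ZoneClass.COMMON, neighbors=("corridor",)),
        Zone("corridor", ZoneClass.TRANSITIONAL,
             neighbors=("B1", "B2", "lounge")),
    ]
    residents = [
        Resident("a", "B1", BedroomType.THREE_BED),
        Resident("b", "B1", BedroomType.THREE_BED),
        Resident("c", "B2", BedroomType.FOUR_BED_COMMON),
        Resident("d", "B2", BedroomType.FOUR_BED_COMMON),
        Resident("e", "B2", BedroomType.FOUR_BED_COMMON),
    ]
    return Facility(zones, residents)


def records_from_spans(spans) -> pd.DataFrame:
    """Expand (device, zone, start, end) spans into per-second records."""
    rows = []
    for device, zone, start, end in spans:
        for t in range(start, end):
            rows.append((device, t, zone))
    return pd.DataFrame(rows, columns=["device_id", "timestamp", "zone_id"])


def intervals_from_spans(spans) -> pd.DataFrame:
    return pd.DataFrame(
        [(d, z, s, e) for d, z, s, e in spans],
        columns=["device_id", "zone_id", "start", "end"],
    )


def brute_force_events(intervals: pd.DataFrame, min_duration_s: int = 300) -> pd.DataFrame:
    """Second-by-second pairwise co-presence scan (independent oracle).

    Presence is expanded to individual seconds; for every unordered pair and
    zone, maximal runs of shared seconds longer than ``min_duration_s``
    become events.
    """
    presence: dict[str, dict[int, str]] = {}
    for row in intervals.itertuples(index=False):
        d = presence.setdefault(row.device_id, {})
        for t in range(int(row.start), int(row.end)):
            d[t] = row.zone_id
    devices = sorted(presence)
    events = []
    for i, a in enumerate(devices):
        for b in devices[i + 1:]:
            shared = sorted(set(presence[a]) & set(presence[b]))
            run_start = None
            run_zone = None
            prev = None
            for t in shared + [None]:
                same_zone = t is not None and presence[a][t] == presence[b][t]
                contiguous = prev is not None and t == prev + 1 and same_zone \
                    and presence[a][t] == run_zone
                if contiguous:
                    prev = t
                    continue
                if run_start is not None and prev is not None:
                    dur = prev + 1 - run_start
                    if dur > min_duration_s:
                        events.append((a, b, run_zone, run_start, prev + 1, dur))
                if t is not None and same_zone:
                    run_start, run_zone, prev = t, presence[a][t], t
                else:
                    run_start = run_zone = prev = None
    out = pd.DataFrame(
        events,
        columns=["resident_a", "resident_b", "zone_id", "start", "end", "duration_s"],
    )
    return out.sort_values(
        ["start", "resident_a", "resident_b", "zone_id"], kind="mergesort"
    ).reset_index(drop=True)


def brute_force_alone(
    intervals: pd.DataFrame,
    residents,
    min_duration_s: int = 300,
    hour_window=None,
) -> pd.Series:
    """Per-second solitude scan: maximal runs alone in a zone, clipped to the
    clock-hour window, counted if longer than the threshold."""
    presence: dict[str, dict[int, str]] = {}
    for row in intervals.itertuples(index=False):
        d = presence.setdefault(row.device_id, {})
        for t in range(int(row.start), int(row.end)):
            d[t] = row.zone_id
    occupancy: dict[tuple[int, str], int] = {}
    for d, tz in presence.items():
        for t, z in tz.items():
            occupancy[(t, z)] = occupancy.get((t, z), 0) + 1

    def in_window(t):
        if hour_window is None:
            return True
        h0, h1 = hour_window
        h = (t // 3600) % 24
        return (h0 <= h < h1) if h0 < h1 else (h >= h0 or h < h1)

    counts = pd.Series(0, index=sorted(residents), dtype=int)
    for r in counts.index:
        tz = presence.get(r, {})
        solo = sorted(
            t for t, z in tz.items() if occupancy[(t, z)] == 1 and in_window(t)
        )
        run = 0
        prev = None
        prev_zone = None
        for t in solo + [None]:
            if (
                t is not None
                and prev is not None
                and t == prev + 1
                and tz[t] == prev_zone
            ):
                run += 1
                prev = t
                continue
            if prev is not None and run > min_duration_s:
                counts[r] += 1
            if t is not None:
                run, prev, prev_zone = 1, t, tz[t]
            else:
                run, prev, prev_zone = 0, None, None
    return counts
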