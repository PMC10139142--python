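"""Agent-based generator of device-zone location streams with planted social
structure and sensor noise.

The generator stands in for non-public indoor-positioning data from a
long-term care facility.  It emulates the data regime of a BLE room-level
tracking deployment: second-by-second ``(device, timestamp, zone)`` records,
hours sampled in alternation (12 of 24 h per day), ~85% per-second detection
probability, and occasional cross-talk duplicates in a physically adjacent
zone.

Movement follows a semi-Markov dwell model.  Time is divided into dwell slots
(default 600 s, staggered per resident); in each slot a resident either stays
in their own bedroom, visits a partner's bedroom (partner drawn with
probability proportional to a symmetric pairwise *affinity* matrix), or goes
to a common area, with mixing probabilities set by the resident's
*behaviour profile*.  Residents are partitioned into planted clusters, each
with its own profile and a high within-cluster affinity block, so the
downstream feature/clustering stages have a recoverable ground truth.

All randomness flows from a single seed; per-resident sub-streams are derived
deterministically, so identical configurations yield byte-identical streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .copresence import EVENT_COLUMNS, RECORD_COLUMNS, write_records  # noqa: F401
from .facility import (
    BEDROOM_CAPACITY,
    AdjacencyClass,
    BedroomType,
    Facility,
    Resident,
    Zone,
    ZoneClass,
)

__all__ = [
    "BehaviourProfile",
    "SimulationConfig",
    "GroundTruth",
    "build_default_facility",
    "default_profiles",
    "default_clusters",
    "build_affinity",
    "simulate",
    "write_records",
]

SECONDS_PER_DAY = 86400
NIGHT_HOURS = frozenset({22, 23, 0, 1, 2, 3, 4, 5})


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class BehaviourProfile:
    """Daytime activity mix of one planted cluster.

    ``p_own`` + ``p_visit`` + ``p_common`` must sum to 1; ``p_night_out`` is
    the per-slot probability of sitting in a common area during night hours
    (otherwise the resident is in bed).
    """

    name: str
    p_own: float
    p_visit: float
    p_common: float
    p_night_out: float = 0.01

    def __post_init__(self):
        probs = (self.p_own, self.p_visit, self.p_common, self.p_night_out)
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError(f"profile {self.name!r}: probabilities must be in [0,1]")
        if abs(self.p_own + self.p_visit + self.p_common - 1.0) > 1e-9:
            raise ConfigError(
                f"profile {self.name!r}: day probabilities must sum to 1"
            )


def default_profiles() -> list[BehaviourProfile]:
    """Three contrasting activity mixes: bedroom-social, common-area-social,
    and restricted."""
    return [
        BehaviourProfile("bedroom_social", p_own=0.50, p_visit=0.45, p_common=0.05,
                         p_night_out=0.04),
        BehaviourProfile("common_social", p_own=0.42, p_visit=0.03, p_common=0.55,
                         p_night_out=0.01),
        BehaviourProfile("restricted", p_own=0.96, p_visit=0.01, p_common=0.03,
                         p_night_out=0.0),
    ]


def default_clusters(facility: Facility, n_clusters: int = 3) -> list[list[str]]:
    """Partition the roster into ``n_clusters`` planted clusters by whole
    bedrooms (rooms assigned round-robin, so bedroom *types* mix across
    clusters).  Room-aligned clusters keep the planted structure physically
    coherent: roommates share one social milieu, and visitors to a bedroom
    meet residents of their own cluster."""
    rooms = sorted({facility.residents[r].bedroom_zone for r in facility.roster()})
    clusters: list[list[str]] = [[] for _ in range(n_clusters)]
    for i, room in enumerate(rooms):
        clusters[i % n_clusters].extend(facility.occupants(room))
    return [sorted(c) for c in clusters]


def build_affinity(
    facility: Facility,
    clusters: Sequence[Sequence[str]],
    within: float = 1.0,
    between: float = 0.05,
) -> pd.DataFrame:
    """Symmetric zero-diagonal pairwise visit-propensity matrix with block
    structure along the planted clusters."""
    roster = facility.roster()
    label = {}
    for c, members in enumerate(clusters):
        for r in members:
            label[r] = c
    n = len(roster)
    aff = np.full((n, n), between, dtype=float)
    for i, a in enumerate(roster):
        for j, b in enumerate(roster):
            if i != j and label.get(a) == label.get(b) and label.get(a) is not None:
                aff[i, j] = within
    np.fill_diagonal(aff, 0.0)
    return pd.DataFrame(aff, index=roster, columns=roster)


# ---------------------------------------------------------------------------
# Default facility (one residential unit)
# ---------------------------------------------------------------------------

_BEDROOM_ATTRS = {
    BedroomType.THREE_BED: dict(
        adjacency_class=AdjacencyClass.SEMI_PRIVATE,
        n_transitional_to_common=2,
        sees_common=False,
        beds_visible_from_common=False,
    ),
    BedroomType.FOUR_BED_CORRIDOR: dict(
        adjacency_class=AdjacencyClass.SEMI_PUBLIC,
        n_transitional_to_common=1,
        sees_common=True,
        beds_visible_from_common=False,
    ),
    BedroomType.FOUR_BED_COMMON: dict(
        adjacency_class=AdjacencyClass.PUBLIC,
        n_transitional_to_common=0,
        sees_common=True,
        beds_visible_from_common=True,
    ),
    BedroomType.FIVE_BED: dict(
        adjacency_class=AdjacencyClass.SEMI_PUBLIC,
        n_transitional_to_common=2,
        sees_common=False,
        beds_visible_from_common=False,
    ),
}

# (bedroom type, zone prefix, participants per room); every room keeps >= 2
# participants so each resident has at least one tracked roommate
_DEFAULT_ROOMS = [
    (BedroomType.THREE_BED, "B3", [3, 2, 2]),            # 7 residents
    (BedroomType.FOUR_BED_CORRIDOR, "BC", [4, 4, 4, 3, 3]),  # 18
    (BedroomType.FOUR_BED_COMMON, "BM", [4, 4, 4, 3]),   # 15
    (BedroomType.FIVE_BED, "B5", [5, 3]),                # 8
]

# male participant counts per bedroom type (roster totals 24 M / 24 F)
_DEFAULT_MALES = {
    BedroomType.THREE_BED: 1,
    BedroomType.FOUR_BED_CORRIDOR: 11,
    BedroomType.FOUR_BED_COMMON: 9,
    BedroomType.FIVE_BED: 3,
}


def build_default_facility() -> Facility:
    """One residential unit: 48 tracked residents in four shared-bedroom
    types (7 three-bed, 18 four-bed corridor, 15 four-bed common, 8
    five-bed), two common areas, a corridor and a nursing station."""
    common = [
        Zone("lounge", ZoneClass.COMMON, neighbors=("corridor", "dining")),
        Zone("dining", ZoneClass.COMMON, neighbors=("corridor", "lounge")),
    ]
    other = [
        Zone("nursing_station", ZoneClass.OTHER, neighbors=("corridor",)),
    ]
    bedrooms: list[Zone] = []
    residents: list[Resident] = []
    idx = 0
    for btype, prefix, room_sizes in _DEFAULT_ROOMS:
        males_left = _DEFAULT_MALES[btype]
        for room_no, size in enumerate(room_sizes, start=1):
            zid = f"{prefix}-{room_no}"
            bedrooms.append(
                Zone(
                    zid,
                    ZoneClass.BEDROOM,
                    capacity=BEDROOM_CAPACITY[btype],
                    neighbors=("corridor",),
                    **_BEDROOM_ATTRS[btype],
                )
            )
            for _ in range(size):
                idx += 1
                sex = "M" if males_left > 0 else "F"
                males_left -= 1
                residents.append(
                    Resident(f"R{idx:02d}", bedroom_zone=zid, bedroom_type=btype, sex=sex)
                )
    corridor = Zone(
        "corridor",
        ZoneClass.TRANSITIONAL,
        neighbors=tuple(z.zone_id for z in bedrooms + common + other),
    )
    return Facility(common + other + bedrooms + [corridor], residents)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    facility: Facility
    n_days: int = 30
    slot_s: int = 600
    sampling_pattern: str = "alternating_hours"  # or "all_hours"
    sampling_phase: int = 0  # even hours sampled by default
    detection_prob: float = 0.85
    duplication_prob: float = 0.02
    interaction_min_s: int = 300
    affinity: pd.DataFrame | None = None
    planted_clusters: list[list[str]] | None = None
    profiles: list[BehaviourProfile] | None = None
    rng_seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill defaults and validate; returns a self-consistent copy."""
        cfg = replace(self)
        if cfg.planted_clusters is None:
            cfg.planted_clusters = default_clusters(cfg.facility)
        if cfg.profiles is None:
            cfg.profiles = default_profiles()
        if cfg.affinity is None:
            cfg.affinity = build_affinity(cfg.facility, cfg.planted_clusters)
        _validate(cfg)
        return cfg


def _validate(cfg: SimulationConfig) -> None:
    if cfg.n_days < 1:
        raise ConfigError("n_days must be >= 1")
    if cfg.slot_s < 1:
        raise ConfigError("slot_s must be >= 1")
    for name in ("detection_prob", "duplication_prob"):
        p = getattr(cfg, name)
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must be in [0,1], got {p}")
    if cfg.sampling_pattern not in ("all_hours", "alternating_hours"):
        raise ConfigError(f"unknown sampling_pattern {cfg.sampling_pattern!r}")
    roster = cfg.facility.roster()
    flat = [r for c in cfg.planted_clusters for r in c]
    if sorted(flat) != roster:
        raise ConfigError("planted_clusters must partition the roster")
    if len(cfg.profiles) != len(cfg.planted_clusters):
        raise ConfigError("need one behaviour profile per planted cluster")
    aff = cfg.affinity
    if list(aff.index) != roster or list(aff.columns) != roster:
        raise ConfigError("affinity must be indexed by the sorted roster")
    a = aff.to_numpy(float)
    if not np.allclose(a, a.T):
        raise ConfigError("affinity must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ConfigError("affinity diagonal must be zero")
    if np.any(a < 0):
        raise ConfigError("affinity must be non-negative")


@dataclass
class GroundTruth:
    """Noise-free truth for a simulated stream: the interaction events the
    ideal sensor would record, the planted cluster labels, and the affinity
    matrix that generated partner choices."""

    true_events: pd.DataFrame
    planted_clusters: dict[str, int]
    affinity: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "true_events": self.true_events.to_dict(orient="list"),
            "planted_clusters": self.planted_clusters,
            "affinity": {
                "index": list(self.affinity.index),
                "values": self.affinity.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        aff = pd.DataFrame(
            payload["affinity"]["values"],
            index=payload["affinity"]["index"],
            columns=payload["affinity"]["index"],
        )
        return cls(
            true_events=pd.DataFrame(payload["true_events"], columns=EVENT_COLUMNS),
            planted_clusters={k: int(v) for k, v in payload["planted_clusters"].items()},
            affinity=aff,
        )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _sampled_hour(hour_of_day: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.sampling_pattern == "all_hours":
        return np.ones_like(hour_of_day, dtype=bool)
    return (hour_of_day % 2) == (cfg.sampling_phase % 2)


def _clip_to_sampling(start: int, end: int, cfg: SimulationConfig) -> list[tuple[int, int]]:
    """Intersect [start, end) with the union of sampled clock hours, one
    piece per maximal sampled stretch (blackouts split episodes)."""
    if cfg.sampling_pattern == "all_hours":
        return [(start, end)]
    phase = cfg.sampling_phase % 2
    out: list[tuple[int, int]] = []
    h = start // 3600
    while h * 3600 < end:
        if (h % 24) % 2 == phase:
            s = max(start, h * 3600)
            e = min(end, (h + 1) * 3600)
            if e > s:
                out.append((s, e))
        h += 1
    return out


def _resident_trajectory(
    i: int,
    roster: list[str],
    cfg: SimulationConfig,
    profile: BehaviourProfile,
    aff_row: np.ndarray,
    bedroom_code: np.ndarray,
    own_code: int,
    common_codes: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Episodes (zone_code, start, end) tiling [0, n_days*86400)."""
    horizon = cfg.n_days * SECONDS_PER_DAY
    offset = int(rng.integers(0, cfg.slot_s))
    bounds = np.arange(offset, horizon, cfg.slot_s, dtype=np.int64)
    starts = np.concatenate(([0], bounds)) if offset > 0 else bounds
    ends = np.append(starts[1:], horizon)
    n_slots = len(starts)
    hours = (starts // 3600) % 24
    night = np.isin(hours, list(NIGHT_HOURS))
    u = rng.random(n_slots)

    zones = np.full(n_slots, own_code, dtype=np.int64)
    # night: mostly in bed, occasionally in a common area
    night_out = night & (u < profile.p_night_out)
    # day: visit / common / own
    day = ~night
    visit = day & (u < profile.p_visit)
    common = day & ~visit & (u < profile.p_visit + profile.p_common)

    total = aff_row.sum()
    k_visit = int(visit.sum())
    if k_visit:
        if total > 0:
            partners = rng.choice(len(roster), size=k_visit, p=aff_row / total)
            zones[visit] = bedroom_code[partners]
        # with an all-zero affinity row the resident never visits
    k_common = int(common.sum()) + int(night_out.sum())
    if k_common and len(common_codes):
        picks = rng.choice(common_codes, size=k_common)
        zones[common] = picks[: int(common.sum())]
        zones[night_out] = picks[int(common.sum()):]

    # run-length merge of consecutive identical zones
    episodes: list[tuple[int, int, int]] = []
    cur_zone, cur_start = int(zones[0]), int(starts[0])
    for s, z in zip(starts[1:], zones[1:]):
        if int(z) != cur_zone:
            episodes.append((cur_zone, cur_start, int(s)))
            cur_zone, cur_start = int(z), int(s)
    episodes.append((cur_zone, cur_start, horizon))
    return episodes


def _pair_intersect(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Intersections of two sorted disjoint interval arrays (ground-truth
    path; intentionally independent of the detection module's sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((int(s), int(e)))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Run the generator; returns ``(records, ground_truth)``.

    ``records`` is the noisy sampled stream (``device_id, timestamp,
    zone_id``, device id equals resident id); ``ground_truth`` holds the
    events an ideal lossless sensor would report for the sampled hours, plus
    the planted cluster labels and affinity matrix.
    """
    cfg = config.resolved()
    fac = cfg.facility
    roster = fac.roster()
    zone_ids = sorted(fac.zones)
    zcode = {z: i for i, z in enumerate(zone_ids)}
    bedroom_code = np.array(
        [zcode[fac.residents[r].bedroom_zone] for r in roster], dtype=np.int64
    )
    common_codes = np.array(
        sorted(zcode[z.zone_id] for z in fac.zones_of_class(ZoneClass.COMMON)),
        dtype=np.int64,
    )
    cluster_of: dict[str, int] = {}
    for c, members in enumerate(cfg.planted_clusters):
        for r in members:
            cluster_of[r] = c
    aff = cfg.affinity.to_numpy(float)

    ss = np.random.SeedSequence(cfg.rng_seed)
    children = ss.spawn(len(roster) + 1)

    # --- noiseless trajectories ---------------------------------------
    sampled_eps: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(roster):
        rng = np.random.default_rng(children[i])
        eps = _resident_trajectory(
            i, roster, cfg, cfg.profiles[cluster_of[r]], aff[i],
            bedroom_code, int(bedroom_code[i]), common_codes, rng,
        )
        clipped = []
        for z, s, e in eps:
            for cs, ce in _clip_to_sampling(s, e, cfg):
                clipped.append((z, cs, ce))
        sampled_eps[r] = clipped

    # --- ground-truth events -------------------------------------------
    by_zone: dict[int, dict[str, np.ndarray]] = {}
    for r, eps in sampled_eps.items():
        for z, s, e in eps:
            by_zone.setdefault(z, {}).setdefault(r, []).append((s, e))
    ev_rows = []
    for z, per_res in by_zone.items():
        merged = {}
        for r, ivs in per_res.items():
            ivs = sorted(ivs)
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[r] = np.asarray(out, dtype=np.int64)
        rs = sorted(merged)
        for i, a in enumerate(rs):
            for b in rs[i + 1:]:
                for s, e in _pair_intersect(merged[a], merged[b]):
                    if e - s > cfg.interaction_min_s:
                        ev_rows.append((a, b, zone_ids[z], s, e, e - s))
    true_events = (
        pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
        .sort_values(["start", "resident_a", "resident_b", "zone_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- noisy record emission ------------------------------------------
    neighbor_codes = {
        zcode[z.zone_id]: np.array(
            sorted(zcode[n] for n in z.neighbors)
            if z.neighbors
            else sorted(c for zz, c in zcode.items() if zz != z.zone_id),
            dtype=np.int64,
        )
        for z in fac.zones.values()
    }
    parts = []
    for i, r in enumerate(roster):
        rng = np.random.default_rng(children[i].spawn(1)[0])  # noise sub-stream
        secs = []
        codes = []
        for z, s, e in sampled_eps[r]:
            secs.append(np.arange(s, e, dtype=np.int64))
            codes.append(np.full(e - s, z, dtype=np.int64))
        if not secs:
            continue
        secs = np.concatenate(secs)
        codes = np.concatenate(codes)
        order = np.argsort(secs, kind="mergesort")
        secs, codes = secs[order], codes[order]

        keep = (
            rng.random(len(secs)) < cfg.detection_prob
            if cfg.detection_prob < 1.0
            else np.ones(len(secs), dtype=bool)
        )
        # cross-talk duplicates a *detected* record onto a neighboring
        # sensor: only kept records can be duplicated
        dup = (
            (rng.random(len(secs)) < cfg.duplication_prob) & keep
            if cfg.duplication_prob > 0.0
            else np.zeros(len(secs), dtype=bool)
        )
        out_secs = [secs[keep]]
        out_codes = [codes[keep]]
        if dup.any():
            dsecs = secs[dup]
            dcodes = codes[dup]
            picked = np.empty(len(dsecs), dtype=np.int64)
            for z in np.unique(dcodes):
                m = dcodes == z
                picked[m] = rng.choice(neighbor_codes[int(z)], size=int(m.sum()))
            out_secs.append(dsecs)
            out_codes.append(picked)
        allsec = np.concatenate(out_secs)
        allcode = np.concatenate(out_codes)
        order = np.lexsort((allcode, allsec))
        parts.append(
            pd.DataFrame(
                {
                    "device_id": r,
                    "timestamp": allsec[order],
                    "zone_id": np.asarray(zone_ids, dtype=object)[allcode[order]],
                }
            )
        )
    records = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=RECORD_COLUMNS)
    )
    truth = GroundTruth(
        true_events=true_events,
        planted_clusters=cluster_of,
        affinity=cfg.affinity,
    )
    return records, truth
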