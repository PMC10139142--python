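"""Two-mode and one-mode social networks and per-resident network features.

The analysis follows the standard two-step construction used in spatio-social
network studies: presence intervals first define a *two-mode* (bipartite)
resident-to-location network, and dyadic co-presence events define the
*one-mode* resident-to-resident network whose edge weight is the number of
meaningful-interaction events between the pair.

Per-resident features stratify partners and contact frequencies by the
partner's roommate status and the class of the zone where the event took
place (own bedroom / other bedrooms / common areas), matching the nine-way
layout used for the social-cluster typology, plus overall partner count,
overall daily contact frequency and Freeman-normalized degree centrality.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .facility import Facility, ZoneClass

__all__ = [
    "FEATURE_COLUMNS",
    "ALL_FEATURE_COLUMNS",
    "build_two_mode",
    "project_one_mode",
    "compute_features",
    "summarize_by_group",
    "pooled_mean",
    "export_network",
    "read_network",
]

#: the nine clustering features: four partner-count strata and five
#: frequency strata (including solo episodes)
FEATURE_COLUMNS = [
    "n_partners_roommates_own_bedroom",
    "n_partners_nonroommates_other_bedrooms",
    "n_partners_roommates_common",
    "n_partners_nonroommates_common",
    "freq_roommates_own_bedroom",
    "freq_nonroommates_other_bedrooms",
    "freq_alone",
    "freq_roommates_common",
    "freq_nonroommates_common",
]

ALL_FEATURE_COLUMNS = FEATURE_COLUMNS + [
    "n_partners_total",
    "freq_total",
    "degree_centrality",
]

_STRATA = {
    ("roommate", "own_bedroom"): (
        "n_partners_roommates_own_bedroom",
        "freq_roommates_own_bedroom",
    ),
    ("nonroommate", "bedroom"): (
        "n_partners_nonroommates_other_bedrooms",
        "freq_nonroommates_other_bedrooms",
    ),
    ("roommate", "common"): (
        "n_partners_roommates_common",
        "freq_roommates_common",
    ),
    ("nonroommate", "common"): (
        "n_partners_nonroommates_common",
        "freq_nonroommates_common",
    ),
}


def build_two_mode(intervals: pd.DataFrame, dwell_weight: bool = False) -> nx.Graph:
    """Bipartite resident/zone network from presence intervals.

    Edge weight is the number of distinct visit intervals; the total dwell
    time in seconds is stored as ``dwell_s`` (and becomes ``weight`` when
    ``dwell_weight=True``).
    """
    G = nx.Graph()
    if len(intervals) == 0:
        return G
    collide = set(intervals["device_id"].astype(str)) & set(
        intervals["zone_id"].astype(str)
    )
    if collide:
        raise ValueError(f"resident and zone ids collide: {sorted(collide)}")
    agg = (
        intervals.assign(dwell=intervals["end"] - intervals["start"])
        .groupby(["device_id", "zone_id"], sort=True)
        .agg(n_visits=("dwell", "size"), dwell_s=("dwell", "sum"))
        .reset_index()
    )
    for row in agg.itertuples(index=False):
        G.add_node(row.device_id, bipartite=0, kind="resident")
        G.add_node(row.zone_id, bipartite=1, kind="zone")
        w = int(row.dwell_s) if dwell_weight else int(row.n_visits)
        G.add_edge(
            row.device_id,
            row.zone_id,
            weight=w,
            n_visits=int(row.n_visits),
            dwell_s=int(row.dwell_s),
        )
    return G


def _classify(event_zone: str, a: str, b: str, facility: Facility) -> tuple[str, str]:
    """(relation, place) stratum of one event: relation in
    {roommate, nonroommate}, place in {own_bedroom, bedroom, common, other}."""
    rel = "roommate" if facility.are_roommates(a, b) else "nonroommate"
    zone = facility.zones[event_zone]
    if zone.zone_class is ZoneClass.BEDROOM:
        if rel == "roommate":
            shared = facility.residents[a].bedroom_zone
            place = "own_bedroom" if event_zone == shared else "other"
        else:
            place = "bedroom"
    elif zone.zone_class is ZoneClass.COMMON:
        place = "common"
    else:
        place = "other"
    return rel, place


def project_one_mode(
    events: pd.DataFrame,
    facility: Facility | None = None,
    roster: Sequence[str] | None = None,
) -> nx.Graph:
    """One-mode (resident-resident) projection of the event list.

    Every roster resident appears as a node (isolates included); each edge
    carries ``weight`` (event count) and, when a facility is supplied,
    per-stratum event counts keyed ``n_<relation>_<place>``.
    """
    G = nx.Graph()
    nodes = list(roster) if roster is not None else (
        facility.roster() if facility is not None else []
    )
    G.add_nodes_from(nodes)
    if facility is not None:
        for r in nodes:
            if r in facility.residents:
                G.nodes[r]["bedroom_type"] = facility.residents[r].bedroom_type.value
    if len(events) == 0:
        return G
    for row in events.itertuples(index=False):
        a, b = row.resident_a, row.resident_b
        if not G.has_edge(a, b):
            G.add_edge(a, b, weight=0)
        G[a][b]["weight"] += 1
        if facility is not None:
            rel, place = _classify(row.zone_id, a, b, facility)
            key = f"n_{rel}_{place}"
            G[a][b][key] = G[a][b].get(key, 0) + 1
    return G


def compute_features(
    events: pd.DataFrame,
    facility: Facility,
    window_days: float,
    alone_counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-resident network feature vectors.

    Partner counts are distinct alters per stratum (an alter is counted once
    per stratum however many events the pair shares); frequencies are events
    per sampled day (``window_days`` = number of sampled 24 h days, no
    extrapolation for unsampled hours).  ``degree_centrality`` is the
    Freeman-normalized binary degree: distinct partners over ``N - 1``.
    ``alone_counts`` (from :func:`carenet.copresence.count_alone_episodes`)
    feeds ``freq_alone``; residents absent from it get 0.
    """
    roster = facility.roster()
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    feats = pd.DataFrame(
        0.0, index=pd.Index(roster, name="resident_id"), columns=ALL_FEATURE_COLUMNS
    )
    partner_sets: dict[tuple[str, str], set] = {}
    total_partners: dict[str, set] = {r: set() for r in roster}
    for row in events.itertuples(index=False):
        a, b = row.resident_a, row.resident_b
        for ego, alter in ((a, b), (b, a)):
            if ego not in facility.residents:
                raise KeyError(f"resident {ego!r} not in roster")
            rel, place = _classify(row.zone_id, a, b, facility)
            total_partners[ego].add(alter)
            feats.at[ego, "freq_total"] += 1
            if (rel, place) in _STRATA:
                n_col, f_col = _STRATA[(rel, place)]
                feats.at[ego, f_col] += 1
                partner_sets.setdefault((ego, n_col), set()).add(alter)
    for (ego, n_col), alters in partner_sets.items():
        feats.at[ego, n_col] = len(alters)
    n = len(roster)
    for r in roster:
        feats.at[r, "n_partners_total"] = len(total_partners[r])
        feats.at[r, "degree_centrality"] = (
            len(total_partners[r]) / (n - 1) if n > 1 else 0.0
        )
    freq_cols = [c for c in ALL_FEATURE_COLUMNS if c.startswith("freq")]
    feats[freq_cols] = feats[freq_cols] / float(window_days)
    if alone_counts is not None:
        feats["freq_alone"] = (
            alone_counts.reindex(roster).fillna(0).astype(float) / float(window_days)
        )
    return feats


def summarize_by_group(
    features: pd.DataFrame,
    grouping: pd.Series | Mapping[str, str],
    columns: Sequence[str] = ("n_partners_total", "freq_total", "degree_centrality"),
) -> pd.DataFrame:
    """Per-group unweighted means plus an overall participant-weighted row.

    ``grouping`` maps each resident to a group label and must cover all rows
    of ``features``.  Empty groups are reported as missing (NaN).  The
    ``overall`` row weights each group mean by its participant count, which
    equals the plain mean over residents.
    """
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    missing = features.index.difference(grouping.index)
    if len(missing):
        raise ValueError(f"grouping does not cover residents: {list(missing)}")
    g = grouping.reindex(features.index)
    out = features[list(columns)].groupby(g).mean()
    out["n"] = features.groupby(g).size()
    overall = features[list(columns)].mean()
    overall["n"] = len(features)
    out.loc["overall"] = overall
    return out


def pooled_mean(group_means: Sequence[float], group_counts: Sequence[int]) -> float:
    """Participant-weighted overall mean from per-group means and sizes."""
    m = np.asarray(group_means, dtype=float)
    n = np.asarray(group_counts, dtype=float)
    if m.shape != n.shape or n.sum() <= 0:
        raise ValueError("means and counts must align with positive total count")
    return float((m * n).sum() / n.sum())


def export_network(G: nx.Graph, path, fmt: str = "graphml") -> None:
    """Serialize a network as GraphML, GEXF, or an edge-list CSV."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
    elif fmt == "csv":
        rows = [
            {"source": u, "target": v, **{k: d[k] for k in sorted(d)}}
            for u, v, d in G.edges(data=True)
        ]
        pd.DataFrame(rows, columns=None).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        return nx.read_gexf(path)
    raise ValueError(f"unknown network format {fmt!r}")
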