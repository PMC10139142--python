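"""Report-shaped tables and display rounding.

All internal computation runs at full precision; these helpers only shape and
round for display.  Display rounding is round-half-up to 2 decimal places
(0.125 -> "0.13"), applied uniformly to means and percentages.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .association import AssociationTable
from .clustering import ContingencyTable
from .facility import BedroomType, Facility, PrivacyAssessment

__all__ = [
    "round_half_up",
    "fmt",
    "participant_table",
    "privacy_table",
    "network_summary_table",
    "cluster_means_table",
    "contingency_table",
    "association_report",
    "render_text",
]

BEDROOM_ORDER = [t.value for t in BedroomType]
BEDROOM_DISPLAY = {
    "three_bed": "Three-bedroom",
    "four_bed_corridor": "Four-bedroom (corridor)",
    "four_bed_common": "Four-bedroom (common)",
    "five_bed": "Five-bedroom",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (0.125 -> 0.13)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float, ndigits: int = 2) -> str:
    v = round_half_up(x, ndigits)
    return "" if np.isnan(v) else f"{v:.{ndigits}f}"


def participant_table(facility: Facility) -> pd.DataFrame:
    """Participant counts and % of sample by bedroom type (plus a total)."""
    counts = facility.bedroom_type_counts()
    total = sum(counts.values())
    rows = {}
    by_sex: dict[str, dict] = {"M": {}, "F": {}}
    for t in BedroomType:
        members = [r for r in facility.residents.values() if r.bedroom_type is t]
        by_sex["M"][t.value] = sum(1 for r in members if r.sex == "M")
        by_sex["F"][t.value] = sum(1 for r in members if r.sex == "F")
    rows["pct_of_sample"] = {
        t.value: round_half_up(100.0 * counts[t] / total) for t in BedroomType
    }
    rows["male"] = by_sex["M"]
    rows["female"] = by_sex["F"]
    rows["total"] = {t.value: counts[t] for t in BedroomType}
    df = pd.DataFrame(rows).T[BEDROOM_ORDER]
    df["total"] = [100.0, sum(by_sex["M"].values()), sum(by_sex["F"].values()), total]
    return df


def privacy_table(assessments: Mapping[str, PrivacyAssessment], facility: Facility) -> pd.DataFrame:
    """Per-bedroom-type factor scores and totals (one column per type).

    All bedrooms of a type share architectural attributes in a well-formed
    facility description; the first bedroom of each type represents it.
    """
    cols = {}
    for t in BedroomType:
        zones = sorted(
            {facility.residents[r].bedroom_zone
             for r in facility.roster()
             if facility.residents[r].bedroom_type is t}
        )
        if not zones:
            continue
        a = assessments[zones[0]]
        cols[t.value] = {
            "occupancy": a.occupancy_score,
            "adjacency": a.adjacency_score,
            "transitional": a.transitional_score,
            "visual_privacy": a.visual_privacy_score,
            "visibility": a.visibility_score,
            "total": a.total,
        }
    return pd.DataFrame(cols)


def network_summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Round a group-summary frame for display (2 dp, half-up)."""
    out = summary.copy()
    for c in out.columns:
        if c != "n":
            out[c] = out[c].map(lambda v: round_half_up(v))
    return out


def cluster_means_table(
    cluster_means: pd.DataFrame,
    flags: pd.DataFrame,
    shares: pd.Series,
) -> pd.DataFrame:
    """Cluster-centroid table: rounded means, '*' on flagged (extreme) cells,
    a cross-cluster Mean column, and a share-of-sample row."""
    cells = pd.DataFrame(index=cluster_means.index, columns=cluster_means.columns, dtype=object)
    for c in cluster_means.index:
        for f in cluster_means.columns:
            mark = "*" if bool(flags.at[c, f]) else ""
            cells.at[c, f] = f"{fmt(cluster_means.at[c, f])}{mark}"
    out = cells.T
    out["Mean"] = [fmt(cluster_means[f].mean()) for f in cluster_means.columns]
    share_row = {c: fmt(shares.get(c, np.nan)) for c in out.columns if c != "Mean"}
    share_row["Mean"] = ""
    out.loc["of_sample_pct"] = pd.Series(share_row)
    return out


def contingency_table(table: ContingencyTable) -> pd.DataFrame:
    """Counts with within-type percentages, largest share starred."""
    out = pd.DataFrame(index=table.counts.index, columns=table.counts.columns, dtype=object)
    for r in table.counts.index:
        for c in table.counts.columns:
            pct = table.column_pct.at[r, c]
            star = "*" if bool(table.column_max.at[r, c]) else ""
            out.at[r, c] = f"{int(table.counts.at[r, c])} ({fmt(pct, 1)}%){star}"
    out.loc["total"] = [str(int(v)) for v in table.counts.sum(axis=0)]
    return out


def association_report(table: AssociationTable) -> pd.DataFrame:
    """Coefficient (p-value) cells with significance stars."""
    out = pd.DataFrame(index=table.coef.index, columns=table.coef.columns, dtype=object)
    for o in table.coef.index:
        for p in table.coef.columns:
            r = table.coef.at[o, p]
            pv = table.pvalues.at[o, p]
            if np.isnan(r):
                out.at[o, p] = "undefined"
                continue
            tier = table.tiers.at[o, p]
            star = tier if tier in ("*", "**") else ""
            out.at[o, p] = f"{round_half_up(r, 3):.3f}{star} ({round_half_up(pv, 3):.3f})"
    return out


def render_text(df: pd.DataFrame, title: str | None = None) -> str:
    body = df.to_string()
    return f"{title}\n{'=' * len(title)}\n{body}\n" if title else body + "\n"
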