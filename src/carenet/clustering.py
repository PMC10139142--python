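"""Social-cluster typology: k-means over the nine network features, elbow
selection, rule-based cluster naming, extremeness flagging and
cluster-by-bedroom contingency tables.

Residents are grouped by non-hierarchical k-means (Euclidean distance, best
of ``n_restarts`` initialisations per k, k swept from 1 to 10).  The elbow of
the within-cluster sum-of-squares (WCSS) curve picks k, with a manual
override for conceptual judgement.  Clusters are then named after the
classical social-network typology for older adults — diverse,
non-roommate-focused, roommate-focused, restricted — by comparing raw-scale
centroids across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .facility import BedroomType, Facility
from .networks import FEATURE_COLUMNS

__all__ = [
    "LABELS",
    "FeatureMatrix",
    "ClusterModel",
    "build_feature_matrix",
    "kmeans_sweep",
    "elbow_select",
    "label_clusters",
    "flag_extremes",
    "cluster_by_bedroom_table",
]

LABEL_DIVERSE_COMMON = "Diverse (common area)"
LABEL_DIVERSE_BEDROOM = "Diverse (bedroom)"
LABEL_NONROOMMATE = "Non-roommate-focused"
LABEL_ROOMMATE = "Roommate-focused"
LABEL_RESTRICTED = "Restricted"
LABEL_UNCLASSIFIED = "unclassified"
LABELS = [
    LABEL_DIVERSE_COMMON,
    LABEL_DIVERSE_BEDROOM,
    LABEL_NONROOMMATE,
    LABEL_ROOMMATE,
    LABEL_RESTRICTED,
]

_PARTNER_COLS = [c for c in FEATURE_COLUMNS if c.startswith("n_partners")]
_FREQ_COLS = [c for c in FEATURE_COLUMNS if c.startswith("freq")]


@dataclass
class FeatureMatrix:
    """Residents-by-features matrix ready for clustering.

    Missing cells are imputed to zero (a resident with no events has an
    all-zero row); z-score standardization is on by default so that the
    high-count frequency features do not dominate the Euclidean metric.
    """

    values: np.ndarray
    index: pd.Index
    columns: list[str]
    standardized: bool
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.columns)


def build_feature_matrix(
    features: pd.DataFrame,
    columns: Sequence[str] = tuple(FEATURE_COLUMNS),
    standardize: bool = True,
) -> FeatureMatrix:
    X = features[list(columns)].fillna(0.0).to_numpy(float)
    center = scale = None
    if standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        X = (X - center) / scale
    return FeatureMatrix(
        values=X,
        index=features.index,
        columns=list(columns),
        standardized=standardize,
        center=center,
        scale=scale,
    )


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # resident -> cluster index (0-based)
    centroids: pd.DataFrame  # cluster x feature, on the clustering scale
    wcss: float
    rng_seed: int
    labels: dict[int, str] | None = None
    ambiguous: set[int] = field(default_factory=set)


def kmeans_sweep(
    matrix: FeatureMatrix,
    k_range: Sequence[int] = range(1, 11),
    n_restarts: int = 50,
    seed: int = 0,
) -> dict[int, ClusterModel]:
    """Best-of-restarts k-means for every k in ``k_range``.

    Deterministic under a fixed seed (each k uses a seed derived from it).
    ``k`` larger than the number of rows is an error.
    """
    n = matrix.values.shape[0]
    out: dict[int, ClusterModel] = {}
    for k in k_range:
        if k < 1 or k > n:
            raise ValueError(f"k={k} outside [1, n={n}]")
        km = KMeans(
            n_clusters=k,
            n_init=n_restarts,
            random_state=(seed + k) % (2**32),
        ).fit(matrix.values)
        out[k] = ClusterModel(
            k=k,
            assignments=pd.Series(
                km.labels_.astype(int), index=matrix.index, name="cluster"
            ),
            centroids=pd.DataFrame(km.cluster_centers_, columns=matrix.columns),
            wcss=float(km.inertia_),
            rng_seed=seed,
        )
    return out


def elbow_select(
    wcss_by_k: Mapping[int, float], override: int | None = None
) -> int:
    """Pick k at the elbow of the WCSS curve.

    The elbow is the k maximizing the second forward difference
    ``wcss[k-1] - 2*wcss[k] + wcss[k+1]`` over consecutive k; ties break to
    the smallest k.  ``override`` short-circuits the rule (cluster solutions
    must also make conceptual sense, so manual choice is first-class).
    """
    if override is not None:
        return int(override)
    ks = sorted(wcss_by_k)
    if len(ks) < 3:
        raise ValueError("need WCSS for at least 3 consecutive k")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k values must be consecutive")
    w = np.array([wcss_by_k[k] for k in ks], dtype=float)
    if np.any(np.diff(w) > 1e-9):
        warnings.warn("WCSS increases with k; restarts may be too few")
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]  # indexed by interior ks
    best = int(np.argmax(np.round(d2, 12)))  # first max wins -> smallest k
    return ks[1 + best]


def _argmax_clusters(series: pd.Series) -> list[int]:
    m = series.max()
    return sorted(int(c) for c in series.index[series == m])


def label_clusters(
    model: ClusterModel, features: pd.DataFrame
) -> dict[int, str]:
    """Assign typology names to clusters from raw-scale cluster means.

    Rules (applied in order; each label used at most once; ties break to the
    smallest cluster index, with all tied clusters flagged ambiguous):

    - *Restricted*: lowest summed partner counts and lowest summed contact
      frequencies.
    - *Diverse (common area)*: highest contact frequency with roommates in
      common areas.
    - *Non-roommate-focused*: highest contact frequency with non-roommates in
      common areas.
    - *Diverse (bedroom)*: highest contact frequency with roommates in own
      bedrooms.
    - *Roommate-focused*: above-average roommate partners in own bedrooms and
      below-average non-roommate contact in common areas.

    Clusters matching no rule are labeled ``unclassified``.
    """
    means = (
        features.loc[model.assignments.index, FEATURE_COLUMNS]
        .groupby(model.assignments)
        .mean()
    )
    labels: dict[int, str] = {}
    model.ambiguous = set()

    def take(candidates: list[int], label: str) -> None:
        free = [c for c in candidates if c not in labels]
        if not free:
            return
        if len(free) > 1:
            model.ambiguous.update(free)
        labels[free[0]] = label

    partner_sum = means[_PARTNER_COLS].sum(axis=1)
    freq_sum = means[_FREQ_COLS].sum(axis=1)
    low_p = set(_argmax_clusters(-partner_sum))
    low_f = set(_argmax_clusters(-freq_sum))
    restricted = sorted(low_p & low_f)
    if restricted:
        take(restricted, LABEL_RESTRICTED)

    take(_argmax_clusters(means["freq_roommates_common"]), LABEL_DIVERSE_COMMON)
    take(_argmax_clusters(means["freq_nonroommates_common"]), LABEL_NONROOMMATE)
    take(_argmax_clusters(means["freq_roommates_own_bedroom"]), LABEL_DIVERSE_BEDROOM)

    rm_mean = means["n_partners_roommates_own_bedroom"].mean()
    nrc_mean = means["freq_nonroommates_common"].mean()
    for c in means.index:
        if c in labels:
            continue
        if (
            means.at[c, "n_partners_roommates_own_bedroom"] >= rm_mean
            and means.at[c, "freq_nonroommates_common"] <= nrc_mean
        ):
            labels[int(c)] = LABEL_ROOMMATE

    for c in means.index:
        labels.setdefault(int(c), LABEL_UNCLASSIFIED)
    model.labels = {int(c): labels[int(c)] for c in sorted(labels)}
    return model.labels


def flag_extremes(
    cluster_means: pd.DataFrame,
    overall_mean: pd.Series,
    sd: pd.Series,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag cluster means at least ``threshold`` SDs away from the overall
    mean (the table-bolding rule).  Features with zero SD yield no flags."""
    cm = cluster_means
    mean = overall_mean.reindex(cm.columns)
    s = sd.reindex(cm.columns)
    flags = (cm.sub(mean, axis=1).abs()).ge(threshold * s, axis=1)
    flags.loc[:, (s <= 0) | s.isna()] = False
    return flags


@dataclass
class ContingencyTable:
    counts: pd.DataFrame  # label x bedroom type
    column_pct: pd.DataFrame  # within-bedroom-type percentages
    column_max: pd.DataFrame  # bold markers: largest share per bedroom type
    cluster_share: pd.Series  # cluster share of the total sample (%)


def cluster_by_bedroom_table(
    assignments: pd.Series,
    facility: Facility,
    labels: Mapping[int, str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate cluster membership against bedroom type.

    Rows are clusters (typology labels when given), columns bedroom types;
    cell percentages are within-column (within bedroom type), and
    ``cluster_share`` gives each cluster's share of the whole sample.
    """
    missing = [r for r in facility.roster() if r not in assignments.index]
    if missing:
        raise ValueError(f"assignments do not cover roster: {missing}")
    rows = assignments.map(labels) if labels is not None else assignments
    btype = pd.Series(
        {r: facility.residents[r].bedroom_type.value for r in assignments.index}
    )
    counts = pd.crosstab(rows, btype.reindex(assignments.index))
    counts = counts.reindex(columns=[t.value for t in BedroomType], fill_value=0)
    col_tot = counts.sum(axis=0)
    column_pct = counts.div(col_tot.where(col_tot > 0), axis=1) * 100.0
    column_max = column_pct.eq(column_pct.max(axis=0), axis=1) & (counts > 0)
    cluster_share = counts.sum(axis=1) / counts.to_numpy().sum() * 100.0
    cluster_share.name = "share_pct"
    return ContingencyTable(counts, column_pct, column_max, cluster_share)
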