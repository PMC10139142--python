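"""Associations between bedroom-privacy factors and network structure.

Produces the 9-outcome x 6-predictor association table (degree centrality,
four partner-count strata and four contact-frequency strata against overall
privacy plus the five factors).  Two inferential modes are supported:

- pairwise Pearson correlations with two-sided p-values (the default table),
- ordinary least squares on standardized variables (multiple regression).

Predictors are bedroom-level scores broadcast to residents, so observations
within a bedroom share predictor values; with only four distinct bedroom
types the five factors are exactly collinear, which the OLS path detects and
reports rather than silently absorbing.  No multiple-testing correction is
applied by default (a Benjamini-Hochberg option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .facility import DEFAULT_VISIBILITY_CODING, Facility, assess_facility

__all__ = [
    "OUTCOME_COLUMNS",
    "PREDICTOR_COLUMNS",
    "AssociationTable",
    "privacy_predictors",
    "correlate",
    "multiple_regress",
    "association_table",
    "null_calibration",
    "significance_tier",
]

#: the nine outcome variables of the association table, in report order
OUTCOME_COLUMNS = [
    "degree_centrality",
    "n_partners_roommates_own_bedroom",
    "n_partners_nonroommates_other_bedrooms",
    "n_partners_roommates_common",
    "n_partners_nonroommates_common",
    "freq_roommates_own_bedroom",
    "freq_nonroommates_other_bedrooms",
    "freq_roommates_common",
    "freq_nonroommates_common",
]

PREDICTOR_COLUMNS = [
    "overall_privacy",
    "occupancy_score",
    "visual_privacy_score",
    "visibility_score",
    "adjacency_score",
    "transitional_score",
]

FACTOR_COLUMNS = PREDICTOR_COLUMNS[1:]


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear predictor columns: {columns}")


def significance_tier(p: float) -> str:
    """``**`` for p<0.01, ``*`` for p<0.05, ``ns`` otherwise (NaN -> ``na``)."""
    if p is None or np.isnan(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AssociationTable:
    coef: pd.DataFrame
    pvalues: pd.DataFrame
    tiers: pd.DataFrame
    mode: str = "pearson"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (outcome, predictor) cell."""
        rows = []
        for o in self.coef.index:
            for p in self.coef.columns:
                rows.append(
                    {
                        "outcome": o,
                        "predictor": p,
                        "coef": self.coef.at[o, p],
                        "p_value": self.pvalues.at[o, p],
                        "tier": self.tiers.at[o, p],
                    }
                )
        return pd.DataFrame(rows)


def privacy_predictors(
    facility: Facility, visibility_coding: str = DEFAULT_VISIBILITY_CODING
) -> pd.DataFrame:
    """Per-resident predictor matrix: bedroom-level privacy scores broadcast
    to each resident of the bedroom (within-bedroom rows are identical; the
    non-independence this induces is a documented caveat of the design)."""
    assessments = assess_facility(facility, visibility_coding)
    rows = {}
    for r in facility.roster():
        a = assessments[facility.residents[r].bedroom_zone]
        rows[r] = {
            "overall_privacy": a.total,
            "occupancy_score": a.occupancy_score,
            "visual_privacy_score": a.visual_privacy_score,
            "visibility_score": a.visibility_score,
            "adjacency_score": a.adjacency_score,
            "transitional_score": a.transitional_score,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[PREDICTOR_COLUMNS]


def correlate(
    outcomes: pd.DataFrame,
    predictors: pd.DataFrame,
    bh_correct: bool = False,
) -> AssociationTable:
    """Pearson r with two-sided p for every (outcome, predictor) pair.

    Requires at least 3 complete rows.  Zero-variance columns yield NaN
    cells marked ``na``.  ``bh_correct`` applies Benjamini-Hochberg across
    all cells before tiering.
    """
    common = outcomes.index.intersection(predictors.index)
    if len(common) < 3:
        raise ValueError("need at least 3 complete resident rows")
    O = outcomes.loc[common]
    P = predictors.loc[common]
    coef = pd.DataFrame(np.nan, index=O.columns, columns=P.columns)
    pval = pd.DataFrame(np.nan, index=O.columns, columns=P.columns)
    for o in O.columns:
        y = O[o].to_numpy(float)
        for p in P.columns:
            x = P[p].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, pv = scipy.stats.pearsonr(x, y)
            coef.at[o, p] = r
            pval.at[o, p] = pv
    pt = pval.copy()
    if bh_correct:
        flat = pval.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = flat.copy()
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        pt = pd.DataFrame(
            adj.reshape(pval.shape), index=pval.index, columns=pval.columns
        )
    tiers = pt.map(significance_tier)
    return AssociationTable(coef=coef, pvalues=pval, tiers=tiers, mode="pearson")


@dataclass
class RegressionResult:
    coef: pd.Series  # standardized coefficients
    pvalues: pd.Series
    r_squared: float
    n: int


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns made redundant by earlier ones, via pivoted QR."""
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(names[i] for i in piv[rank:])


def multiple_regress(
    outcome: pd.Series,
    factors: pd.DataFrame,
    on_collinear: str = "raise",
) -> RegressionResult:
    """OLS of one outcome on the privacy factors, standardized scale.

    Both sides are z-scored, so coefficients are standardized betas with
    t-based p-values.  Rank-deficient designs raise
    :class:`CollinearityError` naming the redundant columns (with predictors
    broadcast from only four distinct bedroom types this is the expected
    outcome); ``on_collinear="drop"`` instead drops them and proceeds.
    """
    common = outcome.index.intersection(factors.index)
    X = factors.loc[common].to_numpy(float)
    y = outcome.loc[common].to_numpy(float)
    names = list(factors.columns)
    if len(common) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    sx = X.std(axis=0)
    if np.any(sx == 0):
        bad = [names[i] for i in np.where(sx == 0)[0]]
        raise CollinearityError(bad)
    Xz = (X - X.mean(axis=0)) / sx
    sy = y.std()
    if sy == 0:
        raise ValueError("outcome has zero variance")
    yz = (y - y.mean()) / sy
    bad = _collinear_columns(Xz, names)
    if bad:
        if on_collinear == "raise":
            raise CollinearityError(bad)
        keep = [n for n in names if n not in bad]
        names = keep
        Xz = (factors.loc[common, keep].to_numpy(float) - factors.loc[common, keep].mean().to_numpy()) / factors.loc[common, keep].std(ddof=0).to_numpy()
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    coef = pd.Series(model.params[1:], index=names)
    pvals = pd.Series(model.pvalues[1:], index=names)
    return RegressionResult(
        coef=coef, pvalues=pvals, r_squared=float(model.rsquared), n=len(common)
    )


def association_table(
    features: pd.DataFrame,
    facility: Facility,
    mode: str = "pearson",
    visibility_coding: str = DEFAULT_VISIBILITY_CODING,
    bh_correct: bool = False,
) -> AssociationTable:
    """The 9x6 privacy-network association table.

    Default mode is pairwise Pearson correlation (the convention the table
    layout reports); ``mode="ols"`` fills factor columns with standardized
    multiple-regression coefficients instead and requires a full-rank design.
    """
    predictors = privacy_predictors(facility, visibility_coding)
    outcomes = features[OUTCOME_COLUMNS]
    if mode == "pearson":
        return correlate(outcomes, predictors, bh_correct=bh_correct)
    if mode != "ols":
        raise ValueError(f"unknown mode {mode!r}")
    coef = pd.DataFrame(np.nan, index=OUTCOME_COLUMNS, columns=PREDICTOR_COLUMNS)
    pval = coef.copy()
    for o in OUTCOME_COLUMNS:
        res = multiple_regress(features[o], predictors[FACTOR_COLUMNS])
        coef.loc[o, FACTOR_COLUMNS] = res.coef
        pval.loc[o, FACTOR_COLUMNS] = res.pvalues
        r, pv = scipy.stats.pearsonr(
            predictors["overall_privacy"].to_numpy(float), features[o].to_numpy(float)
        )
        coef.at[o, "overall_privacy"] = r
        pval.at[o, "overall_privacy"] = pv
    tiers = pval.map(significance_tier)
    return AssociationTable(coef=coef, pvalues=pval, tiers=tiers, mode="ols")


@dataclass
class CalibrationResult:
    n_reps: int
    alpha: float
    rejection_rate: float
    ci_low: float
    ci_high: float
    sign_correct_rate: float | None  # among planted-effect reps: significant AND correct sign


def null_calibration(
    predictor: Sequence[float] | pd.Series,
    n_reps: int,
    seed: int,
    effect: float = 0.0,
    alpha: float = 0.05,
) -> CalibrationResult:
    """Monte-Carlo calibration of the Pearson test against a fixed predictor.

    Each replicate draws ``y = effect * z(predictor) + N(0, 1)`` and tests
    the outcome-predictor correlation at level ``alpha``.  With
    ``effect=0`` this measures the empirical type-I error (should sit inside
    the binomial band around ``alpha``); with a nonzero effect it measures
    power and the rate of significant results with the planted sign.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    x = np.asarray(predictor, dtype=float)
    if x.std() == 0:
        raise ValueError("predictor has zero variance")
    xz = (x - x.mean()) / x.std()
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_sign = 0
    for _ in range(n_reps):
        y = effect * xz + rng.standard_normal(len(x))
        r, p = scipy.stats.pearsonr(x, y)
        if p < alpha:
            n_sig += 1
            if effect != 0 and np.sign(r) == np.sign(effect):
                n_sign += 1
    lo, hi = proportion_confint(n_sig, n_reps, alpha=0.05, method="normal")
    return CalibrationResult(
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=n_sig / n_reps,
        ci_low=float(lo),
        ci_high=float(hi),
        sign_correct_rate=(n_sign / n_reps) if effect != 0 else None,
    )
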