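"""Exposure-disparity statistics: relative disparity, per-source
rankings, income quintiles, and Q-Q distributional comparisons.

The relative exposure disparity of group d is

    D_d = (PopWtdConc_d - PopWtdConc_t) / PopWtdConc_t

so D_d = +1.20 means the group's population-weighted exposure is 2.2
times the domain average (exposure ratio 1 + D_d).  Because the total is
itself the population-weighted mean over an exhaustive group partition,
the population-weighted average of D_d across groups is exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import pop_weighted_concentration
from .transport import TractConcentrations

logger = logging.getLogger(__name__)

QQ_PERCENTILES = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95)


@dataclass
class DisparityResult:
    group: str
    disparity: float
    per_source_disparity: pd.Series  # sorted descending
    fraction_sources_positive: float

    @property
    def exposure_ratio(self) -> float:
        return 1.0 + self.disparity


def relative_disparity(group_conc: float, total_conc: float) -> float:
    """(group - total) / total; the group-relative exposure excess."""
    if total_conc <= 0:
        raise ValueError("total population-weighted concentration must be positive")
    return (group_conc - total_conc) / total_conc


def per_source_disparity(
    tract_conc: TractConcentrations,
    group_pops: pd.Series,
    total_pops: pd.Series,
) -> DisparityResult:
    """Disparity of one group overall and per source category.

    Each category's disparity is the relative-disparity statistic
    applied to that category's concentration component.  Categories with
    zero domain-wide weighted mean are excluded (and logged): their
    ratio is undefined.  Categories are ranked descending by disparity.
    """
    total_overall = pop_weighted_concentration(tract_conc.total, total_pops)
    group_overall = pop_weighted_concentration(tract_conc.total, group_pops)
    overall = relative_disparity(group_overall, total_overall)

    per_source = {}
    for cat in tract_conc.categories:
        comp = tract_conc.values[cat]
        tmean = pop_weighted_concentration(comp, total_pops)
        if tmean <= 0:
            logger.warning("category %s has zero weighted mean; excluded", cat)
            continue
        gmean = pop_weighted_concentration(comp, group_pops)
        per_source[cat] = relative_disparity(gmean, tmean)
    ps = pd.Series(per_source).sort_values(ascending=False)
    frac_pos = float((ps > 0).mean()) if len(ps) else float("nan")
    return DisparityResult(
        group=str(group_pops.name or "group"),
        disparity=overall,
        per_source_disparity=ps,
        fraction_sources_positive=frac_pos,
    )


def assign_income_quintiles(
    tracts: pd.DataFrame, by: str = "population"
) -> pd.DataFrame:
    """Label each tract Q1 (lowest income) .. Q5 (highest income).

    Tracts are ranked by mean income (ties broken by tract_id).  With
    ``by="population"`` (default) the cuts fall at 20/40/60/80% of
    cumulative population, so each quintile holds ~20% of people; with
    ``by="count"`` the cuts are on tract counts instead.
    """
    if tracts["mean_income"].isna().any():
        bad = tracts.loc[tracts["mean_income"].isna(), "tract_id"].tolist()
        raise ValueError(f"tracts missing mean income: {bad}")
    if by not in ("population", "count"):
        raise ValueError("by must be 'population' or 'count'")
    order = tracts.sort_values(["mean_income", "tract_id"]).index
    weights = (
        tracts.loc[order, "pop_total"].to_numpy(dtype=float)
        if by == "population"
        else np.ones(len(order))
    )
    cum = np.cumsum(weights)
    total = cum[-1]
    # midpoint rule: a tract belongs to the quintile containing the
    # midpoint of its cumulative-weight interval
    mid = cum - weights / 2.0
    q = np.minimum((mid / total * 5).astype(int), 4)
    labels = pd.Series([f"Q{i + 1}" for i in q], index=order)
    out = tracts.copy()
    out["quintile"] = labels.reindex(out.index).astype("string")
    return out


def quintile_populations(tracts: pd.DataFrame) -> pd.DataFrame:
    """Per-tract population by income quintile (columns Q1..Q5); a
    tract's whole population sits in its assigned quintile."""
    out = pd.DataFrame(
        0.0, index=pd.Index(tracts["tract_id"], name="tract_id"),
        columns=[f"Q{i}" for i in range(1, 6)],
    )
    for tid, q, p in zip(tracts["tract_id"], tracts["quintile"], tracts["pop_total"]):
        if pd.isna(q):
            raise ValueError("assign_income_quintiles must run first")
        out.loc[tid, str(q)] = float(p)
    return out


def weighted_quantile(values: np.ndarray, weights: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Quantiles of a weighted empirical distribution (inverse-CDF rule
    on the cumulative weights, midpoint convention)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(np.asarray(qs, dtype=float), cdf, v)


def qq_compare(
    conc: pd.Series,
    group_pops: pd.Series,
    total_pops: pd.Series,
    percentiles: tuple[int, ...] = QQ_PERCENTILES,
) -> pd.DataFrame:
    """Matched person-level exposure quantiles: group vs population.

    Each person carries their tract's concentration; quantiles are
    population-weighted.  Points above the 1:1 line at a percentile mean
    the group experiences higher concentrations there.
    """
    gp = group_pops.reindex(conc.index).fillna(0.0)
    tp = total_pops.reindex(conc.index).fillna(0.0)
    if gp.sum() <= 0:
        raise ValueError("group population is empty")
    qs = np.asarray(percentiles, dtype=float) / 100.0
    return pd.DataFrame(
        {
            "percentile": list(percentiles),
            "group_quantile": weighted_quantile(conc.to_numpy(), gp.to_numpy(), qs),
            "population_quantile": weighted_quantile(conc.to_numpy(), tp.to_numpy(), qs),
        }
    )
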